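"""Per-base conservation scoring of genomic features.

phastCons-style fragment scores (per-base scores summed and divided by
fragment length) over exons, introns, 1000-bp promoters, and random
intergenic background fragments (3400 bp +- 20%); phyloP-style maxima
over a strand-aware -500/+100 window around the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, complement, merge_intervals
from .lncrna import TranscriptModel, group_by_gene

PROMOTER_LENGTH = 1000
PHYLOP_UPSTREAM = 500
PHYLOP_DOWNSTREAM = 100
INTERGENIC_SIZE_MEAN = 3400
INTERGENIC_SIZE_JITTER = 0.2


@dataclass
class ConservationTrack:
    """Sparse per-base scores: sorted non-overlapping runs per chromosome.

    ``runs[chrom]`` is (starts, ends, values). Uncovered bases read as 0
    in phastCons-style averaging; phyloP-style maxima ignore them (a max
    over signed scores must not be dragged to 0 by missing data).
    """

    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, (s, e, _) in self.runs.items():
            if np.any(s[1:] < e[:-1]) or np.any(s >= e):
                raise ValueError(f"{chrom}: runs must be sorted and non-overlapping")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, chrom_sizes: dict[str, int]):
        """Build from bedGraph-like columns (chrom, start, end, value)."""
        runs = {}
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("start")
            runs[chrom] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )
        return cls(runs=runs, chrom_sizes=dict(chrom_sizes))

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v})
            for chrom, (s, e, v) in sorted(self.runs.items())
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(frames, ignore_index=True)

    def _overlaps(self, interval: GenomicInterval):
        """(lengths, values) of run fragments intersecting the interval."""
        if interval.chrom not in self.runs:
            return np.zeros(0, dtype=np.int64), np.zeros(0)
        s, e, v = self.runs[interval.chrom]
        lo = np.searchsorted(e, interval.start, side="right")
        hi = np.searchsorted(s, interval.end, side="left")
        if lo >= hi:
            return np.zeros(0, dtype=np.int64), np.zeros(0)
        cs = np.maximum(s[lo:hi], interval.start)
        ce = np.minimum(e[lo:hi], interval.end)
        return ce - cs, v[lo:hi]

    def fragment_sum(self, interval: GenomicInterval) -> tuple[float, int]:
        """(sum of per-base scores, covered bp) over an interval."""
        lengths, values = self._overlaps(interval)
        return float(np.dot(lengths, values)), int(lengths.sum())

    def fragment_max(self, interval: GenomicInterval) -> float:
        """Max per-base score over covered bases; NaN if none covered."""
        lengths, values = self._overlaps(interval)
        values = values[lengths > 0]
        return float(values.max()) if values.size else float("nan")


def fragment_score(track: ConservationTrack, interval: GenomicInterval) -> float:
    """Mean per-base score: sum / fragment length (uncovered bases = 0).

    Warns when the interval is entirely uncovered."""
    if interval.chrom in track.chrom_sizes and interval.end > track.chrom_sizes[interval.chrom]:
        raise ValueError(f"interval {interval} beyond chromosome")
    total, covered = track.fragment_sum(interval)
    if covered == 0:
        warnings.warn(f"interval {interval} has no conservation coverage",
                      stacklevel=2)
    return total / interval.length


def fragment_score_set(
    track: ConservationTrack, intervals: Sequence[GenomicInterval]
) -> float:
    """Length-weighted fragment score over a set (e.g. merged exons)."""
    if not intervals:
        return float("nan")
    total = 0.0
    length = 0
    for iv in intervals:
        s, _ = track.fragment_sum(iv)
        total += s
        length += iv.length
    return total / length


def promoter_interval(
    t: TranscriptModel, length: int = PROMOTER_LENGTH
) -> GenomicInterval:
    """The ``length`` bp immediately upstream of the TSS, strand-aware.

    '+': [tss-length, tss); '-': [tss+1, tss+length+1); clipped to the
    chromosome at position 0 (callers flag clipping at the 3' edge).
    """
    if t.strand == "-":
        return GenomicInterval(t.chrom, t.tss + 1, t.tss + 1 + length, "-")
    return GenomicInterval(t.chrom, max(0, t.tss - length), max(1, t.tss), "+")


def feature_scores(
    track: ConservationTrack,
    models: Sequence[TranscriptModel],
    promoter_length: int = PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Per-gene phastCons-style scores for exons, introns, promoters.

    Exon/intron scores are per-transcript fragment scores averaged over
    the gene's transcripts (single-exon transcripts contribute no intron
    score); the promoter score is computed once over the merged set of
    the transcripts' 1-kb upstream windows.
    """
    rows = []
    for gene_id, txs in group_by_gene(models).items():
        exon_scores, intron_scores = [], []
        promoters = []
        for t in txs:
            exon_scores.append(fragment_score_set(track, t.exons))
            introns = [
                GenomicInterval(t.chrom, a.end, b.start, t.strand)
                for a, b in zip(t.exons, t.exons[1:])
                if b.start > a.end
            ]
            if introns:
                intron_scores.append(fragment_score_set(track, introns))
            promoters.append(promoter_interval(t, promoter_length))
        merged_prom = merge_intervals(promoters)
        size = track.chrom_sizes.get(txs[0].chrom)
        if size is not None:
            merged_prom = [
                GenomicInterval(p.chrom, p.start, min(p.end, size))
                for p in merged_prom
                if p.start < size
            ]
        rows.append(
            (
                gene_id,
                float(np.mean(exon_scores)),
                float(np.mean(intron_scores)) if intron_scores else float("nan"),
                fragment_score_set(track, merged_prom),
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "exon_score", "intron_score", "promoter_score"]
    ).set_index("gene_id")


def sample_intergenic(
    chrom_sizes: Mapping[str, int],
    models: Sequence[TranscriptModel],
    n: int,
    size_mean: int = INTERGENIC_SIZE_MEAN,
    size_jitter: float = INTERGENIC_SIZE_JITTER,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Random intergenic fragments, size uniform in mean*(1 +- jitter).

    Fragments are placed uniformly in the complement of gene spans and
    must not overlap any gene (fragments may overlap each other).
    Rejection sampling capped at 10*n attempts; failing that, an error
    reports the achieved count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_spans = merge_intervals([t.span() for t in models]) if models else []
    gaps = complement(gene_spans, dict(chrom_sizes))
    lo = int(round(size_mean * (1 - size_jitter)))
    hi = int(round(size_mean * (1 + size_jitter)))
    usable = [g for g in gaps if g.length >= lo]
    if not usable:
        raise ValueError("no intergenic gap can hold a fragment")
    weights = np.array([g.length for g in usable], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    attempts = 0
    while len(out) < n and attempts < 10 * n:
        attempts += 1
        gap = usable[rng.choice(len(usable), p=weights)]
        size = int(rng.integers(lo, hi + 1))
        if gap.length < size:
            continue
        start = int(rng.integers(gap.start, gap.end - size + 1))
        out.append(GenomicInterval(gap.chrom, start, start + size))
    if len(out) < n:
        raise RuntimeError(
            f"intergenic sampling exhausted {10 * n} attempts; "
            f"achieved {len(out)}/{n} fragments"
        )
    return out


def phylop_tss_max(
    track: ConservationTrack,
    models: Sequence[TranscriptModel],
    upstream: int = PHYLOP_UPSTREAM,
    downstream: int = PHYLOP_DOWNSTREAM,
) -> pd.Series:
    """Per-gene max per-base score over the TSS window, strand-aware.

    '+': [tss-upstream, tss+downstream); '-' mirrored. The gene value is
    the max over its transcripts; uncovered windows give NaN.
    """
    out = {}
    for gene_id, txs in group_by_gene(models).items():
        best = float("nan")
        for t in txs:
            if t.strand == "-":
                w_start, w_end = t.tss - downstream + 1, t.tss + upstream + 1
            else:
                w_start, w_end = t.tss - upstream, t.tss + downstream
            size = track.chrom_sizes.get(t.chrom)
            w_start = max(0, w_start)
            if size is not None:
                w_end = min(w_end, size)
            if w_end <= w_start:
                continue
            m = track.fragment_max(GenomicInterval(t.chrom, w_start, w_end, t.strand))
            if np.isnan(best) or (not np.isnan(m) and m > best):
                best = m
        out[gene_id] = best
    return pd.Series(out, name="phylop_tss_max")
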