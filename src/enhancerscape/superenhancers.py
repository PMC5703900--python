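"""ROSE-style super-enhancer calling.

Constituent enhancers within 12.5 kb of each other are stitched into one
locus; stitched loci are ranked by input-corrected per-million H3K27Ac
signal, and the slope-1 point of the scaled rank/signal curve separates
super-enhancers (SEs, above the cutoff) from the rest. Per condition a
region must be flagged SE in both replicates; the global SE list is the
union over conditions, and typical enhancers (TEs) are the CEs that do
not overlap it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chip import BinnedTrack
from .intervals import GenomicInterval, merge_intervals, overlaps_any

DEFAULT_STITCH_DISTANCE = 12_500

SE = "SE"
TE = "TE"
UNASSIGNED = "unassigned"


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituent_ids: list[int]
    signal: float = 0.0
    rank: int = 0
    klass: str = UNASSIGNED


def stitch(
    ces: Sequence[GenomicInterval],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
) -> list[StitchedEnhancer]:
    """Transitively merge consecutive CEs whose gap is <= stitch_distance.

    Input must be sorted and disjoint (the output of CE calling);
    constituent ids are indices into the input list.
    """
    for prev, nxt in zip(ces, list(ces)[1:]):
        if (nxt.chrom, nxt.start) < (prev.chrom, prev.start) or (
            nxt.chrom == prev.chrom and nxt.start < prev.end
        ):
            raise ValueError(
                "stitch() requires sorted, disjoint constituent enhancers; "
                "merge overlapping intervals first"
            )
    out: list[StitchedEnhancer] = []
    cur_ids: list[int] = []
    cur: GenomicInterval | None = None
    for i, ce in enumerate(ces):
        if cur is not None and ce.chrom == cur.chrom and ce.start - cur.end <= stitch_distance:
            cur = GenomicInterval(cur.chrom, cur.start, max(cur.end, ce.end))
            cur_ids.append(i)
        else:
            if cur is not None:
                out.append(StitchedEnhancer(cur, cur_ids))
            cur = GenomicInterval(ce.chrom, ce.start, ce.end)
            cur_ids = [i]
    if cur is not None:
        out.append(StitchedEnhancer(cur, cur_ids))
    return out


def region_count(track: BinnedTrack, region: GenomicInterval) -> float:
    """Total allocated counts in bins overlapping the region."""
    if region.chrom not in track.counts:
        raise ValueError(f"region chromosome {region.chrom} not in track")
    bs = track.bin_size
    b0 = region.start // bs
    b1 = (region.end - 1) // bs
    c = track.counts[region.chrom]
    if b1 >= len(c):
        raise ValueError(f"region {region} beyond track bounds")
    return float(c[b0 : b1 + 1].sum())


def score_region(
    sample: BinnedTrack,
    input_track: BinnedTrack,
    region: GenomicInterval,
    length_normalized: bool = False,
) -> float:
    """Input-corrected per-million read count over a region.

    signal = max(0, rpm_sample(region) - rpm_input(region)); the
    length-normalized variant divides by region length in kb (for
    signal-density comparisons between TE and SE constituents).
    """
    if region.length <= 0:
        raise ValueError("empty region")
    if sample.total_mapped == 0:
        return 0.0
    rpm_s = region_count(sample, region) / sample.total_mapped * 1e6
    rpm_i = (
        region_count(input_track, region) / input_track.total_mapped * 1e6
        if input_track.total_mapped > 0
        else 0.0
    )
    sig = max(0.0, rpm_s - rpm_i)
    if length_normalized:
        sig /= region.length / 1000.0
    return sig


def se_cutoff(signals: Sequence[float]) -> float:
    """Signal threshold at the slope-1 point of the ranked-signal curve.

    Signals are sorted ascending; ranks are scaled to [0, 1] by (N-1) and
    signals to [0, 1] by the maximum. The cutoff is the (unscaled) signal
    at the tangent point of a slope-1 line approached from below — the
    point minimizing y - x in scaled coordinates (last such index on
    ties). Regions strictly above the threshold are super-enhancers.
    Degenerate inputs (all equal, or max 0) give threshold = max, i.e.
    zero SEs.
    """
    s = np.asarray(signals, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 signals to place a cutoff")
    if np.any(s < 0):
        raise ValueError("negative signal")
    s = np.sort(s)
    smax = s[-1]
    if smax == 0 or s[0] == smax:
        return float(smax)
    x = np.arange(s.size) / (s.size - 1)
    y = s / smax
    d = y - x
    i_star = s.size - 1 - int(np.argmin(d[::-1]))  # last index attaining min
    return float(s[i_star])


def flag_se(signals: Sequence[float]) -> np.ndarray:
    """Boolean SE flags for a signal vector (strictly above the cutoff)."""
    s = np.asarray(signals, dtype=float)
    if s.size == 0:
        return np.zeros(0, dtype=bool)
    if s.size == 1:
        # a single stitched region gives no distribution to place a
        # cutoff on; conservatively not SE
        return np.zeros(1, dtype=bool)
    return s > se_cutoff(s)


@dataclass
class SeTeResult:
    global_se: list[GenomicInterval]
    te: list[GenomicInterval]
    per_condition_se: dict[str, list[GenomicInterval]]
    stitched: dict[str, list[StitchedEnhancer]]  # per condition, with class/rank
    rank_tables: dict[str, pd.DataFrame]  # per condition/replicate rank plots


def call_se_te(
    chip_tracks: Mapping[tuple[str, int], BinnedTrack],
    input_tracks: Mapping[str, BinnedTrack],
    per_condition_ces: Mapping[str, Sequence[GenomicInterval]],
    global_ces: Sequence[GenomicInterval],
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    replicates: Sequence[int] = (1, 2),
) -> SeTeResult:
    """Full SE/TE calling across conditions and replicates.

    Per condition, that condition's CEs are stitched once and scored in
    each replicate; a stitched region is SE for the condition iff flagged
    in both replicates. Global SE = merged union over conditions; TE =
    global CEs with zero SE overlap.
    """
    per_condition_se: dict[str, list[GenomicInterval]] = {}
    stitched_all: dict[str, list[StitchedEnhancer]] = {}
    rank_tables: dict[str, pd.DataFrame] = {}
    for cond, ces in per_condition_ces.items():
        for rep in replicates:
            if (cond, rep) not in chip_tracks:
                raise ValueError(f"missing replicate {rep} for condition {cond}")
        if cond not in input_tracks:
            raise ValueError(f"missing input track for condition {cond}")
        regions = stitch(ces, stitch_distance)
        stitched_all[cond] = regions
        if not regions:
            per_condition_se[cond] = []
            continue
        flags = np.ones(len(regions), dtype=bool)
        mean_sig = np.zeros(len(regions))
        for rep in replicates:
            sig = np.array(
                [
                    score_region(chip_tracks[(cond, rep)], input_tracks[cond], r.interval)
                    for r in regions
                ]
            )
            flags &= flag_se(sig)
            mean_sig += sig / len(replicates)
            order = np.argsort(sig)
            n = len(sig)
            rank_tables[f"{cond}_rep{rep}"] = pd.DataFrame(
                {
                    "rank": np.arange(1, n + 1),
                    "signal": sig[order],
                    "scaled_x": np.arange(n) / max(n - 1, 1),
                    "scaled_y": sig[order] / sig[order][-1] if sig[order][-1] > 0 else 0.0,
                    "is_se": flag_se(sig)[order],
                }
            )
        ranks = np.empty(len(regions), dtype=int)
        ranks[np.argsort(mean_sig)] = np.arange(1, len(regions) + 1)
        for i, r in enumerate(regions):
            r.signal = float(mean_sig[i])
            r.rank = int(ranks[i])
            r.klass = SE if flags[i] else UNASSIGNED
        per_condition_se[cond] = [r.interval for i, r in enumerate(regions) if flags[i]]
    global_se = merge_intervals(
        [iv for lst in per_condition_se.values() for iv in lst]
    )
    te = [ce for ce in global_ces if not overlaps_any(ce, global_se)]
    return SeTeResult(
        global_se=global_se,
        te=te,
        per_condition_se=per_condition_se,
        stitched=stitched_all,
        rank_tables=rank_tables,
    )


def activity_matrix(
    global_list: Sequence[GenomicInterval],
    per_condition_lists: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Boolean enhancer x condition matrix: active iff any-length overlap
    with the condition's own list."""
    idx = [str(iv) for iv in global_list]
    data = {
        cond: [overlaps_any(iv, lst) for iv in global_list]
        for cond, lst in per_condition_lists.items()
    }
    return pd.DataFrame(data, index=idx)
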