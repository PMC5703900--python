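"""Transcript filtering and the four-way epigenomic lncRNA classification.

Retained lncRNAs are classified, in precedence order, as promoter-
associated (H3K4me3 within +-1 kb of the TSS), SE-associated (any part of
the gene overlaps a super-enhancer), TE-associated (likewise vs typical
enhancers), or unmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_intervals, overlaps_any

PCG = "PCG"
ANNOT_LNC = "annotated_lnc"
NOVEL_LNC = "novel_lnc"
BIOTYPES = (PCG, ANNOT_LNC, NOVEL_LNC)

PLNCRNA = "plncRNA"
SE_LNCRNA = "SE_lncRNA"
TE_LNCRNA = "TE_lncRNA"
UNMARKED = "unmarked"
LNC_CLASSES = (PLNCRNA, SE_LNCRNA, TE_LNCRNA, UNMARKED)


@dataclass
class TranscriptModel:
    """A transcript: sorted disjoint exons on one chromosome/strand.

    ``coding_score`` is an externally computed protein-coding-potential
    score (GeneID-style); transcripts scoring above 4 are discarded as
    putative coding.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval]
    coding_score: float = 0.0

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span chrom/strand")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        """Mature (exonic) length."""
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def span(self) -> GenomicInterval:
        """Full gene-body span (exons + introns)."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def group_by_gene(models: Iterable[TranscriptModel]) -> dict[str, list[TranscriptModel]]:
    out: dict[str, list[TranscriptModel]] = {}
    for m in models:
        out.setdefault(m.gene_id, []).append(m)
    return out


# --- filters ------------------------------------------------------------

REJECT_LENGTH = "length"
REJECT_EXONS = "exons"
REJECT_CODING = "coding_score"
REJECT_EXPRESSION = "expression"


def filter_transcripts(
    models: Sequence[TranscriptModel],
    expression: pd.DataFrame | None,
    min_len: int = 200,
    min_exons: int = 2,
    max_coding_score: float = 4.0,
    min_fpkm: float = 0.1,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Apply the transcript retention filters; returns (retained, log).

    Novel lncRNAs must reach ``min_len`` mature bp and ``min_exons``
    exons; all lncRNAs must have coding score <= ``max_coding_score``
    (strictly greater is discarded); every transcript's gene must exceed
    ``min_fpkm`` mean FPKM in at least one condition (``expression`` is a
    gene x condition-mean table; a missing row counts as all-zero). The
    log records the first failed rule per rejected transcript.
    """
    retained: list[TranscriptModel] = []
    rows = []
    for m in models:
        reason = None
        if m.biotype == NOVEL_LNC and m.length < min_len:
            reason = REJECT_LENGTH
        elif m.biotype == NOVEL_LNC and m.n_exons < min_exons:
            reason = REJECT_EXONS
        elif m.biotype in (ANNOT_LNC, NOVEL_LNC) and m.coding_score > max_coding_score:
            reason = REJECT_CODING
        else:
            if expression is None or m.gene_id not in expression.index:
                expr_max = 0.0
            else:
                expr_max = float(expression.loc[m.gene_id].max())
            if not expr_max > min_fpkm:
                reason = REJECT_EXPRESSION
        if reason is None:
            retained.append(m)
        else:
            rows.append((m.transcript_id, m.gene_id, m.biotype, reason))
    log = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype", "reason"])
    return retained, log


# --- classification -----------------------------------------------------


def classify_lncrna(
    transcripts: Sequence[TranscriptModel],
    h3k4me3_regions: Sequence[GenomicInterval],
    se_list: Sequence[GenomicInterval],
    te_list: Sequence[GenomicInterval],
    promoter_halfwidth: int = 1000,
) -> str:
    """Classify one lncRNA gene from its transcripts.

    Precedence: promoter-associated (H3K4me3 overlapping any transcript's
    TSS +- ``promoter_halfwidth``) > SE-associated (any bp of the gene
    span overlaps an SE) > TE-associated > unmarked. A transcript
    qualifying at a higher-precedence rule sets the gene class.
    """
    if not transcripts:
        raise ValueError("gene has no transcripts")
    for t in transcripts:
        w_start = max(0, t.tss - promoter_halfwidth)
        window = GenomicInterval(t.chrom, w_start, t.tss + promoter_halfwidth + 1)
        if overlaps_any(window, h3k4me3_regions):
            return PLNCRNA
    for t in transcripts:
        if overlaps_any(t.span(), se_list):
            return SE_LNCRNA
    for t in transcripts:
        if overlaps_any(t.span(), te_list):
            return TE_LNCRNA
    return UNMARKED


def classify_all(
    models: Sequence[TranscriptModel],
    h3k4me3_regions: Sequence[GenomicInterval],
    se_list: Sequence[GenomicInterval],
    te_list: Sequence[GenomicInterval],
    promoter_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Class assignment per lncRNA gene (PCGs are passed through untouched).

    Returns a table (gene_id, biotype, lnc_class)."""
    rows = []
    for gene_id, txs in group_by_gene(models).items():
        biotype = txs[0].biotype
        if biotype == PCG:
            continue
        klass = classify_lncrna(
            txs, h3k4me3_regions, se_list, te_list, promoter_halfwidth
        )
        rows.append((gene_id, biotype, klass))
    return pd.DataFrame(rows, columns=["gene_id", "biotype", "lnc_class"])


def class_composition(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-biotype fractions over the four classes (rows sum to 1).

    Biotypes with zero genes get NaN fractions (not zeros)."""
    out = pd.DataFrame(
        index=[ANNOT_LNC, NOVEL_LNC], columns=list(LNC_CLASSES), dtype=float
    )
    for biotype in out.index:
        sub = assignments[assignments["biotype"] == biotype]
        if len(sub) == 0:
            continue
        counts = sub["lnc_class"].value_counts()
        for k in LNC_CLASSES:
            out.loc[biotype, k] = counts.get(k, 0) / len(sub)
    return out
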