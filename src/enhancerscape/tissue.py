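"""Tissue-panel preprocessing and heart-enrichment scoring.

A 12-tissue stranded, replicated count panel is strand-summed, replicate-
averaged, size-factor normalized, and expression-filtered. The Heart-
Enrichment score of a gene is

    HE = mu_cardiac / (mu_non-cardiac + 2 * sigma_non-cardiac)

with mu/sigma the mean and sample (n-1) standard deviation over the 11
non-cardiac tissues; HE > 1 (strict) defines a heart-enriched gene. The
same form applied with each tissue in the numerator gives per-tissue
enrichment scores, and enrichment ratios compare the percentage of
enriched genes between two gene sets.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_stats import size_factors

HEART = "heart"
MIN_PANEL_EXPRESSION = 0.1


def preprocess_panel(
    raw: pd.DataFrame,
    min_expression: float = MIN_PANEL_EXPRESSION,
    normalize: bool = True,
) -> pd.DataFrame:
    """Strand-sum, replicate-mean, size-factor normalize, filter.

    ``raw`` is a gene x sample matrix whose columns are a MultiIndex
    (tissue, replicate, strand) with two replicates and two strands per
    tissue. Genes below ``min_expression`` in every tissue are dropped
    (kept if >= the floor in at least one tissue).
    """
    if not isinstance(raw.columns, pd.MultiIndex) or raw.columns.nlevels != 3:
        raise ValueError("raw panel needs (tissue, replicate, strand) columns")
    tissues = raw.columns.get_level_values(0).unique()
    for t in tissues:
        sub = raw[t]
        reps = sub.columns.get_level_values(0).unique()
        if len(reps) != 2:
            raise ValueError(f"tissue {t!r}: expected 2 replicates, got {len(reps)}")
        for r in reps:
            if len(sub[r].columns) != 2:
                raise ValueError(f"tissue {t!r} replicate {r!r}: expected 2 strands")
    # strand sum, then replicate mean
    stranded = raw.T.groupby(level=[0, 1]).sum().T
    panel = stranded.T.groupby(level=0).mean().T
    panel = panel[list(tissues)]  # keep the input tissue order
    if normalize:
        sf = size_factors(panel)
        panel = panel / sf
    keep = (panel >= min_expression).any(axis=1)
    return panel.loc[keep]


def _enrichment_score(target: float, others: np.ndarray) -> float:
    mu = others.mean()
    sigma = others.std(ddof=1)
    denom = mu + 2.0 * sigma
    if denom == 0:
        return float("inf") if target > 0 else 0.0
    return float(target / denom)


def he_score(gene_row: pd.Series, heart_label: str = HEART) -> float:
    """Heart-Enrichment score of one gene row (index = tissue labels)."""
    if heart_label not in gene_row.index:
        raise KeyError(f"no {heart_label!r} column in panel")
    others = gene_row.drop(heart_label).to_numpy(dtype=float)
    if len(others) < 2:
        raise ValueError("need >=2 non-cardiac tissues")
    return _enrichment_score(float(gene_row[heart_label]), others)


def tissue_enrichment_scores(gene_row: pd.Series) -> pd.Series:
    """Per-tissue enrichment scores: value_t / (mean_{!=t} + 2*sd_{!=t})."""
    if len(gene_row) < 3:
        raise ValueError("need >=3 tissues")
    out = {}
    for t in gene_row.index:
        others = gene_row.drop(t).to_numpy(dtype=float)
        out[t] = _enrichment_score(float(gene_row[t]), others)
    return pd.Series(out, name=gene_row.name)


def he_table(panel: pd.DataFrame, heart_label: str = HEART) -> pd.DataFrame:
    """HE score and enriched flag for every gene in a preprocessed panel."""
    scores = panel.apply(he_score, axis=1, heart_label=heart_label)
    return pd.DataFrame({"he_score": scores, "enriched": scores > 1.0})


def tissue_score_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Gene x tissue matrix of per-tissue enrichment scores."""
    return panel.apply(tissue_enrichment_scores, axis=1)


def enrichment_ratio(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    panel: pd.DataFrame,
    tissue: str = HEART,
) -> float:
    """Ratio of enriched-gene percentages, set A over set B, for a tissue.

    Genes absent from the panel (filtered out) count toward the set size
    with score 0. NaN with a warning when set B has zero enriched genes.
    """
    if not len(genes_a) or not len(genes_b):
        raise ValueError("both gene sets must be nonempty")
    scores = tissue_score_table(panel)[tissue]

    def pct(genes: Sequence[str]) -> float:
        s = scores.reindex(list(genes)).fillna(0.0)
        return float((s > 1.0).mean() * 100.0)

    pa, pb = pct(genes_a), pct(genes_b)
    if pb == 0:
        warnings.warn(
            f"no {tissue}-enriched genes in the denominator set; ratio undefined",
            stacklevel=2,
        )
        return float("nan")
    return pa / pb


def enrichment_ratio_all_tissues(
    genes_a: Sequence[str], genes_b: Sequence[str], panel: pd.DataFrame
) -> pd.Series:
    """The per-tissue enrichment-ratio vector across the whole panel."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd.Series(
            {t: enrichment_ratio(genes_a, genes_b, panel, t) for t in panel.columns}
        )
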