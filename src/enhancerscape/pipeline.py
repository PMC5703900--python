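"""End-to-end synthetic pipeline orchestration.

Stages run in dependency order and communicate only through files in the
output directory, so any stage can be re-run alone (``only=...``) once
its inputs exist. Fixed seed => byte-identical output trees.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import chip, conservation, expression_stats, io, lncrna, superenhancers, tissue
from .config import PipelineConfig
from .synthetic import (
    CONDITIONS,
    PlantedTruth,
    SyntheticConfig,
    generate_genome_and_transcripts,
    simulate_chip_reads,
    simulate_conservation,
    simulate_expression,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "enrich",
    "superenhancers",
    "classify",
    "specificity",
    "tissue",
    "conserve",
)


class MissingStageError(RuntimeError):
    pass


def _require(outdir: Path, relpath: str, needed_by: str, produced_by: str) -> Path:
    p = outdir / relpath
    if not p.exists():
        raise MissingStageError(
            f"stage '{needed_by}' needs {relpath}, produced by stage "
            f"'{produced_by}'; run that stage first"
        )
    return p


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sc = cfg.synthetic
    chrom_sizes, models, truth = generate_genome_and_transcripts(sc)
    io.write_json({"chrom_sizes": chrom_sizes}, outdir / "genome.json")
    io.write_gtf(models, outdir / "transcripts.gtf")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for mark in ("H3K27Ac", "H3K4me3", "input"):
        for cond in CONDITIONS:
            for rep in (1, 2):
                df = simulate_chip_reads(sc, truth, mark, cond, rep)
                safe = cond.replace("+", "pos").replace("-", "neg")
                io.write_bed(df, reads_dir / f"{mark}_{safe}_rep{rep}.bed")
    fpkm, panel = simulate_expression(sc, truth, models)
    io.write_tsv(fpkm, outdir / "fpkm.tsv")
    flat = panel.copy()
    flat.columns = [f"{t}|{r}|{s}" for t, r, s in panel.columns]
    io.write_tsv(flat, outdir / "tissue_counts.tsv")
    track = simulate_conservation(sc, truth, models)
    io.write_tsv(track.to_dataframe(), outdir / "conservation.tsv", index=False)


def _load_reads(outdir: Path, mark: str, cond: str, rep: int) -> pd.DataFrame:
    safe = cond.replace("+", "pos").replace("-", "neg")
    return io.read_bed(outdir / "reads" / f"{mark}_{safe}_rep{rep}.bed")


def _binned_tracks(cfg: PipelineConfig, outdir: Path, mark: str):
    chrom_sizes = json.loads((outdir / "genome.json").read_text())["chrom_sizes"]
    tracks = {}
    for cond in CONDITIONS:
        for rep in (1, 2):
            reads = _load_reads(outdir, mark, cond, rep)
            tracks[(cond, rep)] = chip.bin_reads(
                reads, chrom_sizes, cfg.bin_size, cfg.extension
            )
    return tracks


def _pooled_inputs(cfg: PipelineConfig, outdir: Path):
    inputs = _binned_tracks(cfg, outdir, "input")
    return {c: inputs[(c, 1)].add(inputs[(c, 2)]) for c in CONDITIONS}


def _enriched_regions(cfg, tracks, pooled_input, mark: str):
    """Per-condition replicate-intersected masks for one mark."""
    masks = {}
    for cond in CONDITIONS:
        reps = []
        for rep in (1, 2):
            reps.append(
                chip.poisson_enriched_bins(
                    tracks[(cond, rep)],
                    pooled_input[cond],
                    cfg.p_threshold,
                    cfg.min_fold,
                    cfg.local_lambda,
                    provenance=(mark, cond, str(rep)),
                )
            )
        masks[cond] = chip.intersect_replicates(*reps)
    return masks


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "genome.json", "enrich", "simulate")
    _require(outdir, "reads", "enrich", "simulate")
    pooled_input = _pooled_inputs(cfg, outdir)
    k27 = _binned_tracks(cfg, outdir, "H3K27Ac")
    k27_masks = _enriched_regions(cfg, k27, pooled_input, "H3K27Ac")
    ces = chip.call_constituent_enhancers(k27_masks, cfg.min_ce_length)
    io.write_bed(ces, outdir / "constituent_enhancers.bed")
    for cond in CONDITIONS:
        runs = chip.mask_to_intervals(k27_masks[cond])
        kept = [iv for iv in runs if iv.length >= cfg.min_ce_length]
        safe = cond.replace("+", "pos").replace("-", "neg")
        io.write_bed(kept, outdir / f"ce_{safe}.bed")
    k4 = _binned_tracks(cfg, outdir, "H3K4me3")
    k4_masks = _enriched_regions(cfg, k4, pooled_input, "H3K4me3")
    k4_regions = chip.call_constituent_enhancers(k4_masks, min_length=cfg.bin_size)
    io.write_bed(k4_regions, outdir / "h3k4me3_positive.bed")


def _stage_superenhancers(cfg: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "constituent_enhancers.bed", "superenhancers", "enrich")
    pooled_input = _pooled_inputs(cfg, outdir)
    k27 = _binned_tracks(cfg, outdir, "H3K27Ac")
    per_cond_ces = {}
    for cond in CONDITIONS:
        safe = cond.replace("+", "pos").replace("-", "neg")
        df = io.read_bed(_require(outdir, f"ce_{safe}.bed", "superenhancers", "enrich"))
        per_cond_ces[cond] = io.bed_to_intervals(df)
    global_ces = io.bed_to_intervals(io.read_bed(outdir / "constituent_enhancers.bed"))
    result = superenhancers.call_se_te(
        k27, pooled_input, per_cond_ces, global_ces, cfg.stitch_distance
    )
    io.write_bed(result.global_se, outdir / "superenhancers.bed")
    io.write_bed(result.te, outdir / "typical_enhancers.bed")
    for cond, lst in result.per_condition_se.items():
        safe = cond.replace("+", "pos").replace("-", "neg")
        io.write_bed(lst, outdir / f"se_{safe}.bed")
    amat = superenhancers.activity_matrix(result.global_se, result.per_condition_se)
    io.write_tsv(amat, outdir / "se_activity_matrix.tsv")
    for name, table in sorted(result.rank_tables.items()):
        safe = name.replace("+", "pos").replace("-", "neg")
        io.write_tsv(table, outdir / f"rank_{safe}.tsv", index=False)


def _retained_models(cfg: PipelineConfig, outdir: Path, needed_by: str):
    models = io.read_gtf(_require(outdir, "transcripts.gtf", needed_by, "simulate"))
    models.sort(key=lambda m: m.transcript_id)
    fpkm = io.read_tsv(_require(outdir, "fpkm.tsv", needed_by, "simulate"))
    cond_of = {c: c.rsplit("_", 1)[0] for c in fpkm.columns}
    means = expression_stats.collapse_replicates(fpkm, cond_of)
    retained, log = lncrna.filter_transcripts(
        models, means, cfg.min_transcript_length, cfg.min_exons,
        cfg.max_coding_score, cfg.min_fpkm,
    )
    return retained, log, means


def _stage_classify(cfg: PipelineConfig, outdir: Path) -> None:
    retained, log, _ = _retained_models(cfg, outdir, "classify")
    io.write_tsv(log, outdir / "filter_rejections.tsv", index=False)
    k4 = io.bed_to_intervals(
        io.read_bed(_require(outdir, "h3k4me3_positive.bed", "classify", "enrich"))
    )
    se = io.bed_to_intervals(
        io.read_bed(_require(outdir, "superenhancers.bed", "classify", "superenhancers"))
    )
    te = io.bed_to_intervals(
        io.read_bed(_require(outdir, "typical_enhancers.bed", "classify", "superenhancers"))
    )
    assignments = lncrna.classify_all(retained, k4, se, te, cfg.promoter_halfwidth)
    io.write_tsv(assignments, outdir / "lncrna_classes.tsv", index=False)
    io.write_tsv(lncrna.class_composition(assignments), outdir / "class_composition.tsv")


def _stage_specificity(cfg: PipelineConfig, outdir: Path) -> None:
    retained, _, means = _retained_models(cfg, outdir, "specificity")
    retained_genes = sorted({m.gene_id for m in retained})
    means = means.loc[means.index.intersection(retained_genes)]
    nd = expression_stats.nd_table(means)
    biotype = {m.gene_id: m.biotype for m in retained}
    table = pd.DataFrame(
        {"ND": nd, "biotype": [biotype[g] for g in means.index]}, index=means.index
    )
    io.write_tsv(table, outdir / "nd_table.tsv")
    groups = {
        bt: table.loc[table["biotype"] == bt, "ND"].dropna().to_numpy()
        for bt in (lncrna.PCG, lncrna.ANNOT_LNC, lncrna.NOVEL_LNC)
    }
    comparisons = {}
    for a, b in (("annotated_lnc", "PCG"), ("novel_lnc", "PCG")):
        if len(groups[a]) and len(groups[b]):
            res = expression_stats.compare_nd_distributions(groups[a], groups[b], "greater")
            comparisons[f"{a}_gt_{b}"] = {"p": res.p_value, "method": res.method}
    io.write_json(comparisons, outdir / "nd_comparisons.json")
    fpkm = io.read_tsv(outdir / "fpkm.tsv")
    de = expression_stats.welch_de(
        fpkm, [c for c in fpkm.columns if c.startswith("Eo+")],
        [c for c in fpkm.columns if c.startswith("Eo-")],
        cfg.pseudocount,
    )
    io.write_tsv(de, outdir / "welch_de_EoPos_vs_EoNeg.tsv")
    for a, b, name in (("Eo+", "Eo-", "eo_pos"), (("Eo-"), ("Eo+"), "eo_neg")):
        genes = expression_stats.enriched_set(
            means, a, b, cfg.fold_change, cfg.pseudocount
        )
        io.write_json(sorted(genes), outdir / f"enriched_{name}.json")


def _stage_tissue(cfg: PipelineConfig, outdir: Path) -> None:
    flat = io.read_tsv(_require(outdir, "tissue_counts.tsv", "tissue", "simulate"))
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split("|")) for c in flat.columns], names=["tissue", "replicate", "strand"]
    )
    raw = flat.copy()
    raw.columns = cols
    panel = tissue.preprocess_panel(raw, cfg.min_fpkm)
    io.write_tsv(panel, outdir / "tissue_panel.tsv")
    he = tissue.he_table(panel)
    io.write_tsv(he, outdir / "he_scores.tsv")
    pos = json.loads(_require(outdir, "enriched_eo_pos.json", "tissue", "specificity").read_text())
    neg = json.loads(_require(outdir, "enriched_eo_neg.json", "tissue", "specificity").read_text())
    if pos and neg:
        ratios = tissue.enrichment_ratio_all_tissues(pos, neg, panel)
        io.write_tsv(ratios.to_frame("enrichment_ratio"), outdir / "tissue_enrichment_ratios.tsv")


def _stage_conserve(cfg: PipelineConfig, outdir: Path) -> None:
    models = io.read_gtf(_require(outdir, "transcripts.gtf", "conserve", "simulate"))
    models.sort(key=lambda m: m.transcript_id)
    chrom_sizes = json.loads(
        _require(outdir, "genome.json", "conserve", "simulate").read_text()
    )["chrom_sizes"]
    df = pd.read_csv(_require(outdir, "conservation.tsv", "conserve", "simulate"), sep="\t")
    track = conservation.ConservationTrack.from_dataframe(df, chrom_sizes)
    scores = conservation.feature_scores(track, models, cfg.phastcons_promoter)
    io.write_tsv(scores, outdir / "conservation_scores.tsv")
    intergenic = conservation.sample_intergenic(
        chrom_sizes, models, cfg.n_intergenic, cfg.intergenic_size_mean,
        cfg.intergenic_size_jitter, seed=cfg.synthetic.seed,
    )
    io.write_bed(intergenic, outdir / "intergenic_background.bed")
    bg = np.array([conservation.fragment_score(track, iv) for iv in intergenic])
    res = expression_stats.compare_nd_distributions(
        scores["promoter_score"].dropna().to_numpy(), bg, "greater"
    )
    phylo = conservation.phylop_tss_max(
        track, models, cfg.phylop_upstream, cfg.phylop_downstream
    )
    io.write_tsv(phylo.to_frame(), outdir / "phylop_tss_max.tsv")
    io.write_json(
        {"promoter_vs_intergenic_p": res.p_value, "method": res.method},
        outdir / "conservation_summary.json",
    )


_STAGE_FN = {
    "simulate": _stage_simulate,
    "enrich": _stage_enrich,
    "superenhancers": _stage_superenhancers,
    "classify": _stage_classify,
    "specificity": _stage_specificity,
    "tissue": _stage_tissue,
    "conserve": _stage_conserve,
}


def run_pipeline(
    config: PipelineConfig,
    outdir,
    only: Sequence[str] | None = None,
) -> Path:
    """Run the synthetic pipeline (or a subset of stages) into ``outdir``.

    The resolved configuration is written next to the outputs. Raises
    MissingStageError when ``only`` skips a stage whose outputs are
    needed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if only is None else list(only)
    for s in stages:
        if s not in _STAGE_FN:
            raise ValueError(f"unknown stage {s!r}; stages are {STAGES}")
    config.to_yaml(outdir / "config_resolved.yaml")
    import warnings

    for s in STAGES:
        if s in stages:
            logger.info("running stage %s", s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _STAGE_FN[s](config, outdir)
    return outdir
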