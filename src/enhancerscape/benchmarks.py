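"""Planted-truth recovery studies.

Each function runs one self-contained simulation study — planting known
features with the synthetic generator, running the corresponding caller
or statistic, and measuring recovery. They back both the validation
suite and the reproduction script.
"""

from __future__ import annotations

import filecmp
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import chip, conservation, superenhancers, tissue
from .expression_stats import compare_nd_distributions
from .intervals import GenomicInterval, overlaps_any
from .synthetic import (
    CONDITIONS,
    PlantedTruth,
    SyntheticConfig,
    TissuePlan,
    _rng,
    generate_genome_and_transcripts,
    make_enhancer_plan,
    simulate_chip_reads,
    simulate_conservation,
    simulate_tissue_panel,
)


def _bare_config(seed: int, chrom_sizes: dict[str, int],
                 reads: int) -> SyntheticConfig:
    """A gene-free config (ChIP benchmarks plant only enhancers)."""
    return SyntheticConfig(
        seed=seed, chrom_sizes=chrom_sizes, reads_per_replicate=reads,
        n_pcg=0, n_annot_lnc=0, n_novel_lnc=0, n_single_exon_decoys=0,
        n_short_decoys=0, n_coding_decoys=0, n_enhancer_lnc=0,
    )


def _esc_ce_pipeline(cfg: SyntheticConfig, truth: PlantedTruth):
    """Reads -> binned tracks -> replicate-intersected mask -> CEs (ESC)."""
    tracks = {
        ("ESC", rep): chip.bin_reads(
            simulate_chip_reads(cfg, truth, "H3K27Ac", "ESC", rep),
            cfg.chrom_sizes,
        )
        for rep in (1, 2)
    }
    pooled_input = chip.bin_reads(
        simulate_chip_reads(cfg, truth, "input", "ESC", 1), cfg.chrom_sizes
    ).add(
        chip.bin_reads(
            simulate_chip_reads(cfg, truth, "input", "ESC", 2), cfg.chrom_sizes
        )
    )
    masks = [
        chip.poisson_enriched_bins(tracks[("ESC", rep)], pooled_input,
                                   provenance=("H3K27Ac", "ESC", str(rep)))
        for rep in (1, 2)
    ]
    esc_mask = chip.intersect_replicates(*masks)
    ces = chip.call_constituent_enhancers({"ESC": esc_mask})
    return tracks, pooled_input, ces


def planted_enhancer_recovery(
    seed: int,
    chrom_mb: int = 5,
    n_isolated: int = 35,
    n_clusters: int = 5,
    fold: float = 20.0,
    reads_per_replicate: int = 1_000_000,
) -> dict:
    """Plant 50 constituents (5 SE clusters of 3 + 35 isolated) at 20x
    background on a 2 x 5-Mb genome and measure CE/SE recovery.

    Also runs the identical calling chain on a background-only genome
    (no planted sites) and counts the super-enhancers called there.
    """
    sizes = {"chr1": chrom_mb * 1_000_000, "chr2": chrom_mb * 1_000_000}
    plan = make_enhancer_plan(
        sizes, seed, n_isolated=n_isolated, n_clusters=n_clusters, fold=fold
    )
    for site in plan:  # every site active in every condition
        site.active_conditions = CONDITIONS
    cfg = _bare_config(seed, sizes, reads_per_replicate)
    cfg.enhancer_plan = plan
    truth = PlantedTruth(enhancers=plan)

    tracks, pooled_input, ces = _esc_ce_pipeline(cfg, truth)
    recovered = sum(overlaps_any(s.interval, ces) for s in truth.enhancers)

    res = superenhancers.call_se_te(
        tracks, {"ESC": pooled_input}, {"ESC": ces}, ces, replicates=(1, 2)
    )
    clusters = truth.se_clusters()
    clusters_as_se = sum(
        any(overlaps_any(s.interval, res.global_se) for s in sites)
        for sites in clusters.values()
    )
    isolated_as_te = sum(
        overlaps_any(s.interval, res.te) for s in truth.isolated_sites()
    )

    # called-CE precision vs planted sites + their 200-bp extension shadow
    shadow = [
        GenomicInterval(s.chrom, max(0, s.start - 200), s.start + s.width + 200)
        for s in truth.enhancers
    ]
    from .intervals import covered_fraction

    precision = covered_fraction(ces, shadow) if ces else float("nan")

    # background-only control through the same chain
    ctrl = _bare_config(seed + 1, sizes, reads_per_replicate)
    ctrl_truth = PlantedTruth()
    ctrl_tracks, ctrl_input, ctrl_ces = _esc_ce_pipeline(ctrl, ctrl_truth)
    ctrl_res = superenhancers.call_se_te(
        ctrl_tracks, {"ESC": ctrl_input}, {"ESC": ctrl_ces}, ctrl_ces,
        replicates=(1, 2),
    )
    return {
        "n_planted": len(truth.enhancers),
        "n_ces": len(ces),
        "recovered": int(recovered),
        "recovery_fraction": recovered / len(truth.enhancers),
        "ce_precision": float(precision),
        "n_clusters": len(clusters),
        "clusters_called_se": int(clusters_as_se),
        "isolated_called_te": int(isolated_as_te),
        "control_se_count": len(ctrl_res.global_se),
        "control_ce_count": len(ctrl_ces),
    }


def cutoff_separation_trials(
    n_trials: int = 100,
    n_background: int = 200,
    n_planted: int = 10,
    planted_fold: float = 50.0,
    sigma: float = 0.25,
    seed: int = 0,
) -> dict:
    """LogNormal background signals + planted outliers at ``planted_fold``
    x the background median: count trials where every planted signal
    clears the slope-1 cutoff."""
    wins = 0
    for t in range(n_trials):
        rng = np.random.default_rng([seed, t])
        bg = rng.lognormal(0.0, sigma, size=n_background)
        planted = np.full(n_planted, planted_fold * float(np.median(bg)))
        thr = superenhancers.se_cutoff(np.concatenate([bg, planted]))
        wins += bool((planted > thr).all())
    return {"n_trials": n_trials, "all_planted_above_cutoff": wins,
            "success_fraction": wins / n_trials}


def heart_enrichment_recovery(
    seed: int,
    n_genes: int = 1_000,
    n_planted: int = 100,
    effect_fold: float = 8.0,
    cv: float = 0.2,
    n_seeds: int = 20,
) -> dict:
    """Plant heart-enriched genes in a noisy 12-tissue panel and measure
    sensitivity and false-positive rate of the HE > 1 rule."""
    tp = fp = fn = tn = 0
    plan = TissuePlan(n_heart_genes=n_planted, effect_fold=effect_fold, cv=cv)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    for s in range(n_seeds):
        rng = _rng(seed, 20, s)
        planted = set(
            genes[i] for i in rng.choice(n_genes, size=n_planted, replace=False)
        )
        raw = simulate_tissue_panel(plan, genes, planted, rng)
        panel = tissue.preprocess_panel(raw)
        he = tissue.he_table(panel)
        for g in genes:
            enriched = bool(he.loc[g, "enriched"]) if g in he.index else False
            if g in planted:
                tp += enriched
                fn += not enriched
            else:
                fp += enriched
                tn += not enriched
    return {
        "n_seeds": n_seeds,
        "sensitivity": tp / (tp + fn),
        "false_positive_rate": fp / (fp + tn),
    }


def promoter_conservation_recovery(
    seed: int,
    n_genes: int = 200,
    delta: float = 0.3,
    n_intergenic: int = 1_000,
) -> dict:
    """Plant promoter conservation elevation for ``n_genes`` genes and
    test promoters vs random intergenic fragments (one-tail Wilcoxon)."""
    cfg = SyntheticConfig(
        seed=seed,
        chrom_sizes={"chr1": 8_000_000, "chr2": 6_000_000},
        n_pcg=n_genes, n_annot_lnc=0, n_novel_lnc=0,
        n_single_exon_decoys=0, n_short_decoys=0, n_coding_decoys=0,
        n_enhancer_lnc=0,
    )
    cfg.expression.n_specific_per_condition = 0
    cfg.tissue_plan.n_heart_genes = 0
    cfg.conservation_plan.n_conserved_genes = n_genes
    cfg.conservation_plan.promoter_delta = delta
    sizes, models, truth = generate_genome_and_transcripts(cfg)
    track = simulate_conservation(cfg, truth, models)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = conservation.feature_scores(track, models)
        frags = conservation.sample_intergenic(
            sizes, models, n_intergenic, seed=_rng(seed, 21)
        )
        bg = np.array([conservation.fragment_score(track, iv) for iv in frags])
    lengths_ok = all(2_720 <= iv.length <= 4_080 for iv in frags)
    spans = [m.span() for m in models]
    overlap_free = not any(overlaps_any(iv, spans) for iv in frags)
    res = compare_nd_distributions(
        scores["promoter_score"].dropna().to_numpy(), bg, "greater"
    )
    return {
        "n_promoters": int(scores["promoter_score"].notna().sum()),
        "n_intergenic": len(frags),
        "wilcoxon_p": res.p_value,
        "lengths_in_band": bool(lengths_ok),
        "zero_gene_overlap": bool(overlap_free),
    }


def pipeline_determinism(seed: int, outdir) -> dict:
    """Run the full synthetic pipeline twice at one seed and compare
    every output file byte for byte."""
    from .config import PipelineConfig
    from .pipeline import run_pipeline
    from .synthetic import default_config

    outdir = Path(outdir)
    runs = []
    for tag in ("a", "b"):
        cfg = PipelineConfig(synthetic=default_config(seed))
        runs.append(run_pipeline(cfg, outdir / tag))
    files_a = sorted(p.relative_to(runs[0]) for p in runs[0].rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(runs[1]) for p in runs[1].rglob("*") if p.is_file())
    identical = files_a == files_b and all(
        filecmp.cmp(runs[0] / f, runs[1] / f, shallow=False) for f in files_a
    )
    return {"n_files": len(files_a), "byte_identical": bool(identical)}
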