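"""Seeded synthetic data with recorded planted truth.

Generates a toy genome with transcript models, piecewise-constant-
intensity ChIP read sets (H3K27Ac at planted enhancers, H3K4me3 at
planted promoters, background-only input), FPKM matrices with planted
condition-specific genes, a 12-tissue stranded count panel with planted
heart-enriched genes, and conservation tracks with planted promoter
elevation. Everything downstream of read alignment is exercised against
this truth without any downloads.

All randomness flows from one seed through named sub-streams keyed by
(purpose, mark, condition, replicate), so adding one track never
perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals
from .lncrna import ANNOT_LNC, NOVEL_LNC, PCG, TranscriptModel

CONDITIONS = ("ESC", "Eo-", "Eo+")
MARKS = ("H3K27Ac", "H3K4me3", "input")
TISSUES = (
    "thymus", "liver", "stomach", "colon", "ovary", "spleen", "heart",
    "kidney", "mammary", "frontal_lobe", "cortex", "cerebellum",
)
READ_LENGTH = 50  # single-end; fragment extension happens downstream

_MARK_CODE = {m: i + 1 for i, m in enumerate(MARKS)}
_COND_CODE = {c: i + 1 for i, c in enumerate(CONDITIONS)}

DECOY_SINGLE_EXON = "single_exon"
DECOY_SHORT = "short"
DECOY_CODING = "coding_score"


def _rng(seed: int, *codes: int) -> np.random.Generator:
    """Named sub-stream of the master seed."""
    return np.random.default_rng([int(seed)] + [int(c) for c in codes])


@dataclass
class PlantedSite:
    """One planted constituent enhancer (H3K27Ac intensity multiplier)."""

    chrom: str
    start: int
    width: int
    fold: float
    active_conditions: tuple[str, ...] = CONDITIONS
    se_cluster_id: int | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.start + self.width)


@dataclass
class TissuePlan:
    n_heart_genes: int = 50
    effect_fold: float = 8.0
    base_mean: float = 5.0
    cv: float = 0.2
    n_replicates: int = 2


@dataclass
class ConservationPlan:
    n_conserved_genes: int = 50
    promoter_delta: float = 0.3
    background_mean: float = 0.1
    background_sd: float = 0.05
    window: int = 100  # bp resolution of the generated track


@dataclass
class ExpressionPlan:
    n_specific_per_condition: int = 8
    specific_mean: float = 50.0
    base_mean: float = 5.0
    off_mean: float = 0.0
    cv: float = 0.2
    n_replicates: int = 4


@dataclass
class SyntheticConfig:
    """All knobs of the generator; one seed drives everything."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_200_000, "chr2": 800_000}
    )
    n_pcg: int = 30
    n_annot_lnc: int = 15
    n_novel_lnc: int = 15
    n_single_exon_decoys: int = 3
    n_short_decoys: int = 2
    n_coding_decoys: int = 2
    n_enhancer_lnc: int = 6  # novel lncRNAs deliberately overlapping planted sites
    enhancer_plan: list[PlantedSite] = field(default_factory=list)
    background_rate: float = 0.01  # relative background intensity, reads/bp
    reads_per_replicate: int = 200_000
    promoter_fold: float = 20.0  # H3K4me3 intensity fold at planted promoters
    promoter_halfwidth: int = 1000
    lnc_promoter_fraction: float = 0.3  # lncRNA genes given an H3K4me3 promoter
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    tissue_plan: TissuePlan = field(default_factory=TissuePlan)
    conservation_plan: ConservationPlan = field(default_factory=ConservationPlan)

    def validate(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be nonempty")
        for n in (self.n_pcg, self.n_annot_lnc, self.n_novel_lnc):
            if n < 0:
                raise ValueError("gene counts must be >= 0")
        for site in self.enhancer_plan:
            if site.chrom not in self.chrom_sizes:
                raise ValueError(
                    f"planted site on unknown chromosome: {site.chrom}:{site.start}"
                )
            if site.start < 0 or site.start + site.width > self.chrom_sizes[site.chrom]:
                raise ValueError(
                    f"planted site outside chromosome: "
                    f"{site.chrom}:{site.start}-{site.start + site.width}"
                )
            if site.fold <= 1:
                raise ValueError(
                    f"planted fold must be > 1 at {site.chrom}:{site.start}"
                )
            for c in site.active_conditions:
                if c not in CONDITIONS:
                    raise ValueError(f"unknown condition {c!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        d["enhancer_plan"] = [PlantedSite(**s) for s in d.get("enhancer_plan", [])]
        for key, klass in (
            ("expression", ExpressionPlan),
            ("tissue_plan", TissuePlan),
            ("conservation_plan", ConservationPlan),
        ):
            if key in d and isinstance(d[key], Mapping):
                d[key] = klass(**d[key])
        cfg = cls(**d)
        for site in cfg.enhancer_plan:
            site.active_conditions = tuple(site.active_conditions)
        return cfg


def make_enhancer_plan(
    chrom_sizes: Mapping[str, int],
    seed: int,
    n_isolated: int = 20,
    n_clusters: int = 3,
    cluster_size: int = 3,
    width: int = 500,
    cluster_width: int = 600,
    fold: float = 20.0,
    spacing: int = 30_000,
    offset: int = 20_000,
) -> list[PlantedSite]:
    """Deterministic planted-enhancer layout on a slot grid.

    Isolated sites become typical enhancers; each cluster plants
    ``cluster_size`` constituents within 12.5 kb (stitching is exercised
    by construction). Activity patterns cycle through all-active and
    single-condition-specific sets.
    """
    rng = _rng(seed, 11)
    chroms = sorted(chrom_sizes)
    slots: list[tuple[str, int]] = []
    for chrom in chroms:
        pos = offset
        while pos + spacing < chrom_sizes[chrom]:
            slots.append((chrom, pos))
            pos += spacing
    need = n_isolated + n_clusters
    if need > len(slots):
        raise ValueError(f"genome too small: {need} slots needed, {len(slots)} available")
    chosen = sorted(rng.choice(len(slots), size=need, replace=False))
    patterns = [CONDITIONS, ("ESC",), ("Eo-",), ("Eo+",), CONDITIONS]
    plan: list[PlantedSite] = []
    for k, slot_idx in enumerate(chosen):
        chrom, pos = slots[slot_idx]
        pattern = tuple(patterns[k % len(patterns)])
        if k < n_clusters:
            gap = 4000  # constituent gaps well inside the 12.5-kb stitch range
            for j in range(cluster_size):
                plan.append(
                    PlantedSite(
                        chrom, pos + j * (cluster_width + gap), cluster_width,
                        fold, pattern, se_cluster_id=k,
                    )
                )
        else:
            plan.append(PlantedSite(chrom, pos, width, fold, pattern, None))
    return sorted(plan, key=lambda s: (s.chrom, s.start))


def default_config(seed: int = 0) -> SyntheticConfig:
    """A coherent small study: 12 isolated sites + 3 SE clusters on a
    2-Mb toy genome, with decoy lncRNAs and all planted panels."""
    cfg = SyntheticConfig(seed=seed)
    cfg.enhancer_plan = make_enhancer_plan(
        cfg.chrom_sizes, seed, n_isolated=12, n_clusters=3
    )
    return cfg


@dataclass
class PlantedTruth:
    """Recorded ground truth for every planted feature."""

    enhancers: list[PlantedSite] = field(default_factory=list)
    promoters: list[GenomicInterval] = field(default_factory=list)
    specific_genes: dict[str, list[str]] = field(default_factory=dict)
    heart_enriched: list[str] = field(default_factory=list)
    conserved_promoters: list[str] = field(default_factory=list)
    decoys: dict[str, list[str]] = field(default_factory=dict)

    def se_clusters(self) -> dict[int, list[PlantedSite]]:
        out: dict[int, list[PlantedSite]] = {}
        for s in self.enhancers:
            if s.se_cluster_id is not None:
                out.setdefault(s.se_cluster_id, []).append(s)
        return out

    def isolated_sites(self) -> list[PlantedSite]:
        return [s for s in self.enhancers if s.se_cluster_id is None]

    def to_json(self) -> str:
        d = {
            "enhancers": [asdict(s) for s in self.enhancers],
            "promoters": [
                {"chrom": p.chrom, "start": p.start, "end": p.end, "strand": p.strand}
                for p in self.promoters
            ],
            "specific_genes": self.specific_genes,
            "heart_enriched": self.heart_enriched,
            "conserved_promoters": self.conserved_promoters,
            "decoys": self.decoys,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        enh = []
        for s in d["enhancers"]:
            s = dict(s)
            s["active_conditions"] = tuple(s["active_conditions"])
            enh.append(PlantedSite(**s))
        return cls(
            enhancers=enh,
            promoters=[GenomicInterval(**p) for p in d["promoters"]],
            specific_genes=d["specific_genes"],
            heart_enriched=d["heart_enriched"],
            conserved_promoters=d["conserved_promoters"],
            decoys=d["decoys"],
        )


# --- genome & transcripts ----------------------------------------------


def _make_exons(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    n_exons: int,
    exon_range: tuple[int, int],
    intron_range: tuple[int, int],
) -> list[GenomicInterval]:
    exons = []
    pos = start
    for i in range(n_exons):
        elen = int(rng.integers(*exon_range))
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen + int(rng.integers(*intron_range))
    return exons


def generate_genome_and_transcripts(
    config: SyntheticConfig,
) -> tuple[dict[str, int], list[TranscriptModel], PlantedTruth]:
    """Lay out non-overlapping gene loci away from planted enhancers.

    Novel lncRNAs deliberately include single-exon, sub-200-bp, and
    coding-score>4 decoys (counts from the config) so every retention
    filter is exercised; the truth records which transcript fails which
    filter. Promoter (H3K4me3) sites cover TSS windows of all PCGs and a
    seeded fraction of lncRNA genes.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    margin = 2 * config.promoter_halfwidth
    enhancer_margins: list[GenomicInterval] = [
        GenomicInterval(s.chrom, max(0, s.start - margin),
                        s.start + s.width + margin)
        for s in config.enhancer_plan
    ]
    gene_occupied: list[GenomicInterval] = []

    chroms = sorted(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()

    def place(span_len: int) -> tuple[str, int]:
        for _ in range(2000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            size = config.chrom_sizes[chrom]
            if size <= span_len + 2 * margin:
                continue
            start = int(rng.integers(margin, size - span_len - margin))
            cand = GenomicInterval(chrom, start - margin, start + span_len + margin)
            if not any(cand.overlaps(o) for o in gene_occupied + enhancer_margins):
                gene_occupied.append(cand)
                return chrom, start
        raise RuntimeError("could not place gene; genome too crowded")

    def place_on_site(span_len: int, site: PlantedSite) -> tuple[str, int] | None:
        """Start the gene inside a planted site so an exon overlaps it."""
        start = site.start + min(100, max(0, site.width - 1))
        size = config.chrom_sizes[site.chrom]
        if start + span_len + margin >= size:
            return None
        cand = GenomicInterval(site.chrom, max(0, start - margin),
                               start + span_len + margin)
        if any(cand.overlaps(o) for o in gene_occupied):
            return None
        gene_occupied.append(cand)
        return site.chrom, start

    models: list[TranscriptModel] = []
    truth = PlantedTruth(enhancers=list(config.enhancer_plan))
    truth.decoys = {DECOY_SINGLE_EXON: [], DECOY_SHORT: [], DECOY_CODING: []}

    specs: list[tuple[str, str, str | None, bool]] = []
    specs += [(PCG, f"PCG{i:04d}", None, False) for i in range(config.n_pcg)]
    specs += [(ANNOT_LNC, f"ALNC{i:04d}", None, False) for i in range(config.n_annot_lnc)]
    decoy_types: list[str | None] = (
        [DECOY_SINGLE_EXON] * config.n_single_exon_decoys
        + [DECOY_SHORT] * config.n_short_decoys
        + [DECOY_CODING] * config.n_coding_decoys
    )
    n_enh_lnc = min(config.n_enhancer_lnc, len(config.enhancer_plan))
    if len(decoy_types) + n_enh_lnc > config.n_novel_lnc:
        raise ValueError("more decoys + enhancer-overlapping lncRNAs than novel lncRNAs")
    decoy_types += [None] * (config.n_novel_lnc - len(decoy_types))
    specs += [
        (NOVEL_LNC, f"NLNC{i:04d}", decoy_types[i],
         i >= config.n_novel_lnc - n_enh_lnc)
        for i in range(config.n_novel_lnc)
    ]
    # host slots for enhancer-overlapping lncRNAs: one site per SE
    # cluster first (SE-associated genes), then isolated sites (TE-)
    seen_clusters: set[int] = set()
    cluster_reps, isolated = [], []
    for s in sorted(config.enhancer_plan, key=lambda s: (s.chrom, s.start)):
        if s.se_cluster_id is None:
            isolated.append(s)
        elif s.se_cluster_id not in seen_clusters:
            seen_clusters.add(s.se_cluster_id)
            cluster_reps.append(s)
    enhancer_slots = iter(cluster_reps + isolated)

    promoter_marked: list[TranscriptModel] = []
    for biotype, gene_id, decoy, on_enhancer in specs:
        strand = "+" if rng.random() < 0.5 else "-"
        if decoy == DECOY_SINGLE_EXON:
            n_exons, exon_range, intron_range = 1, (600, 1000), (0, 1)
        elif decoy == DECOY_SHORT:
            n_exons, exon_range, intron_range = 2, (60, 95), (200, 800)
        elif biotype == PCG:
            n_exons, exon_range, intron_range = int(rng.integers(3, 9)), (100, 300), (200, 1500)
        else:
            n_exons, exon_range, intron_range = int(rng.integers(2, 5)), (200, 800), (200, 2000)
        # dry-run the span length with a cloned stream so placement and
        # structure stay independent draws
        probe = _make_exons(np.random.default_rng(rng.integers(2**31)), "x", 0,
                            "+", n_exons, exon_range, intron_range)
        span_len = probe[-1].end
        placed = None
        if on_enhancer:
            strand = "+"  # TSS inside the site; first exon overlaps it
            for site in enhancer_slots:
                placed = place_on_site(span_len, site)
                if placed is not None:
                    break
        if placed is None:
            placed = place(span_len)
        chrom, start = placed
        exons = [
            GenomicInterval(chrom, start + (e.start), start + e.end, strand)
            for e in probe
        ]
        if decoy == DECOY_CODING:
            coding = float(np.round(rng.uniform(4.5, 9.0), 3))
        elif biotype == PCG:
            coding = float(np.round(rng.uniform(6.0, 20.0), 3))
        else:
            coding = float(np.round(rng.uniform(0.0, 3.5), 3))
        m = TranscriptModel(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            biotype=biotype,
            exons=exons,
            coding_score=coding,
        )
        models.append(m)
        if decoy is not None:
            truth.decoys[decoy].append(m.transcript_id)
        if biotype == PCG or (
            not on_enhancer and rng.random() < config.lnc_promoter_fraction
        ):
            promoter_marked.append(m)

    hw = config.promoter_halfwidth
    for m in promoter_marked:
        size = config.chrom_sizes[m.chrom]
        truth.promoters.append(
            GenomicInterval(m.chrom, max(0, m.tss - hw), min(size, m.tss + hw))
        )
    truth.promoters = merge_intervals(truth.promoters)

    # planted condition-specific genes (non-decoy, so they survive the
    # filters); lncRNA genes are drawn with 3x the weight of PCGs so the
    # synthetic transcriptome shows the population-specificity skew of
    # lncRNAs that the ND comparison is built to detect
    decoy_ids = {t for lst in truth.decoys.values() for t in lst}
    eligible = [m for m in models if m.transcript_id not in decoy_ids]
    ep = config.expression
    need = ep.n_specific_per_condition * len(CONDITIONS)
    if need > len(eligible):
        raise ValueError("not enough genes for the condition-specific plan")
    if need:
        weights = np.array([1.0 if m.biotype == PCG else 3.0 for m in eligible])
        weights /= weights.sum()
        pick = _rng(config.seed, 2).choice(
            len(eligible), size=need, replace=False, p=weights
        )
    else:
        pick = np.zeros(0, dtype=int)
    for i, cond in enumerate(CONDITIONS):
        sel = pick[i * ep.n_specific_per_condition : (i + 1) * ep.n_specific_per_condition]
        truth.specific_genes[cond] = sorted(eligible[j].gene_id for j in sel)
    eligible = [m.gene_id for m in eligible]

    tp = config.tissue_plan
    hr = _rng(config.seed, 3).choice(len(eligible), size=min(tp.n_heart_genes, len(eligible)),
                                     replace=False)
    truth.heart_enriched = sorted(eligible[j] for j in hr)

    cp = config.conservation_plan
    cr = _rng(config.seed, 4).choice(
        len(eligible), size=min(cp.n_conserved_genes, len(eligible)), replace=False
    )
    truth.conserved_promoters = sorted(eligible[j] for j in cr)

    return dict(config.chrom_sizes), models, truth


# --- ChIP reads ---------------------------------------------------------


def intensity_segments(
    config: SyntheticConfig,
    truth: PlantedTruth,
    mark: str,
    condition: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Piecewise-constant read-start intensity per chromosome.

    Returns per-chrom (boundaries, rates): rate[i] applies on
    [boundaries[i], boundaries[i+1]). Background is ``background_rate``
    everywhere; planted sites active in the condition multiply it by
    their fold (H3K27Ac: enhancers; H3K4me3: promoters); input is
    background only. This is the ground-truth intensity the samplers
    draw from, exposed so tests can verify truth consistency without
    sampling noise.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    sites: list[tuple[GenomicInterval, float]] = []
    if mark == "H3K27Ac":
        sites = [
            (s.interval, s.fold)
            for s in truth.enhancers
            if condition in s.active_conditions
        ]
    elif mark == "H3K4me3":
        sites = [(p, config.promoter_fold) for p in truth.promoters]
    out = {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        cuts = {0, size}
        for iv, _ in sites:
            if iv.chrom == chrom:
                cuts.update((iv.start, iv.end))
        bounds = np.array(sorted(cuts), dtype=np.int64)
        rates = np.full(len(bounds) - 1, config.background_rate, dtype=float)
        for iv, fold in sites:
            if iv.chrom != chrom:
                continue
            i0 = np.searchsorted(bounds, iv.start)
            i1 = np.searchsorted(bounds, iv.end)
            rates[i0:i1] *= fold
        out[chrom] = (bounds, rates)
    return out


def simulate_chip_reads(
    config: SyntheticConfig,
    truth: PlantedTruth,
    mark: str,
    condition: str,
    replicate: int,
    read_length: int = READ_LENGTH,
) -> pd.DataFrame:
    """Sample one replicate's reads from the planted intensity.

    Per-segment counts are Poisson with expectation proportional to
    rate x length, scaled so the expected total is
    ``reads_per_replicate``; 5' starts are uniform within segments,
    strands uniform, aligned spans ``read_length`` bp clipped to the
    chromosome. Output is a sorted BED6-style frame.
    """
    config.validate()
    if replicate not in (1, 2):
        raise ValueError(f"replicate must be 1 or 2, got {replicate}")
    segs = intensity_segments(config, truth, mark, condition)
    total_intensity = sum(
        float(np.dot(np.diff(b), r)) for b, r in segs.values()
    )
    scale = config.reads_per_replicate / total_intensity
    rng = _rng(config.seed, 7, _MARK_CODE[mark], _COND_CODE[condition], replicate)
    rows = []
    for chrom in sorted(segs):
        bounds, rates = segs[chrom]
        lengths = np.diff(bounds)
        mu = rates * lengths * scale
        counts = rng.poisson(mu)
        n = int(counts.sum())
        if n == 0:
            continue
        starts5 = np.concatenate(
            [
                rng.integers(bounds[i], bounds[i + 1], size=c)
                for i, c in enumerate(counts)
                if c > 0
            ]
        )
        plus = rng.random(n) < 0.5
        size = config.chrom_sizes[chrom]
        start = np.where(plus, starts5, starts5 - (read_length - 1))
        end = np.where(plus, starts5 + read_length, starts5 + 1)
        start = np.clip(start, 0, size)
        end = np.clip(end, 1, size)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": start.astype(np.int64),
                    "end": end.astype(np.int64),
                    "strand": np.where(plus, "+", "-"),
                }
            )
        )
    if not rows:
        df = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    else:
        df = pd.concat(rows, ignore_index=True)
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort").reset_index(drop=True)
    df.insert(3, "name", [f"{mark}_{condition}_r{replicate}_{i}" for i in range(len(df))])
    df.insert(4, "score", 0)
    return df


# --- expression ---------------------------------------------------------


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise; exactly 1 when cv=0."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2, sigma, size=shape))


def simulate_expression(
    config: SyntheticConfig,
    truth: PlantedTruth,
    models: Sequence[TranscriptModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (3 conditions x replicates) and tissue count panel.

    Condition-specific genes get ``specific_mean`` in their condition
    and ``off_mean`` elsewhere; heart-enriched genes get
    ``effect_fold x base_mean`` in heart. Replicate noise is mean-1
    log-normal with the configured CV. Tissue totals are split between
    strands by a random fraction (strand counts sum exactly to the gene
    total).
    """
    genes = sorted({m.gene_id for m in models})
    ep = config.expression
    cond_of_gene = {
        g: cond for cond, lst in truth.specific_genes.items() for g in lst
    }
    mean = np.full((len(genes), len(CONDITIONS)), float(ep.base_mean))
    for i, g in enumerate(genes):
        if g in cond_of_gene:
            mean[i, :] = ep.off_mean
            mean[i, CONDITIONS.index(cond_of_gene[g])] = ep.specific_mean
    rng = _rng(config.seed, 8)
    cols, data = [], []
    for j, cond in enumerate(CONDITIONS):
        for r in range(1, ep.n_replicates + 1):
            cols.append(f"{cond}_{r}")
            data.append(mean[:, j] * _lognormal_noise(rng, ep.cv, len(genes)))
    fpkm = pd.DataFrame(np.column_stack(data), index=pd.Index(genes, name="gene_id"),
                        columns=cols)

    panel_df = simulate_tissue_panel(
        config.tissue_plan, genes, truth.heart_enriched, _rng(config.seed, 9)
    )
    return fpkm, panel_df


def simulate_tissue_panel(
    plan: TissuePlan,
    genes: Sequence[str],
    heart_genes: Iterable[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Stranded replicated tissue counts with planted heart enrichment.

    Heart-enriched genes get mean ``effect_fold x base_mean`` in heart,
    ``base_mean`` elsewhere; per-replicate totals carry mean-1 log-normal
    noise and are split between strands by a random fraction.
    """
    heart = set(heart_genes)
    tmean = np.full((len(genes), len(TISSUES)), float(plan.base_mean))
    hcol = TISSUES.index("heart")
    for i, g in enumerate(genes):
        if g in heart:
            tmean[i, hcol] = plan.base_mean * plan.effect_fold
    columns = pd.MultiIndex.from_tuples(
        [
            (t, r, s)
            for t in TISSUES
            for r in range(1, plan.n_replicates + 1)
            for s in ("+", "-")
        ],
        names=["tissue", "replicate", "strand"],
    )
    panel = np.zeros((len(genes), len(columns)))
    col = 0
    for ti in range(len(TISSUES)):
        for _ in range(plan.n_replicates):
            total = tmean[:, ti] * _lognormal_noise(rng, plan.cv, len(genes))
            frac = rng.uniform(0.3, 0.7, size=len(genes))
            panel[:, col] = total * frac
            panel[:, col + 1] = total * (1 - frac)
            col += 2
    return pd.DataFrame(panel, index=pd.Index(list(genes), name="gene_id"),
                        columns=columns)


# --- conservation -------------------------------------------------------


def simulate_conservation(
    config: SyntheticConfig,
    truth: PlantedTruth,
    models: Sequence[TranscriptModel],
):
    """phastCons-like track: noisy background with elevated promoters.

    Per-window background scores are normal(background_mean,
    background_sd) clipped to [0, 1]; windows in the 1-kb upstream
    promoter of each designated conserved gene are raised by
    ``promoter_delta``.
    """
    from .conservation import ConservationTrack, promoter_interval

    cp = config.conservation_plan
    rng = _rng(config.seed, 10)
    conserved = set(truth.conserved_promoters)
    promoters = [
        promoter_interval(m) for m in models if m.gene_id in conserved
    ]
    runs = {}
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        n_win = -(-size // cp.window)
        starts = np.arange(n_win, dtype=np.int64) * cp.window
        ends = np.minimum(starts + cp.window, size)
        vals = np.clip(
            rng.normal(cp.background_mean, cp.background_sd, size=n_win), 0.0, 1.0
        )
        for p in promoters:
            if p.chrom != chrom:
                continue
            w0 = min(p.start // cp.window, n_win - 1)
            w1 = min((p.end - 1) // cp.window, n_win - 1)
            vals[w0 : w1 + 1] = np.clip(vals[w0 : w1 + 1] + cp.promoter_delta, 0.0, 1.0)
        runs[chrom] = (starts, ends, vals)
    return ConservationTrack(runs=runs, chrom_sizes=dict(config.chrom_sizes))
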