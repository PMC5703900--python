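#!/usr/bin/env python
"""Population specificity of gene expression: the ND statistic.

ND(x) = (max - min) / mean of a gene's FPKM across ESC, Eo- and Eo+
(bounded [0, 3]; 3 = expressed in exactly one population). Compares ND
distributions between gene classes with one-tail Wilcoxon tests, and
builds the >2-fold Eo+/Eo- enriched gene sets used by the tissue
analysis.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from enhancerscape.config import PipelineConfig
from enhancerscape.pipeline import run_pipeline
from enhancerscape.synthetic import default_config


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()
    cfg = PipelineConfig(synthetic=default_config(args.seed))
    run_pipeline(cfg, args.outdir, only=["specificity"])
    nd = pd.read_csv(args.outdir / "nd_table.tsv", sep="\t", index_col=0)
    print("median ND by biotype:")
    for bt, sub in nd.groupby("biotype"):
        print(f"  {bt:13s}: {sub['ND'].median():.3f} (n={len(sub)})")
    comp = json.loads((args.outdir / "nd_comparisons.json").read_text())
    for name, r in comp.items():
        print(f"Wilcoxon {name}: p = {r['p']:.3g} ({r['method']})")
    for tag in ("eo_pos", "eo_neg"):
        genes = json.loads((args.outdir / f"enriched_{tag}.json").read_text())
        print(f">2FC {tag} enriched genes: {len(genes)}")


if __name__ == "__main__":
    main()
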