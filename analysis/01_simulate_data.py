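#!/usr/bin/env python
"""Generate the synthetic study: toy genome, transcripts, ChIP reads,
expression matrices, tissue panel, and conservation track.

Writes reads/, transcripts.gtf, fpkm.tsv, tissue_counts.tsv,
conservation.tsv and the planted truth (truth.json) under the output
directory; downstream scripts (02-07) consume these files.
"""

import argparse
import json
from pathlib import Path

from enhancerscape.config import PipelineConfig
from enhancerscape.pipeline import run_pipeline
from enhancerscape.synthetic import default_config


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()
    cfg = PipelineConfig(synthetic=default_config(args.seed))
    run_pipeline(cfg, args.outdir, only=["simulate"])
    truth = json.loads((args.outdir / "truth.json").read_text())
    n_clusters = len({s["se_cluster_id"] for s in truth["enhancers"]
                      if s["se_cluster_id"] is not None})
    print(f"wrote synthetic dataset to {args.outdir}")
    print(f"  planted enhancer sites : {len(truth['enhancers'])}"
          f" ({n_clusters} SE clusters)")
    print(f"  planted promoter marks : {len(truth['promoters'])}")
    print(f"  condition-specific genes: "
          + ", ".join(f"{c}:{len(g)}" for c, g in truth["specific_genes"].items()))
    print(f"  heart-enriched genes   : {len(truth['heart_enriched'])}")
    print(f"  conserved promoters    : {len(truth['conserved_promoters'])}")


if __name__ == "__main__":
    main()
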