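"""Readers and writers for the standard text formats.

BED and bedGraph are written 0-based half-open (native to the internal
coordinate convention); GTF is converted to 1-based inclusive at this
boundary. Floating-point TSV output uses 6 significant digits so runs
diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval
from .lncrna import TranscriptModel

FLOAT_FORMAT = "%.6g"

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(intervals_or_df, path) -> None:
    """Write BED (3 or 6 columns) from intervals or a reads DataFrame."""
    if isinstance(intervals_or_df, pd.DataFrame):
        df = intervals_or_df
        cols = [c for c in BED6_COLUMNS if c in df.columns]
        df[cols].to_csv(path, sep="\t", header=False, index=False)
        return
    rows = [
        f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}"
        for iv in intervals_or_df
    ]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a chrom/start/end[/name/score/strand] frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    strand = df["strand"] if "strand" in df.columns else ["."] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), st)
        for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strand)
    ]


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Write transcripts as exon features (GTF: 1-based inclusive)."""
    lines = []
    for m in models:
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'biotype "{m.biotype}"; coding_score "{FLOAT_FORMAT % m.coding_score}";'
        )
        for e in m.exons:
            lines.append(
                "\t".join(
                    [
                        e.chrom,
                        "enhancerscape",
                        "exon",
                        str(e.start + 1),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features back into TranscriptModel objects."""
    import re

    by_tx: dict[str, dict] = {}
    attr_re = re.compile(r'(\w+) "([^"]*)"')
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(attr_re.findall(f[8]))
            tid = attrs["transcript_id"]
            rec = by_tx.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "biotype": attrs.get("biotype", "PCG"),
                    "coding_score": float(attrs.get("coding_score", 0.0)),
                    "exons": [],
                },
            )
            rec["exons"].append(
                GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6])
            )
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            biotype=rec["biotype"],
            exons=rec["exons"],
            coding_score=rec["coding_score"],
        )
        for tid, rec in by_tx.items()
    ]


def write_bedgraph(track, path, per_million: bool = False) -> None:
    """Write a BinnedTrack as bedGraph (optionally per-million scaled)."""
    scale = 1e6 / track.total_mapped if (per_million and track.total_mapped) else 1.0
    lines = []
    bs = track.bin_size
    for chrom in sorted(track.counts):
        c = track.counts[chrom]
        size = track.chrom_sizes[chrom]
        nz = np.flatnonzero(c)
        for i in nz:
            v = c[i] * scale
            lines.append(
                f"{chrom}\t{i * bs}\t{min((i + 1) * bs, size)}\t{FLOAT_FORMAT % v}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"], dtype={0: str})
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
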