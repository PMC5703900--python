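import numpy as np
import pandas as pd
import pytest

from enhancerscape.chip import BinnedTrack
from enhancerscape.config import PipelineConfig
from enhancerscape.pipeline import run_pipeline
from enhancerscape.synthetic import default_config, generate_genome_and_transcripts


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=3)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome_and_transcripts(small_config)


@pytest.fixture(scope="session")
def pipeline_out(tmp_path_factory, small_config):
    """One full synthetic pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    run_pipeline(PipelineConfig(synthetic=small_config), out)
    return out


def track_from_counts(counts: dict[str, np.ndarray], total_mapped=None,
                      bin_size=25) -> BinnedTrack:
    """Hand-built binned track for arithmetic tests."""
    counts = {c: np.asarray(v, dtype=np.int64) for c, v in counts.items()}
    chrom_sizes = {c: len(v) * bin_size for c, v in counts.items()}
    if total_mapped is None:
        total_mapped = int(sum(v.sum() for v in counts.values()))
    return BinnedTrack(bin_size=bin_size, chrom_sizes=chrom_sizes,
                       counts=counts, total_mapped=total_mapped)


def reads_frame(rows):
    """rows: (chrom, start, end, strand)."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
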