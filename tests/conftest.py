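import numpy as np
import pytest

from rdipkit.genome_io import Genome, GenomicInterval
from rdipkit.synthetic_data import (
    SimulationConfig,
    simulate_genome,
    simulate_peaks_and_reads,
)


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 1_000, "chr2": 500})


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 800_000, "chr2": 600_000},
        n_genes=60,
        n_peaks=120,
        reads_per_peak=30,
        n_cpg_sites=2_000,
        n_repeats=80,
        window_width=100_000,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    config = SimulationConfig(
        seed=23,
        chrom_lengths={"chr1": 800_000, "chr2": 600_000},
        n_genes=60,
        n_peaks=150,
        reads_per_peak=30,
        n_cpg_sites=2_000,
        n_repeats=80,
    )
    genome, features = simulate_genome(config)
    peaks, sam_lines, truth = simulate_peaks_and_reads(config, genome, features)
    return {
        "config": config,
        "genome": genome,
        "features": features,
        "peaks": peaks,
        "sam_lines": sam_lines,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def scored_peaks(small_dataset):
    from rdipkit.strandedness import score_peaks

    from _helpers import records_from_lines

    records = list(records_from_lines(small_dataset["sam_lines"]))
    return score_peaks(small_dataset["peaks"], records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
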