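import numpy as np
import pytest

from oridyn import GenomeSpec, SignalTrack, SimConfig, default_genome, default_origin_set


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec((("chrA", 10_000), ("chrB", 5_000)))


@pytest.fixture
def toy_genome() -> GenomeSpec:
    return default_genome()


@pytest.fixture
def toy_origins(toy_genome):
    return default_origin_set(toy_genome)


@pytest.fixture
def quiet_config() -> SimConfig:
    """Noise-free, stall-free configuration for exact kinematics checks."""
    return SimConfig(seed=0, n_cells=1, stall_prob=0.0, restart_fail_prob=0.0, fiber_noise_sd=0.0)


def track_from(genome: GenomeSpec, bin_size: int, **vectors) -> SignalTrack:
    """Build a track from explicit per-chromosome vectors (zero elsewhere)."""
    track = SignalTrack.zeros(genome, bin_size)
    for chrom, values in vectors.items():
        arr = np.asarray(values, dtype=float)
        track.data[chrom][: len(arr)] = arr
    return track
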