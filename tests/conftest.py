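import numpy as np
import pytest

from chipscale import (
    BinnedCoverage,
    GenomeLayout,
    SimulationConfig,
    make_bin_grid,
)


@pytest.fixture
def toy_layout():
    return GenomeLayout((("chrA", 1000), ("chrB", 700)))


@pytest.fixture
def toy_grid(toy_layout):
    return make_bin_grid(toy_layout, 500)


@pytest.fixture
def small_sim_config():
    """Scaled-down simulation that runs in well under a second."""
    return SimulationConfig(
        n_sequences=1,
        sequence_length=500_000,
        n_artifact_bins=20,
        n_minor_artifact_bins=50,
        n_domains=3,
        domain_length_range=(20_000, 60_000),
        n_promoters=20,
        seed=0,
    )


def track(grid, values):
    """Coverage track from explicit per-bin values."""
    values = np.asarray(values, dtype=float)
    total = float((values * grid.bin_lengths).sum())
    return BinnedCoverage(grid, values, total)


@pytest.fixture
def make_track():
    return track


def brute_force_coverage(fragments_by_seq, layout, bin_size):
    """Per-base depth accumulation oracle: mean depth per bin, bin by bin."""
    out = []
    for name, length in layout.sequences:
        depth = np.zeros(length)
        for s, e in fragments_by_seq.get(name, []):
            depth[max(0, s) : min(e, length)] += 1
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            out.append(depth[start:end].mean())
    return np.array(out)
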