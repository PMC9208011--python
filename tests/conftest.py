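import numpy as np
import pytest

from nanet.synthetic import generate_coupling, generate_population, simulate_traces
from nanet.types import ASTRO, NEURON, Population, Roi
from nanet.waveforms import TemplateLibrary


@pytest.fixture(scope="session")
def small_population() -> Population:
    """12 neurons + 2 astrocytes with ~4 segments each, deterministic."""
    return generate_population(
        12, 2, segments_per_astrocyte=4.0, fov=(1000.0, 1000.0), seed=11,
        dish_id="fix",
    )


@pytest.fixture(scope="session")
def small_traceset(small_population):
    coupling = generate_coupling(small_population, 0.2, 0.2, seed=3)
    return simulate_traces(
        small_population, coupling, duration=60.0, sampling_rate=20.0, seed=5
    )


@pytest.fixture(scope="session")
def library() -> TemplateLibrary:
    return TemplateLibrary.default(20.0)


@pytest.fixture
def two_neuron_population() -> Population:
    return Population(
        rois=[Roi("n0", NEURON, 100.0, 100.0), Roi("n1", NEURON, 400.0, 300.0)],
        fov_width=1000.0,
        fov_height=1000.0,
        dish_id="pair",
    )


def grid_population(n_neurons: int, n_astro_cells: int, segs: int,
                    fov=(1000.0, 1000.0)) -> Population:
    """Deterministic population on a jittered grid (helper for tests)."""
    rng = np.random.default_rng(123)
    rois = []
    for i in range(n_neurons):
        rois.append(
            Roi(f"n{i}", NEURON, rng.uniform(0, fov[0]), rng.uniform(0, fov[1]))
        )
    for a in range(n_astro_cells):
        cx, cy = rng.uniform(100, fov[0] - 100), rng.uniform(100, fov[1] - 100)
        for s in range(segs):
            rois.append(
                Roi(
                    f"a{a}s{s}",
                    ASTRO,
                    cx + rng.uniform(-40, 40),
                    cy + rng.uniform(-40, 40),
                    parent_cell_id=f"a{a}",
                )
            )
    return Population(rois=rois, fov_width=fov[0], fov_height=fov[1], dish_id="grid")
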