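import numpy as np
import pytest

from heatrr.blocks import DEFAULT_REGISTRY, TYPE_I
from heatrr.mavb import MAVBParams
from heatrr.solver import SolverConfig, _iter_structures, _structure_levels


def draw_on_grid_params(
    rng: np.random.Generator,
    blocktype_id: int,
    delta_a_range: tuple[int, int] = (190, 330),
    increment_max: int = 40,
    grid_step: int = 1,
) -> MAVBParams:
    """Random on-grid parameters for one blocktype preset (ground truth
    for recovery tests)."""
    structures = list(_iter_structures(DEFAULT_REGISTRY[blocktype_id]))
    structure = structures[int(rng.integers(len(structures)))]
    deltas = []
    for spec, _, _ in structure:
        lo, hi = spec.delta_bounds
        if spec.block_type == TYPE_I and hi > lo:
            top = int(min(hi, increment_max)) // grid_step
            deltas.append(float(rng.integers(0, top + 1) * grid_step))
        else:
            deltas.append(0.0)
    lo, hi = delta_a_range
    delta_a = float(rng.integers(lo // grid_step, hi // grid_step) * grid_step)
    return MAVBParams(delta_a, blocktype_id, _structure_levels(structure, deltas))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def coarse_config():
    """5 ms grids: small enough for the brute-force oracle."""
    return SolverConfig(grid_step=5.0)


@pytest.fixture
def fast_config():
    """Single-level blocktypes only: cheap solves for pipeline tests."""
    return SolverConfig(blocktype_ids=(1, 2))
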