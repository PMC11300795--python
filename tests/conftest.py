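"""Shared fixtures: small maps, selections and ensembles built in memory."""

import numpy as np
import pytest

from cryoreweight.density import DensityMap, VoxelSelection
from cryoreweight.forward import Structure
from cryoreweight.synth import make_two_state_ensemble


@pytest.fixture
def small_map():
    """A 4x5x6 map with deterministic positive values and a known origin."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.0, 1.0, size=(4, 5, 6))
    values[2, 2, 3] = 1.0  # pin the maximum
    return DensityMap(values, origin=np.array([1.0, -2.0, 3.5]), voxel_size=1.5)


@pytest.fixture
def single_atom():
    return Structure(
        coords=np.array([[0.0, 0.0, 0.0]]),
        elements=["C"],
        atom_names=["CA"],
        residue_ids=np.array([1]),
        chain_ids=["A"],
        label="atom",
    )


def make_selection(ref, models, sigma=1.0):
    """A VoxelSelection over every voxel of hand-given density vectors."""
    ref = np.asarray(ref, dtype=np.float64)
    models = np.asarray(models, dtype=np.float64)
    return VoxelSelection(
        indices=np.arange(len(ref)),
        ref_density=ref,
        model_density=models,
        sigma_kernel=sigma,
    )


@pytest.fixture
def toy_selection():
    """Two models, six voxels: model 0 matches the reference exactly."""
    ref = np.array([1.0, 0.8, 0.6, 0.4, 0.2, 0.1])
    m0 = ref.copy()
    m1 = np.array([0.1, 0.2, 0.4, 0.6, 0.8, 1.0])
    return make_selection(ref, np.stack([m0, m1], axis=1))


@pytest.fixture(scope="session")
def tiny_two_state():
    """A small (M=10) discrete-heterogeneity ensemble for fast pipeline tests."""
    return make_two_state_ensemble(M=10, seed=7)
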