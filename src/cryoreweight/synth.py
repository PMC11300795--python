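"""Synthetic heterogeneity benchmarks with ground-truth weights.

Three test designs, each a pure function of its seed:

* **two_state** - a toy two-domain hinged polymer whose open and closed end
  states differ by a hinge rotation (default 30 degrees, giving an end-state
  RMSD around 8 A, comparable to a large domain closure such as adenylate
  kinase's 7.16 A open/closed transition).  References mix the two
  state-mean maps at populations 0.0-1.0; discrete heterogeneity.
* **continuous_subset** - a continuous ensemble generated by smooth
  low-frequency backbone deformations of the same polymer; a random
  ``subset_size``-member subset defines the reference map (continuous
  heterogeneity, nascent-chain style).
* **compositional** - two species sharing a frame (the polymer, with and
  without a companion globular domain) mixed at a known fraction
  (compositional heterogeneity, extra-factor style).

All structures are pseudo-atomic (one atom per residue, 3.8 A spacing,
cycled C/N/O/S elements) so the benchmarks need no external coordinates;
real PDB/mmCIF inputs go through the standard readers instead.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np

from .density import DensityMap, NoiseModel, add_noise, normalize_map
from .forward import EnsembleSpec, Structure, molmap_sigma, simulate_reference_map

__all__ = [
    "BenchmarkSpec",
    "GroundTruth",
    "make_two_state_ensemble",
    "make_continuous_ensemble",
    "make_mixture_reference",
    "make_subset_reference",
    "make_compositional_ensemble",
    "add_companion_domain",
    "two_state_grid",
    "CI_POPULATIONS",
    "CI_RESOLUTIONS",
    "CI_NOISE_FRACTIONS",
    "FULL_POPULATIONS",
    "FULL_RESOLUTIONS",
    "FULL_NOISE_FRACTIONS",
]

RESIDUE_SPACING = 3.8  # A, consecutive pseudo-atoms
DEFAULT_HINGE_ANGLE = 30.0  # deg, open -> closed rotation of the second arm
JITTER_SD = 0.3  # A, per-coordinate member jitter within a state
HINGE_WOBBLE_SD = 3.0  # deg, per-member hinge-angle wobble
_ELEMENT_CYCLE = ("C", "N", "C", "O", "C", "N", "C", "O", "C", "S")

# Benchmark grids: the quick grid exercised by the test suite, and the full
# 11 x 3 x 2 = 66-map design.
CI_POPULATIONS = (0.2, 0.5, 0.8)
CI_RESOLUTIONS = (6.0, 10.0)
CI_NOISE_FRACTIONS = (0.01,)
FULL_POPULATIONS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
FULL_RESOLUTIONS = (3.0, 6.0, 10.0)
FULL_NOISE_FRACTIONS = (0.01, 0.10)


@dataclasses.dataclass
class BenchmarkSpec:
    """One benchmark condition; ``seed`` is recorded in every manifest."""

    design: str
    resolution: float
    noise_fraction: float
    seed: int
    population: float | None = None
    subset_size: int | None = None
    ensemble_size: int = 100

    def __post_init__(self) -> None:
        if self.design not in {"two_state", "continuous_subset", "compositional"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.population is not None and not (0.0 <= self.population <= 1.0):
            raise ValueError("population must lie in [0, 1]")
        if self.subset_size is not None and self.subset_size > self.ensemble_size:
            raise ValueError("subset_size cannot exceed ensemble size")

    def to_manifest(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GroundTruth:
    """True member weights plus the clean (pre-noise) reference map."""

    weights: np.ndarray
    member_ids: np.ndarray
    clean_map: DensityMap | None = None
    species_fraction: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("ground-truth weights must be normalised")
        self.member_ids = np.asarray(self.member_ids, dtype=np.int64)

    def to_manifest(self) -> dict:
        return {
            "weights": list(map(float, self.weights)),
            "member_ids": list(map(int, self.member_ids)),
            "species_fraction": self.species_fraction,
        }


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def _elements(n: int) -> list[str]:
    return [_ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)] for i in range(n)]


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _base_chain(n_residues: int, hinge_angle_deg: float) -> np.ndarray:
    """The hinged two-arm polymer; ``hinge_angle_deg`` closes the second arm.

    Arm A runs from the hinge along one fixed direction, arm B along another;
    a small alternating out-of-plane zig-zag gives the maps internal texture.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues (2 per arm)")
    n_a = n_residues // 2
    n_b = n_residues - n_a
    coords = np.zeros((n_residues, 3))
    dir_a = np.array([np.cos(np.deg2rad(150.0)), np.sin(np.deg2rad(150.0)), 0.0])
    dir_b = _rot_z(hinge_angle_deg) @ np.array([1.0, 0.0, 0.0])
    for i in range(n_a):
        coords[n_a - 1 - i] = (i + 1) * RESIDUE_SPACING * dir_a
    for j in range(n_b):
        coords[n_a + j] = (j + 1) * RESIDUE_SPACING * dir_b
    coords[:, 2] += 0.8 * np.where(np.arange(n_residues) % 2 == 0, 1.0, -1.0)
    return coords


def _member(coords: np.ndarray, label: str) -> Structure:
    n = len(coords)
    return Structure(
        coords=coords,
        elements=_elements(n),
        atom_names=["CA"] * n,
        residue_ids=np.arange(1, n + 1),
        chain_ids=["A"] * n,
        label=label,
    )


def make_two_state_ensemble(
    n_residues: int = 40,
    hinge_angle: float = DEFAULT_HINGE_ANGLE,
    M: int = 100,
    seed: int = 0,
    jitter_sd: float = JITTER_SD,
    hinge_wobble_sd: float = HINGE_WOBBLE_SD,
) -> EnsembleSpec:
    """M/2 members jittered around each of the open and closed end states.

    ``hinge_angle`` (degrees) is the open-to-closed rotation of the second
    arm; 0 collapses both states onto one conformation.  Labels record the
    source state as ``open:i`` / ``closed:i``.
    """
    if M % 2 != 0:
        raise ValueError("M must be even (M/2 members per state)")
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    structures = []
    for state, base_angle in (("open", 0.0), ("closed", hinge_angle)):
        for i in range(M // 2):
            wobble = rng.normal(0.0, hinge_wobble_sd)
            coords = _base_chain(n_residues, base_angle + wobble)
            coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)
            structures.append(_member(coords, f"{state}:{i}"))
    return EnsembleSpec(structures)


def make_continuous_ensemble(
    n_residues: int = 40,
    M: int = 100,
    seed: int = 0,
    amplitude: float = 6.0,
    n_modes: int = 3,
    jitter_sd: float = JITTER_SD,
) -> EnsembleSpec:
    """A continuum of conformations via smooth low-frequency deformations.

    Each member displaces the open-state chain by a sum of ``n_modes``
    sinusoidal modes along the chain coordinate, with mode amplitude drawn
    from N(0, amplitude/k); the resulting pairwise RMSD spread (several to
    ~20 A at the default amplitude) emulates a highly flexible tethered
    domain.
    """
    rng = np.random.default_rng(seed)
    base = _base_chain(n_residues, DEFAULT_HINGE_ANGLE / 2.0)
    t = np.linspace(0.0, 1.0, n_residues)
    structures = []
    for i in range(M):
        coords = base.copy()
        for k in range(1, n_modes + 1):
            a_k = rng.normal(0.0, amplitude / k)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            vec = rng.normal(size=3)
            vec /= np.linalg.norm(vec)
            coords += a_k * np.sin(np.pi * k * t + phase)[:, None] * vec[None, :]
        coords += rng.normal(0.0, jitter_sd, size=coords.shape)
        structures.append(_member(coords, f"member:{i}"))
    return EnsembleSpec(structures)


# ---------------------------------------------------------------------------
# Reference-map builders
# ---------------------------------------------------------------------------

def _member_maps(
    ensemble: EnsembleSpec, resolution: float,
    voxel_size: float | None, padding: float | None,
) -> list[DensityMap]:
    grid = simulate_reference_map(
        ensemble.structures, resolution, voxel_size=voxel_size, padding=padding
    )
    grid = grid.copy(values=np.zeros(grid.shape))
    sigma = molmap_sigma(resolution)
    from .forward import simulate_model_map

    return [simulate_model_map(s, grid, sigma) for s in ensemble.structures]


def _state_of(structure: Structure) -> str:
    return structure.label.split(":")[0]


def make_mixture_reference(
    ensemble: EnsembleSpec,
    populations,
    resolution: float,
    noise_fraction: float,
    seed: int = 0,
    voxel_size: float | None = None,
    padding: float | None = None,
) -> tuple[DensityMap, GroundTruth, NoiseModel]:
    """Population-weighted average of the state-mean maps, plus noise.

    ``populations`` follows the order in which states first appear in the
    member labels.  The ground truth splits each state's population
    uniformly over that state's members and stores the clean normalised map.
    """
    populations = np.asarray(populations, dtype=np.float64)
    if abs(populations.sum() - 1.0) > 1e-8:
        raise ValueError("populations must be normalised")
    states = list(dict.fromkeys(_state_of(s) for s in ensemble.structures))
    if len(populations) != len(states):
        raise ValueError(
            f"{len(populations)} populations for {len(states)} states ({states})"
        )
    maps = _member_maps(ensemble, resolution, voxel_size, padding)
    member_states = np.array([_state_of(s) for s in ensemble.structures])
    weights = np.zeros(ensemble.n_members)
    mixture = maps[0].copy(values=np.zeros(maps[0].shape))
    for pop, state in zip(populations, states):
        idx = np.flatnonzero(member_states == state)
        state_mean = np.mean([maps[i].values for i in idx], axis=0)
        mixture.values += pop * state_mean
        weights[idx] = pop / len(idx)
    clean = normalize_map(mixture)
    noise = NoiseModel(noise_fraction, seed=seed)
    noisy = add_noise(clean, noise)
    truth = GroundTruth(weights, np.flatnonzero(weights > 0), clean_map=clean)
    return noisy, truth, noise


def make_subset_reference(
    ensemble: EnsembleSpec,
    subset_size: int,
    resolution: float,
    noise_fraction: float,
    seed: int = 0,
    voxel_size: float | None = None,
    padding: float | None = None,
) -> tuple[DensityMap, GroundTruth, NoiseModel]:
    """Uniform average map over a seeded random subset of members."""
    if subset_size < 1:
        raise ValueError("subset_size must be at least 1")
    if subset_size > ensemble.n_members:
        raise ValueError("subset_size cannot exceed ensemble size")
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(ensemble.n_members, size=subset_size, replace=False))
    maps = _member_maps(ensemble, resolution, voxel_size, padding)
    avg = maps[0].copy(values=np.mean([maps[i].values for i in subset], axis=0))
    clean = normalize_map(avg)
    noise = NoiseModel(noise_fraction, seed=seed)
    noisy = add_noise(clean, noise)
    weights = np.zeros(ensemble.n_members)
    weights[subset] = 1.0 / subset_size
    truth = GroundTruth(weights, subset, clean_map=clean)
    return noisy, truth, noise


def add_companion_domain(
    ensemble: EnsembleSpec,
    n_atoms: int = 12,
    offset=(12.0, -14.0, 0.0),
    radius: float = 5.0,
    seed: int = 0,
    species: str = "B",
) -> EnsembleSpec:
    """A second species: each member gains a compact globular companion.

    The companion is one rigid seeded blob of pseudo-atoms placed at a fixed
    offset from the chain terminus, shared across members (the species
    differs by composition, not by companion dynamics).
    """
    rng = np.random.default_rng(seed)
    blob = rng.normal(0.0, radius / 2.0, size=(n_atoms, 3))
    blob -= blob.mean(axis=0)
    offset = np.asarray(offset, dtype=np.float64)
    structures = []
    for i, s in enumerate(ensemble.structures):
        anchor = s.coords[-1]
        extra = blob + anchor + offset
        coords = np.vstack([s.coords, extra])
        structures.append(
            Structure(
                coords=coords,
                elements=list(s.elements) + _elements(n_atoms),
                atom_names=list(s.atom_names) + ["CA"] * n_atoms,
                residue_ids=np.concatenate(
                    [s.residue_ids, np.arange(1, n_atoms + 1) + s.residue_ids.max()]
                ),
                chain_ids=list(s.chain_ids) + ["B"] * n_atoms,
                label=f"{species}:{i}",
            )
        )
    return EnsembleSpec(structures)


def make_compositional_ensemble(
    species_a: EnsembleSpec,
    species_b: EnsembleSpec,
    mix_fraction: float,
    resolution: float,
    noise_fraction: float,
    seed: int = 0,
    voxel_size: float | None = None,
    padding: float | None = None,
) -> tuple[EnsembleSpec, DensityMap, GroundTruth, NoiseModel]:
    """Concatenate two species and build a mixed-composition reference map.

    The reference is the ``(1 - f, f)``-weighted average of the species-mean
    maps (f = ``mix_fraction`` of species B); the ground truth records the
    species fraction and per-member weights.  The species must share a frame
    (overlapping bounding boxes).
    """
    if not (0.0 <= mix_fraction <= 1.0):
        raise ValueError("mix_fraction must lie in [0, 1]")
    lo_a, hi_a = species_a.bounding_box()
    lo_b, hi_b = species_b.bounding_box()
    if np.any(hi_a < lo_b) or np.any(hi_b < lo_a):
        raise ValueError("species bounding boxes are disjoint; frames do not match")
    combined = EnsembleSpec(list(species_a.structures) + list(species_b.structures))
    maps = _member_maps(combined, resolution, voxel_size, padding)
    m_a = species_a.n_members
    mean_a = np.mean([m.values for m in maps[:m_a]], axis=0)
    mean_b = np.mean([m.values for m in maps[m_a:]], axis=0)
    mixture = maps[0].copy(values=(1.0 - mix_fraction) * mean_a + mix_fraction * mean_b)
    clean = normalize_map(mixture)
    noise = NoiseModel(noise_fraction, seed=seed)
    noisy = add_noise(clean, noise)
    weights = np.concatenate(
        [
            np.full(m_a, (1.0 - mix_fraction) / m_a),
            np.full(species_b.n_members, mix_fraction / species_b.n_members),
        ]
    )
    truth = GroundTruth(
        weights,
        np.flatnonzero(weights > 0),
        clean_map=clean,
        species_fraction=mix_fraction,
    )
    return combined, noisy, truth, noise


# ---------------------------------------------------------------------------
# Benchmark grids and manifests
# ---------------------------------------------------------------------------

def two_state_grid(
    populations=CI_POPULATIONS,
    resolutions=CI_RESOLUTIONS,
    noise_fractions=CI_NOISE_FRACTIONS,
    ensemble_size: int = 100,
    seed: int = 0,
) -> list[BenchmarkSpec]:
    """Enumerate two-state benchmark conditions (full grid: 11 x 3 x 2 = 66)."""
    return [
        BenchmarkSpec(
            design="two_state",
            resolution=float(r),
            noise_fraction=float(nf),
            seed=seed,
            population=float(p),
            ensemble_size=ensemble_size,
        )
        for p, r, nf in itertools.product(populations, resolutions, noise_fractions)
    ]


def write_manifest(path: str | Path, spec: BenchmarkSpec, truth: GroundTruth) -> None:
    payload = {"spec": spec.to_manifest(), "ground_truth": truth.to_manifest()}
    Path(path).write_text(json.dumps(payload, indent=2))
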