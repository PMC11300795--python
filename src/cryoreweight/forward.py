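"""Forward density model: atomic structures -> simulated cryo-EM maps.

Each atom contributes a normalised isotropic 3-D Gaussian whose amplitude
comes from a single-Gaussian fit to that element's electron atomic scattering
factor, so an atom's integrated map density is proportional to its scattering
power.  Reference maps use the molmap convention sigma = 0.225 x resolution;
model maps for the reweighting likelihood share one global kernel width sigma
treated as a nuisance parameter.

Structures are read with gemmi (PDB or mmCIF); a light-weight
:class:`Structure` keeps only what the forward model and the metrics need.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import gemmi
import numpy as np

from .density import DensityMap

__all__ = [
    "Structure",
    "EnsembleSpec",
    "KernelTable",
    "DEFAULT_KERNEL_TABLE",
    "read_structure",
    "write_structure",
    "molmap_sigma",
    "simulate_reference_map",
    "simulate_model_map",
    "average_map",
    "grid_rigid_fit",
]

#: molmap blur-kernel bandwidth as a fraction of the nominal resolution.
MOLMAP_SIGMA_FACTOR = 0.225

#: Per-atom Gaussian support radius in units of sigma; truncating at 4 sigma
#: discards < 0.4% of an atom's mass.
TRUNCATION_SIGMAS = 4.0

#: Default grid padding around the ensemble bounding box, in resolutions.
PADDING_RESOLUTIONS = 3.0

#: Default voxel size as a fraction of the resolution (three voxels per
#: resolution element, the usual simulated-map sampling).
VOXEL_PER_RESOLUTION = 1.0 / 3.0


@dataclasses.dataclass
class Structure:
    """An atomic (or pseudo-atomic) model in the map frame.

    ``label`` is a provenance tag (ensemble member id, species name for
    compositional mixtures) carried through reweighting outputs.
    """

    coords: np.ndarray
    elements: list[str]
    atom_names: list[str] | None = None
    residue_ids: np.ndarray | None = None
    chain_ids: list[str] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure must contain at least one atom")
        if len(self.elements) != n:
            raise ValueError("elements length must match coords")
        if self.atom_names is None:
            self.atom_names = ["X"] * n
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, n + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        if self.chain_ids is None:
            self.chain_ids = ["A"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with coords -> coords @ R.T + t (rotation about the centroid)."""
        centre = self.coords.mean(axis=0)
        new = (self.coords - centre) @ np.asarray(rotation).T + centre + translation
        return dataclasses.replace(self, coords=new)


@dataclasses.dataclass
class EnsembleSpec:
    """An ordered structural ensemble sharing an atom correspondence."""

    structures: list[Structure]

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("ensemble must contain at least one structure")

    @property
    def n_members(self) -> int:
        return len(self.structures)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.structures]

    def subset(self, member_idx) -> "EnsembleSpec":
        return EnsembleSpec([self.structures[i] for i in member_idx])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.min([s.coords.min(axis=0) for s in self.structures], axis=0)
        hi = np.max([s.coords.max(axis=0) for s in self.structures], axis=0)
        return lo, hi


# ---------------------------------------------------------------------------
# Scattering-amplitude kernel table
# ---------------------------------------------------------------------------

# Amplitudes are the zero-angle electron scattering power per element
# (sum of the five-Gaussian scattering-factor coefficients collapsed to a
# single Gaussian); b is the indicative intrinsic real-space width of that
# fit in Angstrom.  Only the amplitudes enter the forward model: the kernel
# width is the shared nuisance sigma (or 0.225 x resolution for reference
# synthesis), not sigma combined with b.
_ELEMENT_AMPLITUDES: dict[str, tuple[float, float]] = {
    "H": (0.5288, 0.36),
    "C": (2.5088, 0.46),
    "N": (2.2135, 0.42),
    "O": (1.9834, 0.39),
    "P": (5.7225, 0.58),
    "S": (5.1604, 0.57),
}

_ATOMIC_NUMBER: dict[str, int] = {
    "H": 1, "HE": 2, "LI": 3, "BE": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "NE": 10, "NA": 11, "MG": 12, "AL": 13, "SI": 14, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "CO": 27,
    "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}


class KernelTable:
    """Per-element Gaussian amplitudes for the forward model.

    Unlisted elements fall back to an amplitude proportional to atomic
    number, scaled to the carbon entry.
    """

    def __init__(self, table: dict[str, tuple[float, float]] | None = None) -> None:
        self.table = dict(table if table is not None else _ELEMENT_AMPLITUDES)
        for el, (a, b) in self.table.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"non-positive kernel parameters for {el}")

    def amplitude(self, element: str) -> float:
        el = element.strip().upper()
        if el in self.table:
            return self.table[el][0]
        z = _ATOMIC_NUMBER.get(el)
        if z is None:
            raise KeyError(f"unknown element {element!r} and no atomic-number fallback")
        a_c, _ = self.table.get("C", _ELEMENT_AMPLITUDES["C"])
        return a_c * z / 6.0

    def amplitudes(self, elements: list[str]) -> np.ndarray:
        return np.array([self.amplitude(e) for e in elements])


DEFAULT_KERNEL_TABLE = KernelTable()


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, label: str | None = None) -> Structure:
    """Read a PDB/mmCIF file; keeps the highest-occupancy altloc per atom."""
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()  # keeps the first (highest-occ) altloc
    model = st[0]
    coords, elements, names, resids, chains = [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name)
                names.append(atom.name)
                resids.append(res.seqid.num)
                chains.append(chain.name)
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    return Structure(
        np.array(coords), elements, names, np.array(resids), chains,
        label=label if label is not None else Path(path).stem,
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a minimal single-model PDB file."""
    st = gemmi.Structure()
    st.name = structure.label or "model"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    last_res_key = None
    res = None
    for i in range(structure.n_atoms):
        cid = structure.chain_ids[i]
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        key = (cid, int(structure.residue_ids[i]))
        if key != last_res_key:
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(int(structure.residue_ids[i]), " ")
            chain_map[cid].add_residue(res)
            last_res_key = key
        atom = gemmi.Atom()
        atom.name = structure.atom_names[i]
        atom.element = gemmi.Element(structure.elements[i])
        atom.pos = gemmi.Position(*structure.coords[i])
        chain_map[cid][-1].add_atom(atom)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Map synthesis
# ---------------------------------------------------------------------------

def molmap_sigma(resolution: float) -> float:
    """Blur-kernel width for reference synthesis: 0.225 x resolution (A)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return MOLMAP_SIGMA_FACTOR * resolution


def _empty_grid(
    lo: np.ndarray, hi: np.ndarray, voxel_size: float, padding: float
) -> DensityMap:
    origin = lo - padding
    n = np.ceil((hi + padding - origin) / voxel_size).astype(int) + 1
    return DensityMap(np.zeros(tuple(n)), origin, voxel_size)


def _accumulate_gaussians(
    grid: DensityMap, coords: np.ndarray, amplitudes: np.ndarray, sigma: float
) -> None:
    """Add normalised per-atom Gaussians (truncated at 4 sigma) in place.

    The Gaussian is separable, so each atom costs three 1-D evaluations and
    one outer product over its local support box.
    """
    values = grid.values
    vs = grid.voxel_size
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    norm = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma**3)
    cutoff = TRUNCATION_SIGMAS * sigma
    shape = grid.shape
    rel = (coords - grid.origin[None, :]) / vs  # fractional voxel coords
    half = cutoff / vs
    los = np.maximum(np.ceil(rel - half).astype(int), 0)
    his = np.minimum(np.floor(rel + half).astype(int), np.array(shape) - 1)
    for a in range(len(coords)):
        lo, hi = los[a], his[a]
        if np.any(lo > hi):
            continue  # atom support entirely outside the grid
        gs = []
        for ax in range(3):
            d = (np.arange(lo[ax], hi[ax] + 1) - rel[a, ax]) * vs
            gs.append(np.exp(-d * d * inv2s2))
        contrib = amplitudes[a] * norm * (
            gs[0][:, None, None] * gs[1][None, :, None] * gs[2][None, None, :]
        )
        values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += contrib


def simulate_model_map(
    structure: Structure,
    grid_of: DensityMap,
    sigma: float,
    kernel_table: KernelTable = DEFAULT_KERNEL_TABLE,
) -> DensityMap:
    """Simulate a structure's density on an existing reference grid."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if structure.n_atoms == 0:
        raise ValueError("structure has no atoms")
    out = grid_of.copy(values=np.zeros(grid_of.shape))
    lo_phys = grid_of.origin
    hi_phys = grid_of.origin + (np.array(grid_of.shape) - 1) * grid_of.voxel_size
    inside = np.all(
        (structure.coords >= lo_phys - TRUNCATION_SIGMAS * sigma)
        & (structure.coords <= hi_phys + TRUNCATION_SIGMAS * sigma),
        axis=1,
    )
    if not inside.any():
        raise ValueError("structure lies entirely outside the map grid")
    amps = kernel_table.amplitudes(structure.elements)
    _accumulate_gaussians(out, structure.coords, amps, sigma)
    return out


def simulate_reference_map(
    structures: list[Structure] | Structure,
    resolution: float,
    voxel_size: float | None = None,
    padding: float | None = None,
    kernel_table: KernelTable = DEFAULT_KERNEL_TABLE,
    grid_of: DensityMap | None = None,
) -> DensityMap:
    """Synthesise a molmap-style map (sigma = 0.225 x resolution).

    For multiple structures the equal-weight average of the per-structure
    maps is returned; population-weighted mixtures go through
    :func:`average_map`.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    if not structures:
        raise ValueError("at least one structure required")
    sigma = molmap_sigma(resolution)
    if grid_of is None:
        if voxel_size is None:
            voxel_size = VOXEL_PER_RESOLUTION * resolution
        if voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if padding is None:
            padding = PADDING_RESOLUTIONS * resolution
        lo, hi = EnsembleSpec(list(structures)).bounding_box()
        grid_of = _empty_grid(lo, hi, voxel_size, padding)
    total = grid_of.copy(values=np.zeros(grid_of.shape))
    for s in structures:
        m = simulate_model_map(s, grid_of, sigma, kernel_table)
        total.values += m.values
    total.values /= len(structures)
    return total


def average_map(models: list[DensityMap], weights) -> DensityMap:
    """Voxel-wise weighted average sum_i w_i rho_i of maps on one grid."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(models) != len(weights):
        raise ValueError("weights length must match number of maps")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalised")
    for i, m in enumerate(models[1:], start=1):
        if not models[0].same_grid(m):
            raise ValueError(f"map {i} is not on the shared grid")
    out = np.zeros(models[0].shape)
    for w, m in zip(weights, models):
        out += w * m.values
    return models[0].copy(values=out)


# ---------------------------------------------------------------------------
# Convenience rigid fit
# ---------------------------------------------------------------------------

def _rotation_grid(n_axis_steps: int = 4) -> list[np.ndarray]:
    """A small deterministic set of rotation matrices (identity first)."""
    from scipy.spatial.transform import Rotation

    mats = [np.eye(3)]
    angles = np.linspace(-np.pi / 6, np.pi / 6, n_axis_steps)
    for ax, ang in itertools.product(range(3), angles):
        if abs(ang) < 1e-12:
            continue
        vec = np.zeros(3)
        vec[ax] = ang
        mats.append(Rotation.from_rotvec(vec).as_matrix())
    return mats


def grid_rigid_fit(
    structure: Structure,
    ref: DensityMap,
    resolution: float,
    max_shift_voxels: int = 2,
    rotations: list[np.ndarray] | None = None,
) -> Structure:
    """Coarse exhaustive rigid fit maximising map correlation.

    Scans integer-voxel translations within ``max_shift_voxels`` and a small
    rotation set; ties resolve to the earliest candidate (identity first), so
    a structure already at the optimum comes back unchanged.  The input is
    never mutated.
    """
    from .metrics import map_cc

    if rotations is None:
        rotations = _rotation_grid()
    sigma = molmap_sigma(resolution)
    shifts = np.arange(-max_shift_voxels, max_shift_voxels + 1) * ref.voxel_size
    # Order translations by distance so ties prefer the smallest move.
    trans = sorted(
        itertools.product(shifts, repeat=3), key=lambda t: (np.dot(t, t), t)
    )
    sel = ref.values.ravel() > ref.values.mean()
    voxel_idx = np.flatnonzero(sel)
    best: tuple[float, int, Structure] | None = None
    for k, (rot, t) in enumerate(itertools.product(rotations, trans)):
        cand = structure.transformed(rot, np.array(t))
        try:
            m = simulate_model_map(cand, ref, sigma)
        except ValueError:
            continue
        cc = map_cc(ref, m, voxel_idx)
        if best is None or cc > best[0] + 1e-12:
            best = (cc, k, cand)
    if best is None:
        raise ValueError("no candidate pose overlapped the map")
    return best[2]
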