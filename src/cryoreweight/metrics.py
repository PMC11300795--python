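"""Evaluation metrics for reweighted ensembles.

Global map similarity (Pearson and overlap correlation), per-residue SMOC
(segment-based Manders overlap), Jensen-Shannon divergence between weighted
ensembles, and weighted dynamics summaries (RMSF and PCA about the weighted
mean conformation).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .density import DensityMap
from .forward import EnsembleSpec, Structure, simulate_model_map

__all__ = [
    "ResidueScoreTrack",
    "EnsembleSummary",
    "map_cc",
    "overlap_cc",
    "smoc",
    "jensen_shannon",
    "ensemble_js_divergence",
    "rmsd",
    "kabsch_superpose",
    "weighted_rmsf",
    "weighted_pca",
]


@dataclasses.dataclass
class ResidueScoreTrack:
    residue_ids: np.ndarray
    scores: np.ndarray
    metric: str
    chain_ids: list[str] | None = None

    def to_tsv(self, path: str | Path) -> None:
        chains = self.chain_ids if self.chain_ids is not None else ["A"] * len(self.residue_ids)
        pd.DataFrame(
            {"chain": chains, "resid": self.residue_ids, "score": self.scores}
        ).to_csv(path, sep="\t", index=False)

    def mean(self) -> float:
        return float(np.mean(self.scores))


@dataclasses.dataclass
class EnsembleSummary:
    rmsf: np.ndarray | None = None
    pcs: np.ndarray | None = None
    variance_fractions: np.ndarray | None = None
    weights: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Map similarity
# ---------------------------------------------------------------------------

def map_cc(a: DensityMap, b: DensityMap, voxels=None) -> float:
    """Pearson correlation of two maps over a voxel index set (flat C-order).

    ``voxels=None`` uses the whole box.
    """
    if not a.same_grid(b):
        raise ValueError("maps must share the grid")
    x = a.values.ravel()
    y = b.values.ravel()
    if voxels is not None:
        voxels = np.asarray(voxels, dtype=np.int64)
        x = x[voxels]
        y = y[voxels]
    if len(x) < 2:
        raise ValueError("need at least two voxels")
    x = x - x.mean()
    y = y - y.mean()
    sx = float(np.dot(x, x))
    sy = float(np.dot(y, y))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance on one of the density vectors")
    return float(np.dot(x, y) / np.sqrt(sx * sy))


def overlap_cc(a: DensityMap, b: DensityMap, voxels=None) -> float:
    """Overlap correlation about zero (no mean subtraction)."""
    if not a.same_grid(b):
        raise ValueError("maps must share the grid")
    x = a.values.ravel()
    y = b.values.ravel()
    if voxels is not None:
        voxels = np.asarray(voxels, dtype=np.int64)
        x = x[voxels]
        y = y[voxels]
    denom = np.sqrt(float(np.dot(x, x)) * float(np.dot(y, y)))
    if denom == 0.0:
        raise ValueError("zero norm on one of the density vectors")
    return float(np.dot(x, y) / denom)


def smoc(
    ref: DensityMap,
    structure: Structure,
    sigma: float,
    radius: float = 5.0,
) -> ResidueScoreTrack:
    """Per-residue Manders overlap between the map and the simulated model.

    For each residue the zone is every voxel within ``radius`` Angstrom of
    any of its atoms; the score is the Manders overlap
    sum(ref * sim) / sqrt(sum ref^2 * sum sim^2) over that zone.  Residues
    whose zone is empty (or has no density on either side) score 0 with a
    warning.
    """
    if structure.n_atoms == 0:
        raise ValueError("structure has no atoms")
    sim = simulate_model_map(structure, ref, sigma)
    xs, ys, zs = ref.voxel_coords()
    resids = np.unique(structure.residue_ids)
    scores = np.zeros(len(resids))
    chain_of: list[str] = []
    for k, rid in enumerate(resids):
        atom_idx = np.flatnonzero(structure.residue_ids == rid)
        chain_of.append(structure.chain_ids[atom_idx[0]])
        mask = np.zeros(ref.shape, dtype=bool)
        for i in atom_idx:
            c = structure.coords[i]
            sel = [
                np.flatnonzero(np.abs(ax - c[d]) <= radius)
                for d, ax in enumerate((xs, ys, zs))
            ]
            if any(len(s) == 0 for s in sel):
                continue
            sub = np.ix_(sel[0], sel[1], sel[2])
            dist2 = (
                (xs[sel[0]][:, None, None] - c[0]) ** 2
                + (ys[sel[1]][None, :, None] - c[1]) ** 2
                + (zs[sel[2]][None, None, :] - c[2]) ** 2
            )
            mask[sub] |= dist2 <= radius**2
        r = ref.values[mask]
        s = sim.values[mask]
        denom = np.sqrt(float(np.sum(r * r)) * float(np.sum(s * s)))
        if mask.sum() == 0 or denom == 0.0:
            warnings.warn(f"residue {rid}: empty or zero-density zone, score 0",
                          stacklevel=2)
            scores[k] = 0.0
        else:
            scores[k] = float(np.sum(r * s) / denom)
    return ResidueScoreTrack(resids, scores, metric="SMOC", chain_ids=chain_of)


# ---------------------------------------------------------------------------
# Distribution similarity
# ---------------------------------------------------------------------------

def jensen_shannon(p, q) -> float:
    """JS divergence (natural log): 0.5 KL(p||m) + 0.5 KL(q||m), m = (p+q)/2."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("distributions must share support length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative probability mass")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} is not normalised")
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def _feature_rmsd_to_reference(ensemble: EnsembleSpec, reference: Structure) -> np.ndarray:
    return np.array([rmsd(s.coords, reference.coords) for s in ensemble.structures])


def ensemble_js_divergence(
    ens_a: EnsembleSpec,
    weights_a,
    ens_b: EnsembleSpec,
    weights_b,
    feature=None,
    bins=None,
    reference: Structure | None = None,
) -> float:
    """JS divergence between two weighted ensembles over a scalar feature.

    The default feature is the Kabsch RMSD of each member to a fixed
    reference structure (the first member of ``ens_a`` unless given); both
    ensembles are histogrammed on a shared grid (Freedman-Diaconis bin width
    on the pooled values unless ``bins`` is supplied) and the weighted
    histograms are compared with :func:`jensen_shannon`.
    """
    if feature is None:
        ref = reference if reference is not None else ens_a.structures[0]
        fa = _feature_rmsd_to_reference(ens_a, ref)
        fb = _feature_rmsd_to_reference(ens_b, ref)
    else:
        fa = np.array([feature(s) for s in ens_a.structures])
        fb = np.array([feature(s) for s in ens_b.structures])
    wa = np.asarray(weights_a, dtype=np.float64)
    wb = np.asarray(weights_b, dtype=np.float64)
    pooled = np.concatenate([fa, fb])
    if bins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        if iqr > 0:
            width = 2 * iqr / len(pooled) ** (1 / 3)
            nbins = max(int(np.ceil((pooled.max() - pooled.min()) / width)), 1)
        else:
            nbins = 10
        bins = np.linspace(pooled.min(), pooled.max() + 1e-12, nbins + 1)
    elif np.isscalar(bins):
        if int(bins) < 1:
            raise ValueError("bins specification must yield at least one bin")
        bins = np.linspace(pooled.min(), pooled.max() + 1e-12, int(bins) + 1)
    bins = np.asarray(bins, dtype=np.float64)
    if len(bins) < 2:
        raise ValueError("bins specification must yield at least one bin")
    ha, _ = np.histogram(fa, bins=bins, weights=wa)
    hb, _ = np.histogram(fb, bins=bins, weights=wb)
    return jensen_shannon(ha / ha.sum(), hb / hb.sum())


# ---------------------------------------------------------------------------
# Weighted dynamics summaries
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     weights: np.ndarray | None = None) -> np.ndarray:
    """Least-squares superposition of one coordinate set onto another."""
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets must share shape")
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    a = mobile - mc
    b = target - tc
    h = (w[:, None] * a).T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return a @ rot.T + tc


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """Coordinate RMSD, by default after Kabsch superposition."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must share shape")
    if superpose:
        a = kabsch_superpose(a, b)
    d = a - b
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def _representative_coords(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """One point per residue: the CA atom when present, else the centroid."""
    resids = np.unique(structure.residue_ids)
    coords = np.zeros((len(resids), 3))
    for k, rid in enumerate(resids):
        idx = np.flatnonzero(structure.residue_ids == rid)
        names = [structure.atom_names[i].strip().upper() for i in idx]
        if "CA" in names:
            coords[k] = structure.coords[idx[names.index("CA")]]
        else:
            coords[k] = structure.coords[idx].mean(axis=0)
    return resids, coords


def _aligned_representative_stack(
    ensemble: EnsembleSpec, weights: np.ndarray, passes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose members' representative atoms onto the weighted mean.

    Iterated weighted least squares: the initial target is the weighted mean
    in the input frame (so the result does not depend on member order), and
    every member is re-superposed onto the current weighted mean for a fixed
    number of passes.  ``passes=0`` trusts the input alignment.
    """
    resids = None
    stacks = []
    for s in ensemble.structures:
        r, c = _representative_coords(s)
        if resids is None:
            resids = r
        elif len(r) != len(resids):
            raise ValueError("members disagree on residue count")
        stacks.append(c)
    coords = np.array(stacks)  # (M, R, 3)
    target = np.einsum("i,ijk->jk", weights, coords)
    for _ in range(passes):
        coords = np.array([kabsch_superpose(c, target) for c in coords])
        target = np.einsum("i,ijk->jk", weights, coords)
    return resids, coords


def weighted_rmsf(
    ensemble: EnsembleSpec, weights, superpose: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue weighted RMSF about the weighted mean conformation (A).

    ``superpose=False`` trusts the input alignment (members already share the
    map frame); note that with superposition a strictly local displacement
    partially redistributes into the fitted translation, as in any global
    least-squares alignment.  Returns ``(residue_ids, rmsf)``.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != ensemble.n_members:
        raise ValueError("weights length must match ensemble size")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalised")
    resids, coords = _aligned_representative_stack(
        ensemble, weights, passes=2 if superpose else 0
    )
    mean = np.einsum("i,ijk->jk", weights, coords)
    dev2 = ((coords - mean[None]) ** 2).sum(axis=2)  # (M, R)
    return resids, np.sqrt(np.einsum("i,ij->j", weights, dev2))


def weighted_pca(
    ensemble: EnsembleSpec, weights, n_components: int = 3, superpose: bool = True
) -> EnsembleSummary:
    """Weighted PCA of superposed representative-atom coordinates.

    Eigendecomposition of the weighted covariance of the flattened (R x 3)
    coordinates; components ordered by variance, each signed so its
    largest-magnitude entry is positive.  ``variance_fractions`` are each
    mode's share of the total positional variance.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != ensemble.n_members:
        raise ValueError("weights length must match ensemble size")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalised")
    _, coords = _aligned_representative_stack(
        ensemble, weights, passes=2 if superpose else 0
    )
    flat = coords.reshape(len(coords), -1)  # (M, 3R)
    if n_components > flat.shape[1]:
        raise ValueError("n_components exceeds coordinate dimensionality")
    mean = weights @ flat
    centred = flat - mean
    cov = (weights[:, None] * centred).T @ centred
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    fractions = evals[:n_components] / total if total > 0 else np.zeros(n_components)
    return EnsembleSummary(
        pcs=evecs[:, :n_components].T,
        variance_fractions=fractions,
        weights=weights,
    )
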