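"""Bayesian ensemble reweighting against cryo-EM voxel data.

The posterior over ensemble weights w combines a Kullback-Leibler prior,
exp(-theta * S_KL) with S_KL = sum_i w_i ln(w_i / w0_i), and a Gaussian voxel
likelihood with residuals rho0_n - alpha * sum_i w_i rho_n^i(sigma) and
variance sigma_L^2.  The negative log-posterior

    f(w) = theta * S_KL(w) + sum_n [rho0_n - alpha * rhobar_n]^2 / (2 sigma_L^2)

is minimised over log-weight coordinates g (w_i = w0_i e^{g_i} / Z, with the
last member gauge-fixed to g_M = 0), which keeps the weights strictly
positive and normalised by construction.  The map scale alpha is profiled
analytically at every evaluation: with rhobar = model_density @ w,
alpha* = (rho0 . rhobar) / (rhobar . rhobar), and by the envelope theorem the
gradient of the profiled objective needs no d(alpha)/dw term.

Two chi-square conventions coexist on purpose: the *reported* misfit is
chi2 = sum r^2 / sigma_L^2 (no half), while the posterior's data term carries
the Gaussian 1/2.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import optimize

from .density import DensityMap, NoiseModel, VoxelSelection, estimate_sigma_L, select_voxels  # noqa: F401  (DensityMap in signatures)

logger = logging.getLogger(__name__)

__all__ = [
    "WeightState",
    "OptimizedWeights",
    "ReweightResult",
    "kl_divergence",
    "effective_sample_size",
    "chi2",
    "optimal_alpha",
    "neg_log_posterior",
    "optimize_weights",
    "scan_sigma_kernel",
    "DEFAULT_SIGMA_FACTORS",
]

_NORM_TOL = 1e-8

#: Kernel-width scan grid as multiples of the nominal resolution.
DEFAULT_SIGMA_FACTORS = (0.2, 0.225, 0.25, 0.3)


def _check_weights(w: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError(f"{name} must be strictly positive")
    if abs(w.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"{name} must be normalised (|sum - 1| <= {_NORM_TOL})")
    return w


@dataclasses.dataclass
class WeightState:
    """Prior and current weights over M ensemble members, tied by log-weights g."""

    w0: np.ndarray
    w: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.w0 = _check_weights(self.w0, "w0")
        self.w = _check_weights(self.w, "w")
        self.g = np.asarray(self.g, dtype=np.float64)
        if not (len(self.w0) == len(self.w) == len(self.g)):
            raise ValueError("w0, w and g must share length")

    @classmethod
    def from_g(cls, g: np.ndarray, w0: np.ndarray) -> "WeightState":
        w0 = _check_weights(np.asarray(w0, dtype=np.float64), "w0")
        g = np.asarray(g, dtype=np.float64)
        logu = np.log(w0) + g
        logu -= logu.max()  # overflow guard; w is shift-invariant in g
        u = np.exp(logu)
        w = u / u.sum()
        # strongly down-weighted members may underflow; weights are never
        # exactly 0 in standard mode, so clamp at a representable floor
        w = np.maximum(w, 1e-300)
        return cls(w0=w0, w=w / w.sum(), g=g)


@dataclasses.dataclass
class OptimizedWeights:
    """Output of a single fixed-theta optimisation."""

    state: WeightState
    alpha: float
    chi2: float
    s_kl: float
    neff: float
    objective: float
    converged: bool
    n_iter: int


@dataclasses.dataclass
class ReweightResult:
    """The full standard-mode result at the selected theta and kernel width."""

    weights: np.ndarray
    theta: float
    alpha: float
    sigma_kernel: float
    sigma_L2: float
    chi2: float
    s_kl: float
    neff: float
    theta_curve: "object" = None  # ThetaCurve; kept loose to avoid an import cycle
    cc: float | None = None

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "alpha": self.alpha,
            "sigma_kernel": self.sigma_kernel,
            "sigma_L2": self.sigma_L2,
            "chi2": self.chi2,
            "s_kl": self.s_kl,
            "neff": self.neff,
            "cc": self.cc,
            "weights": list(map(float, self.weights)),
        }


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------

def kl_divergence(w, w0) -> float:
    """S_KL = sum_i w_i ln(w_i / w0_i), in nats; 0 iff w == w0.

    Weights vanishing to numerical zero contribute via the limit
    x ln x -> 0 rather than NaN.
    """
    w = np.asarray(w, dtype=np.float64)
    w0 = np.asarray(w0, dtype=np.float64)
    if w.shape != w0.shape:
        raise ValueError("w and w0 must share length")
    if np.any(w < 0) or np.any(w0 <= 0):
        raise ValueError("weights must be positive (prior strictly so)")
    for name, v in (("w", w), ("w0", w0)):
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"{name} is not normalised")
    mask = w > 0
    total = float(np.sum(w[mask] * np.log(w[mask] / w0[mask])))
    # KL >= 0 by Gibbs' inequality; rounding near w == w0 can dip a hair below
    return max(total, 0.0)


def effective_sample_size(s_kl: float) -> float:
    """Effective sample fraction Neff = exp(-S_KL), in (0, 1]."""
    if s_kl < 0:
        raise ValueError("S_KL must be non-negative")
    return float(np.exp(-s_kl))


def _weighted_model(sel: VoxelSelection, w: np.ndarray) -> np.ndarray:
    return sel.model_density @ w


def chi2(sel: VoxelSelection, w, alpha: float, sigma_L2: float) -> float:
    """Reported misfit sum_n [rho0_n - alpha rhobar_n]^2 / sigma_L^2 (no 1/2)."""
    if sigma_L2 <= 0:
        raise ValueError("sigma_L2 must be positive")
    w = np.asarray(w, dtype=np.float64)
    r = sel.ref_density - alpha * _weighted_model(sel, w)
    if not np.isfinite(r).all():
        raise ValueError("non-finite densities in the residual")
    return float(np.dot(r, r) / sigma_L2)


def optimal_alpha(sel: VoxelSelection, w) -> float:
    """Least-squares map scale alpha* = (rho0 . rhobar) / (rhobar . rhobar)."""
    rhobar = _weighted_model(sel, np.asarray(w, dtype=np.float64))
    denom = float(np.dot(rhobar, rhobar))
    if denom == 0.0:
        raise ValueError("weighted model density is identically zero")
    alpha = float(np.dot(sel.ref_density, rhobar) / denom)
    if alpha <= 0:
        warnings.warn("profiled map scale alpha is non-positive", stacklevel=2)
    return alpha


# ---------------------------------------------------------------------------
# Objective and optimiser
# ---------------------------------------------------------------------------

def neg_log_posterior(
    g: np.ndarray,
    theta: float,
    sel: VoxelSelection,
    w0,
    sigma_L2: float,
) -> tuple[float, np.ndarray]:
    """Negative log-posterior over full log-weights g, with exact gradient.

    Returns theta * S_KL(w(g)) + chi2(w(g), alpha*(w(g))) / 2 and its
    gradient with respect to g.  alpha is profiled analytically, so the
    gradient contains no d(alpha)/dg term (envelope theorem).
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    g = np.asarray(g, dtype=np.float64)
    if not np.isfinite(g).all():
        raise ValueError("non-finite log-weights")
    state = WeightState.from_g(g, w0)
    w = state.w
    rhobar = _weighted_model(sel, w)
    denom = float(np.dot(rhobar, rhobar))
    if denom == 0.0:
        raise ValueError("weighted model density is identically zero")
    alpha = float(np.dot(sel.ref_density, rhobar) / denom)
    resid = sel.ref_density - alpha * rhobar
    s_kl = kl_divergence(w, state.w0)
    value = theta * s_kl + 0.5 * float(np.dot(resid, resid)) / sigma_L2

    # d f / d w_i, alpha held at its profiled optimum
    dfdw = theta * (np.log(w / state.w0) + 1.0) - (alpha / sigma_L2) * (
        sel.model_density.T @ resid
    )
    # chain rule through the softmax-like map w(g): dw_k/dg_i = w_i (delta - w_k)
    grad = w * (dfdw - float(np.dot(w, dfdw)))
    return value, grad


def optimize_weights(
    sel: VoxelSelection,
    w0,
    theta: float,
    sigma_L2: float,
    g_start: np.ndarray | None = None,
    gtol: float = 1e-8,
    max_iter: int = 10_000,
) -> OptimizedWeights:
    """Minimise the negative log-posterior over gauge-fixed log-weights.

    Quasi-Newton (L-BFGS-B) from g = 0 (or a warm start) with the analytic
    gradient; the last member's log-weight is pinned at 0 to remove the
    normalisation degeneracy.  The returned weights are strictly positive.
    """
    w0 = _check_weights(np.asarray(w0, dtype=np.float64), "w0")
    sel_m = sel.n_models
    if len(w0) != sel_m:
        raise ValueError("w0 length must match the model-density columns")
    if sel_m == 1:
        state = WeightState(w0=np.array([1.0]), w=np.array([1.0]), g=np.zeros(1))
        alpha = optimal_alpha(sel, state.w)
        c2 = chi2(sel, state.w, alpha, sigma_L2)
        return OptimizedWeights(state, alpha, c2, 0.0, 1.0, theta * 0.0 + 0.5 * c2, True, 0)

    def split(free: np.ndarray) -> np.ndarray:
        return np.concatenate([free, [0.0]])

    def fun(free: np.ndarray) -> tuple[float, np.ndarray]:
        value, grad = neg_log_posterior(split(free), theta, sel, w0, sigma_L2)
        return value, grad[:-1]

    x0 = np.zeros(sel_m - 1) if g_start is None else np.asarray(g_start, dtype=np.float64)[:-1]
    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": 1e-12, "maxiter": max_iter, "maxls": 50},
    )
    # The data term scales with N / sigma_L2, so judge the gradient relative
    # to the objective's magnitude rather than by an absolute cutoff alone.
    grad_max = float(np.max(np.abs(res.jac))) if np.ndim(res.jac) else float(abs(res.jac))
    converged = bool(res.success) or grad_max <= 1e-4 * max(1.0, abs(float(res.fun)))
    if not converged:
        raise RuntimeError(
            f"weight optimisation did not converge after {res.nit} iterations "
            f"(|grad|_max = {grad_max:.3e}, f = {float(res.fun):.6g}); "
            f"last iterate g = {np.array2string(np.concatenate([res.x, [0.0]]), precision=4)}"
        )
    g = split(res.x)
    state = WeightState.from_g(g, w0)
    alpha = optimal_alpha(sel, state.w)
    s_kl = kl_divergence(state.w, w0)
    c2 = chi2(sel, state.w, alpha, sigma_L2)
    return OptimizedWeights(
        state=state,
        alpha=alpha,
        chi2=c2,
        s_kl=s_kl,
        neff=effective_sample_size(s_kl),
        objective=float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# Kernel-width scan
# ---------------------------------------------------------------------------

def scan_sigma_kernel(
    ensemble,
    ref: DensityMap,
    sigma_grid,
    noise: NoiseModel | None = None,
    ref_threshold: float | None = None,
    thetas=None,
    sigma_L2: float | None = None,
    kernel_table=None,
):
    """Scan candidate kernel widths; return the best sigma and its artifacts.

    For each candidate the model-density matrix is rebuilt, the theta scan
    rerun and the knee selected; the sigma with the lowest knee chi2 wins,
    ties going to the smaller width.  sigma_L^2 is estimated once from the
    reference map against the first candidate's model maps and reused, so
    candidates compete on the same error scale.

    Returns ``(best_sigma, best_selection, best_result)`` where the result is
    a :class:`ReweightResult` (theta curve attached).
    """
    from .forward import DEFAULT_KERNEL_TABLE, simulate_model_map
    from .thetascan import DEFAULT_THETAS, kneedle_select, scan_thetas

    sigma_grid = sorted(float(s) for s in sigma_grid)
    if not sigma_grid:
        raise ValueError("sigma grid must be non-empty")
    if thetas is None:
        thetas = DEFAULT_THETAS
    if kernel_table is None:
        kernel_table = DEFAULT_KERNEL_TABLE
    structures = ensemble.structures if hasattr(ensemble, "structures") else list(ensemble)
    m = len(structures)
    w0 = np.full(m, 1.0 / m)
    best = None
    for sigma in sigma_grid:
        models = [simulate_model_map(s, ref, sigma, kernel_table) for s in structures]
        sel = select_voxels(ref, models, noise=noise, ref_threshold=ref_threshold)
        sel.sigma_kernel = sigma
        if sigma_L2 is None:
            sigma_L2 = estimate_sigma_L(ref, models)
        curve = scan_thetas(sel, w0, sigma_L2, thetas)
        theta, idx = kneedle_select(curve)
        fit = curve.fits[idx]
        logger.info(
            "sigma=%.4f A: knee theta=%.3g chi2=%.4g neff=%.3f", sigma, theta, fit.chi2, fit.neff
        )
        result = ReweightResult(
            weights=fit.state.w,
            theta=theta,
            alpha=fit.alpha,
            sigma_kernel=sigma,
            sigma_L2=sigma_L2,
            chi2=fit.chi2,
            s_kl=fit.s_kl,
            neff=fit.neff,
            theta_curve=curve,
        )
        if best is None or result.chi2 < best[2].chi2 - 1e-12:
            best = (sigma, sel, result)
    return best
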