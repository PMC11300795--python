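"""Theta scan and automatic L-curve knee selection (Kneedle).

The confidence hyperparameter theta trades misfit against departure from the
prior: chi2(theta) is non-decreasing and S_KL(theta) non-increasing in theta,
so the scanned points trace a proper L-curve.  The knee is found with the
Kneedle construction on (x = S_KL, y = chi2): both axes are min-max
normalised to the unit square, the decreasing curve's vertical distance below
the descending diagonal d_i = (1 - x_i) - y_i is computed, and the knee is
the point maximising d.  That maximiser coincides (up to the sqrt(2) scale)
with the point of maximal perpendicular distance to the chord joining the
curve's endpoints.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .density import VoxelSelection
from .reweight import OptimizedWeights, optimize_weights

__all__ = ["ThetaCurve", "DEFAULT_THETAS", "default_theta_grid", "scan_thetas", "kneedle_knee", "kneedle_select"]


def default_theta_grid() -> np.ndarray:
    """{0} plus ten log-spaced points from 1e-2 to 1e7."""
    return np.concatenate([[0.0], np.logspace(-2, 7, 10)])


DEFAULT_THETAS = default_theta_grid()


@dataclasses.dataclass
class ThetaCurve:
    """Scanned theta grid with per-point fit summaries."""

    thetas: np.ndarray
    chi2s: np.ndarray
    s_kls: np.ndarray
    neffs: np.ndarray
    fits: list[OptimizedWeights]
    selected_index: int | None = None
    selection_method: str = "unselected"

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=np.float64)
        self.chi2s = np.asarray(self.chi2s, dtype=np.float64)
        self.s_kls = np.asarray(self.s_kls, dtype=np.float64)
        self.neffs = np.asarray(self.neffs, dtype=np.float64)
        n = len(self.thetas)
        if not (len(self.chi2s) == len(self.s_kls) == len(self.neffs) == n):
            raise ValueError("curve arrays must share length")
        body = self.thetas[1:] if n and self.thetas[0] == 0.0 else self.thetas
        if np.any(np.diff(body) <= 0):
            raise ValueError("thetas must be strictly increasing (after a leading 0)")

    def __len__(self) -> int:
        return len(self.thetas)

    def to_tsv(self, path: str | Path) -> None:
        sel = np.zeros(len(self), dtype=int)
        if self.selected_index is not None:
            sel[self.selected_index] = 1
        pd.DataFrame(
            {"theta": self.thetas, "chi2": self.chi2s, "s_kl": self.s_kls,
             "neff": self.neffs, "selected": sel}
        ).to_csv(path, sep="\t", index=False)

    def plot(self, path: str | Path) -> None:
        """Optional chi2-vs-S_KL plot with the knee marked (needs matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(self.s_kls, self.chi2s, "o-", label="theta scan")
        if self.selected_index is not None:
            ax.plot(self.s_kls[self.selected_index], self.chi2s[self.selected_index],
                    "r*", markersize=14, label="selected theta")
        ax.set_xlabel(r"$S_{KL}$ (nats)")
        ax.set_ylabel(r"$\chi^2$")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def scan_thetas(
    sel: VoxelSelection,
    w0,
    sigma_L2: float,
    thetas,
) -> ThetaCurve:
    """Run the fixed-theta optimisation over a grid.

    The scan proceeds from large theta (solution near the prior) downward,
    warm-starting each optimisation from the previous solution; results are
    reported in ascending theta order.
    """
    thetas = np.asarray(sorted(float(t) for t in thetas), dtype=np.float64)
    if thetas.size == 0:
        raise ValueError("theta grid must be non-empty")
    if np.any(thetas < 0):
        raise ValueError("theta values must be non-negative")
    fits: dict[float, OptimizedWeights] = {}
    g_warm = None
    for theta in thetas[::-1]:
        try:
            fit = optimize_weights(sel, w0, theta, sigma_L2, g_start=g_warm)
        except Exception as exc:
            raise RuntimeError(f"theta scan failed at theta = {theta:g}: {exc}") from exc
        fits[theta] = fit
        g_warm = fit.state.g
    ordered = [fits[t] for t in thetas]
    return ThetaCurve(
        thetas=thetas,
        chi2s=np.array([f.chi2 for f in ordered]),
        s_kls=np.array([f.s_kl for f in ordered]),
        neffs=np.array([f.neff for f in ordered]),
        fits=ordered,
    )


def kneedle_knee(x, y, candidate=None) -> int | None:
    """The Kneedle construction on a decreasing curve; pure geometry.

    ``x`` ascending, ``y`` decreasing (the L-curve read from high theta to
    low).  Both axes are min-max normalised to the unit square; the knee is
    the point maximising the height below the descending diagonal,
    d_i = (1 - x_n,i) - y_n,i, which coincides (up to sqrt 2) with the point
    of maximal perpendicular distance to the chord joining the endpoints.
    Returns the index into ``x``/``y`` or None when no point lies below the
    diagonal (a straight or degenerate curve has no knee).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if candidate is None:
        candidate = np.ones(len(x), dtype=bool)
    x_span = x[-1] - x[0]
    y_span = y.max() - y.min()
    if x_span <= 0 or y_span <= 0:
        return None
    xn = (x - x[0]) / x_span
    yn = (y - y.min()) / y_span
    diff = (1.0 - xn) - yn
    diff[~candidate] = -np.inf
    best = int(np.argmax(diff))
    if not np.isfinite(diff[best]) or diff[best] <= 1e-12:
        return None
    return best


def kneedle_select(
    curve: ThetaCurve,
    chi2_slack: float = 0.05,
) -> tuple[float, int]:
    """Select theta on the (S_KL, chi2) L-curve.

    The primary choice is the Kneedle knee (:func:`kneedle_knee`) over the
    scanned points, theta = 0 barred from candidacy when its Neff drops
    below 1/M (degenerate overfit guard).  Two corrections wrap it:

    * *no knee* (straight or degenerate curve): fall back to the theta whose
      chi2 lies within ``chi2_slack`` of the scan minimum with maximal Neff
      (``selection_method = "fallback"``).
    * *agreement guard*: when the knee's chi2 exceeds the scan minimum by
      more than ``chi2_slack`` AND near-minimal chi2 is attainable away from
      the unregularised end of the curve, the knee is demoted to the
      maximal-Neff point of that low-chi2 plateau
      (``selection_method = "plateau"``).  On coarse logarithmic theta grids
      the raw difference maximum can land well up the misfit cliff; the
      selected theta must keep good agreement with the data, not only guard
      against overfitting.  The guard is waived when the only near-minimal
      point is the low-theta endpoint itself, where demotion would collapse
      the selection to the unregularised fit.

    Returns ``(theta, index)`` and records the choice on the curve.
    """
    n = len(curve)
    if n < 3:
        raise ValueError("knee detection needs at least 3 scanned points")
    m = len(curve.fits[0].state.w) if curve.fits else None

    candidate = np.ones(n, dtype=bool)
    if m is not None:
        degenerate = (curve.thetas == 0.0) & (curve.neffs < 1.0 / m)
        candidate &= ~degenerate

    # Orient by ascending S_KL (descending theta): y = chi2 decreases.
    order = np.argsort(curve.s_kls, kind="stable")
    knee_local = kneedle_knee(
        curve.s_kls[order], curve.chi2s[order], candidate[order]
    )
    selected = int(order[knee_local]) if knee_local is not None else None
    method = "kneedle"

    chi_min = curve.chi2s[candidate].min()
    plateau = candidate & (curve.chi2s <= chi_min * (1.0 + chi2_slack))
    plateau_idx = np.flatnonzero(plateau)
    target = int(plateau_idx[np.argmax(curve.neffs[plateau_idx])])

    if selected is None:
        selected = target
        method = "fallback"
    elif curve.chi2s[selected] > chi_min * (1.0 + chi2_slack):
        # low-theta endpoint among candidates = the max-S_KL point
        endpoint = int(order[candidate[order].nonzero()[0][-1]])
        if target != endpoint:
            selected = target
            method = "plateau"
    curve.selected_index = selected
    curve.selection_method = method
    return float(curve.thetas[selected]), selected
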