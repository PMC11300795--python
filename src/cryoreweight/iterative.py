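"""Iterative reweighting: repeated reweight -> prune -> reweight rounds.

Standard reweighting never zeroes a weight, so a large prior ensemble keeps
many barely-contributing members.  The iterative mode prunes: after each
round, the ceil(Neff x M) members with the highest weights form a new
sub-ensemble which is treated as a fresh prior with uniform weights and put
through the full theta-scan pipeline again.  Rounds continue until the
knee-selected chi2 increases (the previous round is returned) or the
selection stops shrinking, yielding a minimal set of structures that still
explains the map.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityMap, NoiseModel, estimate_sigma_L, select_voxels
from .reweight import ReweightResult
from .thetascan import DEFAULT_THETAS, kneedle_select, scan_thetas

logger = logging.getLogger(__name__)

__all__ = ["RoundRecord", "IterationTrace", "select_subensemble", "iterative_reweight"]

#: Never prune below this many members; a 1-member "ensemble" is a single
#: structure, which the trace reports rather than iterates.
MIN_SUBENSEMBLE = 2


@dataclasses.dataclass
class RoundRecord:
    """One round of the iterative protocol (indices refer to the full ensemble)."""

    member_ids: np.ndarray
    n_members: int
    theta: float
    chi2: float
    s_kl: float
    neff: float
    cc: float | None
    weights: np.ndarray
    alpha: float


@dataclasses.dataclass
class IterationTrace:
    rounds: list[RoundRecord]
    final_round: int
    stop_reason: str

    @property
    def final(self) -> RoundRecord:
        return self.rounds[self.final_round]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "round": i,
                    "members_kept": r.n_members,
                    "theta": r.theta,
                    "chi2": r.chi2,
                    "s_kl": r.s_kl,
                    "neff": r.neff,
                    "cc": r.cc if r.cc is not None else float("nan"),
                }
                for i, r in enumerate(self.rounds)
            ]
        ).to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "final_round": self.final_round,
            "stop_reason": self.stop_reason,
            "rounds": [
                {
                    "member_ids": list(map(int, r.member_ids)),
                    "theta": r.theta,
                    "chi2": r.chi2,
                    "s_kl": r.s_kl,
                    "neff": r.neff,
                    "cc": r.cc,
                    "weights": list(map(float, r.weights)),
                }
                for r in self.rounds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def select_subensemble(w, neff: float) -> np.ndarray:
    """Indices of the ceil(neff x M) largest weights (ties -> lower index).

    The kept set never shrinks below :data:`MIN_SUBENSEMBLE`.
    """
    w = np.asarray(w, dtype=np.float64)
    m = len(w)
    if m < 2:
        raise ValueError("need at least two members to select from")
    if not (0 < neff <= 1):
        raise ValueError("neff must lie in (0, 1]")
    k = max(int(np.ceil(neff * m)), MIN_SUBENSEMBLE)
    k = min(k, m)
    # stable sort on -w keeps lower indices first among ties
    order = np.argsort(-w, kind="stable")
    return np.sort(order[:k])


def iterative_reweight(
    ensemble,
    ref: DensityMap,
    resolution: float | None = None,
    sigma: float | None = None,
    noise: NoiseModel | None = None,
    ref_threshold: float | None = None,
    thetas=None,
    sigma_L2: float | None = None,
    model_maps: list[DensityMap] | None = None,
    max_rounds: int = 50,
    compute_cc: bool = True,
) -> tuple[IterationTrace, ReweightResult]:
    """Run the iterative protocol and return the trace plus the final result.

    Round 0 is a standard run on the full ensemble (kernel width ``sigma``,
    or 0.225 x resolution when only a resolution is given).  Each later round
    restricts the cached model maps to the kept members, resets the prior to
    uniform over them, re-selects voxels and reruns the theta scan.  The
    noise variance sigma_L^2 is estimated once, in round 0, and reused.
    """
    from .forward import average_map, molmap_sigma, simulate_model_map
    from .metrics import map_cc

    structures = ensemble.structures if hasattr(ensemble, "structures") else list(ensemble)
    m_total = len(structures)
    if m_total < 2:
        raise ValueError("iterative mode needs at least two ensemble members")
    if sigma is None:
        if resolution is None:
            raise ValueError("provide sigma or resolution")
        sigma = molmap_sigma(resolution)
    if thetas is None:
        thetas = DEFAULT_THETAS
    if model_maps is None:
        model_maps = [simulate_model_map(s, ref, sigma) for s in structures]
    if sigma_L2 is None:
        sigma_L2 = estimate_sigma_L(ref, model_maps)

    def run_round(member_ids: np.ndarray) -> RoundRecord:
        maps = [model_maps[i] for i in member_ids]
        sel = select_voxels(ref, maps, noise=noise, ref_threshold=ref_threshold)
        sel.sigma_kernel = sigma
        m = len(member_ids)
        w0 = np.full(m, 1.0 / m)
        curve = scan_thetas(sel, w0, sigma_L2, thetas)
        theta, idx = kneedle_select(curve)
        fit = curve.fits[idx]
        cc = None
        if compute_cc:
            post = average_map(maps, fit.state.w)
            cc = map_cc(ref, post, sel.indices)
        return RoundRecord(
            member_ids=np.asarray(member_ids, dtype=np.int64),
            n_members=m,
            theta=theta,
            chi2=fit.chi2,
            s_kl=fit.s_kl,
            neff=fit.neff,
            cc=cc,
            weights=fit.state.w,
            alpha=fit.alpha,
        )

    rounds: list[RoundRecord] = []
    member_ids = np.arange(m_total)
    stop_reason = "max_rounds"
    record = run_round(member_ids)
    rounds.append(record)
    for _ in range(max_rounds):
        current = rounds[-1]
        if current.n_members <= MIN_SUBENSEMBLE:
            stop_reason = "minimum ensemble size reached"
            break
        kept_local = select_subensemble(current.weights, current.neff)
        kept = current.member_ids[kept_local]
        if len(kept) >= current.n_members:
            stop_reason = "selection no longer shrinks (prior sufficient)"
            break
        try:
            nxt = run_round(kept)
        except Exception as exc:  # a failed round keeps the last good one
            stop_reason = f"round failed ({exc}); last good round returned"
            logger.warning(stop_reason)
            break
        if nxt.chi2 > current.chi2:
            rounds.append(nxt)
            stop_reason = "chi2 increased; previous round accepted"
            final = len(rounds) - 2
            trace = IterationTrace(rounds, final, stop_reason)
            return trace, _result_from(trace, sigma, sigma_L2)
        rounds.append(nxt)
    trace = IterationTrace(rounds, len(rounds) - 1, stop_reason)
    return trace, _result_from(trace, sigma, sigma_L2)


def _result_from(trace: IterationTrace, sigma: float, sigma_L2: float) -> ReweightResult:
    r = trace.final
    return ReweightResult(
        weights=r.weights,
        theta=r.theta,
        alpha=r.alpha,
        sigma_kernel=sigma,
        sigma_L2=sigma_L2,
        chi2=r.chi2,
        s_kl=r.s_kl,
        neff=r.neff,
        cc=r.cc,
    )
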