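"""Long-only mean-variance optimization over land-use options.

The decision variable is the land share f_i >= 0 of each option, with
sum_i f_i = 1 (the whole farm is allocated).  Expected portfolio return is
R_p = sum_i f_i r_i and portfolio risk is the standard deviation
sigma_p = sqrt(sum_ij f_i f_j rho_ij s_i s_j).

Three problems are solved exactly:

* minimum-variance portfolio,
* minimum variance subject to a return floor (QP with linear constraints),
* maximum return subject to a risk cap (convex QCQP, solved by bisection on
  the return floor of the previous problem — sigma_min(floor) is
  nondecreasing in the floor, so the largest floor whose minimal risk fits
  under the cap is the risk-capped return maximum).

The QP is solved by face enumeration: for every support set of nonzero
weights the equality-constrained stationary point is computed from its KKT
system, and the best primal-feasible candidate wins.  For the asset counts
of land-use planning (here 8) this is exact, fast and deterministic — no
iterative solver tolerances enter the results.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import AssetStatsSet, CorrelationMatrix

__all__ = [
    "PortfolioWeights",
    "FrontierPoint",
    "InfeasibleProblem",
    "portfolio_return",
    "portfolio_sd",
    "covariance_matrix",
    "min_variance",
    "min_risk_at_return",
    "max_return_at_risk",
    "trace_frontier",
    "composition_frame",
]

WEIGHT_TOL = 1e-8
REPORT_TOL = 5e-4  # weights below this are reported as 0 in tables


class InfeasibleProblem(ValueError):
    """Raised when constraints admit no fully-invested long-only portfolio."""


@dataclass(frozen=True)
class PortfolioWeights:
    """Land shares f_i >= 0 summing to one, in a fixed crop order."""

    crop_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.crop_ids):
            raise ValueError("weights and crop_ids must align")
        if np.any(v < -WEIGHT_TOL):
            raise ValueError("weights must be nonnegative")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        v = np.clip(v, 0.0, None)
        object.__setattr__(self, "crop_ids", tuple(self.crop_ids))
        object.__setattr__(self, "values", v / v.sum())

    def as_dict(self, drop_zero: bool = True) -> dict[str, float]:
        return {
            c: float(w)
            for c, w in zip(self.crop_ids, self.values)
            if not drop_zero or w > REPORT_TOL
        }


@dataclass(frozen=True)
class FrontierPoint:
    """An optimal portfolio: weights plus its return/SD coordinates."""

    weights: PortfolioWeights
    expected_return: float
    sd: float
    risk_cap: float | None = None


def covariance_matrix(stats: AssetStatsSet, corr: CorrelationMatrix) -> np.ndarray:
    """cov_ij = rho_ij s_i s_j, aligned on the stats' crop order."""
    if set(stats.crop_ids) != set(corr.crop_ids):
        raise ValueError("stats and correlation matrix cover different crops")
    corr = corr.subset(list(stats.crop_ids))
    if not corr.is_psd():
        corr = corr.repaired()
    return corr.values * np.outer(stats.sds, stats.sds)


def portfolio_return(w: PortfolioWeights, stats: AssetStatsSet) -> float:
    if w.crop_ids != stats.crop_ids:
        raise ValueError("weights and stats cover different crops")
    return float(w.values @ stats.means)


def portfolio_sd(
    w: PortfolioWeights, stats: AssetStatsSet, corr: CorrelationMatrix
) -> float:
    cov = covariance_matrix(stats, corr)
    if w.crop_ids != stats.crop_ids:
        raise ValueError("weights and stats cover different crops")
    return float(np.sqrt(max(w.values @ cov @ w.values, 0.0)))


# ---------------------------------------------------------------------------
# Exact QP on the simplex


class _FaceSolver:
    """Exact simplex-constrained QP by face enumeration.

    For every support set S of nonzero weights the equality-constrained
    stationary point is computed from its KKT system.  Without a return
    floor that point is fixed; with an *active* floor ``means @ w = floor``
    the KKT right-hand side is affine in the floor, hence so is the
    stationary point: w(floor) = u_S + floor * v_S.  Both pieces are
    precomputed once, so sweeping floors (frontier tracing, bisection on a
    risk cap) costs only feasibility checks.  All candidates are primal
    feasible, so the minimum-variance candidate is the global optimum.
    """

    def __init__(self, cov: np.ndarray, means: np.ndarray | None = None):
        self.cov = cov
        self.means = means
        n = cov.shape[0]
        scale = max(float(np.abs(cov).max()), 1.0)
        self.plain: list[tuple[list[int], np.ndarray]] = []  # (S, w)
        self.affine: list[tuple[list[int], np.ndarray, np.ndarray]] = []  # (S, u, v)
        for r in range(1, n + 1):
            for S in itertools.combinations(range(n), r):
                S = list(S)
                k = len(S)
                A = np.zeros((k + 1, k + 1))
                A[:k, :k] = 2.0 * cov[np.ix_(S, S)] / scale
                A[:k, k] = -1.0
                A[k, :k] = 1.0
                b = np.zeros(k + 1)
                b[k] = 1.0
                try:
                    w_S = np.linalg.solve(A, b)[:k]
                except np.linalg.LinAlgError:
                    w_S = None
                if w_S is not None and np.all(np.isfinite(w_S)) and w_S.min() > -1e-9:
                    self.plain.append((S, w_S))
                if means is None:
                    continue
                Af = np.zeros((k + 2, k + 2))
                Af[:k, :k] = 2.0 * cov[np.ix_(S, S)] / scale
                Af[:k, k] = -1.0
                Af[k, :k] = 1.0
                Af[:k, k + 1] = -means[S]
                Af[k + 1, :k] = means[S]
                rhs = np.zeros((k + 2, 2))
                rhs[k, 0] = 1.0  # budget
                rhs[k + 1, 1] = 1.0  # unit return floor
                try:
                    sol = np.linalg.solve(Af, rhs)
                except np.linalg.LinAlgError:
                    continue
                if np.all(np.isfinite(sol)):
                    self.affine.append((S, sol[:k, 0], sol[:k, 1]))

    def _finish(self, S: list[int], w_S: np.ndarray) -> np.ndarray | None:
        w = np.zeros(self.cov.shape[0])
        w[S] = np.clip(w_S, 0.0, None)
        s = w.sum()
        if s <= 0:
            return None
        return w / s

    def solve(self, floor: float | None = None) -> np.ndarray | None:
        """Best feasible face candidate; None if the floor is unreachable."""
        best_w, best_v = None, np.inf
        for S, w_S in self.plain:
            w = self._finish(S, w_S)
            if w is None:
                continue
            if floor is not None:
                if self.means @ w < floor - 1e-7 * max(1.0, abs(floor)):
                    continue
            v = float(w @ self.cov @ w)
            if v < best_v - 1e-15 * (abs(v) + 1.0):
                best_v, best_w = v, w
        if floor is not None:
            for S, u, vdir in self.affine:
                w_S = u + floor * vdir
                if w_S.min() < -1e-9:
                    continue
                w = self._finish(S, w_S)
                if w is None:
                    continue
                if self.means @ w < floor - 1e-7 * max(1.0, abs(floor)):
                    continue
                v = float(w @ self.cov @ w)
                if v < best_v - 1e-15 * (abs(v) + 1.0):
                    best_v, best_w = v, w
        return best_w


def _qp_min_variance(
    cov: np.ndarray, means: np.ndarray | None = None, floor: float | None = None
) -> np.ndarray | None:
    return _FaceSolver(cov, means if floor is not None else None).solve(floor)


def _point(
    w: np.ndarray,
    stats: AssetStatsSet,
    cov: np.ndarray,
    risk_cap: float | None = None,
) -> FrontierPoint:
    pw = PortfolioWeights(stats.crop_ids, w)
    return FrontierPoint(
        weights=pw,
        expected_return=float(w @ stats.means),
        sd=float(np.sqrt(max(w @ cov @ w, 0.0))),
        risk_cap=risk_cap,
    )


def min_variance(stats: AssetStatsSet, corr: CorrelationMatrix) -> FrontierPoint:
    """Global minimum-risk fully-invested long-only portfolio."""
    if len(stats.crop_ids) == 0:
        raise InfeasibleProblem("no assets")
    cov = covariance_matrix(stats, corr)
    w = _qp_min_variance(cov)
    return _point(w, stats, cov)


def min_risk_at_return(
    stats: AssetStatsSet, corr: CorrelationMatrix, return_floor: float
) -> FrontierPoint:
    """Minimize sigma_p subject to R_p >= return_floor."""
    cov = covariance_matrix(stats, corr)
    if return_floor > stats.means.max() + 1e-9:
        raise InfeasibleProblem(
            f"return floor {return_floor} exceeds best single-option mean "
            f"{stats.means.max():.1f}"
        )
    w = _qp_min_variance(cov, stats.means, floor=return_floor)
    if w is None:
        raise InfeasibleProblem(f"return floor {return_floor} unreachable")
    return _point(w, stats, cov)


def max_return_at_risk(
    stats: AssetStatsSet,
    corr: CorrelationMatrix,
    risk_cap: float,
    bisection_iters: int = 60,
) -> FrontierPoint:
    """Maximize R_p subject to sigma_p <= risk_cap.

    Solved through the return-floor QP: sigma_min(floor) is nondecreasing,
    so bisection on the floor finds the highest return whose minimum risk
    still fits under the cap.  The solution inherits the QP's minimum
    variance property, which also breaks return ties toward lower risk.
    """
    cov = covariance_matrix(stats, corr)
    solver = _FaceSolver(cov, stats.means)
    return _max_return_with_solver(solver, stats, cov, risk_cap, bisection_iters)


def _max_return_with_solver(
    solver: "_FaceSolver",
    stats: AssetStatsSet,
    cov: np.ndarray,
    risk_cap: float,
    bisection_iters: int = 60,
) -> FrontierPoint:
    base = solver.solve()
    lo = float(stats.means @ base)
    if np.sqrt(base @ cov @ base) > risk_cap + 1e-9:
        raise InfeasibleProblem(
            f"risk cap {risk_cap} below the minimum attainable SD "
            f"{float(np.sqrt(base @ cov @ base)):.2f}"
        )
    hi = float(stats.means.max())
    for _ in range(bisection_iters):
        mid = (lo + hi) / 2.0
        w = solver.solve(floor=mid)
        if w is not None and np.sqrt(w @ cov @ w) <= risk_cap:
            lo = mid
        else:
            hi = mid
    w = solver.solve(floor=lo)
    return _point(w, stats, cov, risk_cap=risk_cap)


def trace_frontier(
    stats: AssetStatsSet,
    corr: CorrelationMatrix,
    risk_caps: np.ndarray | list[float],
) -> list[FrontierPoint]:
    """One risk-capped optimum per feasible cap; infeasible caps are skipped."""
    caps = np.asarray(risk_caps, dtype=float)
    if np.any(np.diff(caps) < 0):
        raise ValueError("risk caps must be sorted ascending")
    cov = covariance_matrix(stats, corr)
    solver = _FaceSolver(cov, stats.means)
    points = []
    for cap in caps:
        try:
            points.append(_max_return_with_solver(solver, stats, cov, float(cap)))
        except InfeasibleProblem as exc:
            warnings.warn(f"risk cap {cap:g} infeasible: {exc}", stacklevel=2)
    return points


def composition_frame(points: list[FrontierPoint]) -> pd.DataFrame:
    """Composition table: cap, return, SD and one weight column per crop.

    Weights below 0.05% are reported as zero, matching whole-percent
    reporting granularity.
    """
    if not points:
        return pd.DataFrame()
    ids = points[0].weights.crop_ids
    rows = []
    for p in points:
        row = {
            "risk_cap": p.risk_cap if p.risk_cap is not None else np.nan,
            "expected_return": p.expected_return,
            "sd": p.sd,
        }
        for c, w in zip(ids, p.weights.values):
            row[c] = 0.0 if w <= REPORT_TOL else float(w)
        rows.append(row)
    return pd.DataFrame(rows)
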