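"""The e-geodesic between the S5 and S6 projections and its optimisation.

The exponential-family path between the two projections interpolates the
precision matrices linearly,

    Sigma_t^{-1} = (1 - t) Sigma5^{-1} + t Sigma6^{-1},

and is a valid Gaussian wherever that mixture is positive definite.  The
synergy objective g(t) = D(p || p_t) is strictly convex on the feasible
interval whenever the joint mutual information is positive, so the
minimiser t* is unique and a bounded scalar search suffices.

The target-block determinant

    d(t) = | I - t^2 Q'Q - t(1-t)(R'P'Q + Q'PR) - (1-t)^2 R'R |

satisfies |(1-t) Sigma6 + t Sigma5| = |I - P'P| d(t) on the feasible
interval and carries the shared information: Shd = 0.5 log(1/d(t*)).
Note the orientation: at t = 0 the mixture is Sigma6, so d(0) = |I - R'R|,
and d(1) = |I - Q'Q|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import minimize_scalar

from .core import (
    CrossCorrelationSystem,
    NotPositiveDefiniteError,
    assemble_sigma,
    chol_logdet,
)
from .projections import project

__all__ = [
    "FeasibleInterval",
    "GeodesicSolution",
    "sigma_t",
    "sigma_t_prime",
    "feasible_interval",
    "d_determinant",
    "synergy_objective",
    "optimize_t",
]

#: Cap applied to an unbounded side of the feasible interval before bracketing.
UNBOUNDED_CAP = 1e6

#: Relative shrink applied at each endpoint so g is only evaluated where PD holds.
ENDPOINT_EPS = 1e-9


@dataclass(frozen=True)
class FeasibleInterval:
    """Interval of geodesic parameters t for which Sigma_t is positive definite.

    Whenever the S5 and S6 projections differ the interval has the form
    [-a, 1+b] with a, b > 0, so [0, 1] lies strictly inside.  The ``open``
    flag records that positive definiteness fails at the endpoints
    themselves, which are therefore excluded from optimisation.
    """

    lower: float
    upper: float
    open: bool = True

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def shrunk(self) -> tuple[float, float]:
        """Endpoints pulled inside by a relative margin for safe evaluation."""
        eps = ENDPOINT_EPS * min(self.width, UNBOUNDED_CAP)
        return self.lower + eps, self.upper - eps

    def contains(self, t: float) -> bool:
        return self.lower < t < self.upper


@dataclass(frozen=True)
class GeodesicSolution:
    """Result of minimising the synergy objective along the geodesic."""

    t_star: float
    g_min: float
    d_star: float
    at_endpoint: bool
    interval: FeasibleInterval


def sigma_t(t: float, sigma5: np.ndarray, sigma6: np.ndarray) -> np.ndarray:
    """Covariance at parameter t on the e-geodesic from Sigma5 (t=0) to Sigma6 (t=1)."""
    k5 = _pd_inverse(sigma5, "Sigma5")
    k6 = _pd_inverse(sigma6, "Sigma6")
    precision = (1.0 - t) * k5 + t * k6
    return _pd_inverse(precision, f"geodesic precision at t={t}", infeasible=True)


def sigma_t_prime(t: float, sigma5: np.ndarray, sigma6: np.ndarray) -> np.ndarray:
    """The companion matrix whose inverse is the covariance mixture (1-t)Sigma6 + t Sigma5."""
    mixture = (1.0 - t) * sigma6 + t * sigma5
    return _pd_inverse(mixture, f"covariance mixture at t={t}", infeasible=True)


def _pd_inverse(a: np.ndarray, what: str, infeasible: bool = False) -> np.ndarray:
    a = (a + a.T) / 2.0
    try:
        chol = linalg.cho_factor(a, lower=True)
    except linalg.LinAlgError:
        msg = f"{what} is not positive definite"
        if infeasible:
            msg += " (t outside the feasible interval)"
        raise NotPositiveDefiniteError(msg) from None
    inv = linalg.cho_solve(chol, np.eye(a.shape[0]))
    return (inv + inv.T) / 2.0


def _interval_from_pencil(base: np.ndarray, direction: np.ndarray) -> tuple[float, float]:
    """Feasible t for PD of ``base + t * direction`` given ``base`` PD.

    Positive definiteness holds iff 1 + t*lam > 0 for every generalized
    eigenvalue lam of (direction, base).
    """
    lam = linalg.eigh(direction, base, eigvals_only=True)
    lam_max, lam_min = float(lam.max()), float(lam.min())
    lower = -1.0 / lam_max if lam_max > 1e-14 else -UNBOUNDED_CAP
    upper = -1.0 / lam_min if lam_min < -1e-14 else UNBOUNDED_CAP
    return lower, upper


def feasible_interval(sigma5: np.ndarray, sigma6: np.ndarray) -> FeasibleInterval:
    """Compute the feasible interval F = {t : (1-t)Sigma5^-1 + t Sigma6^-1 is PD}.

    Computed from the generalized eigenvalues of the precision pencil, then
    cross-checked against the covariance-mixture pencil (the two feasible
    sets coincide) and confirmed by Cholesky just inside each endpoint.
    Raises if the projections coincide (degenerate geodesic, which happens
    exactly when the joint mutual information vanishes).
    """
    if np.allclose(sigma5, sigma6, atol=1e-12):
        raise ValueError(
            "S5 and S6 projections coincide (zero joint mutual information); "
            "the geodesic is degenerate"
        )
    k5 = _pd_inverse(sigma5, "Sigma5")
    k6 = _pd_inverse(sigma6, "Sigma6")
    lower, upper = _interval_from_pencil(k5, k6 - k5)
    # the covariance mixture (1-t)Sigma6 + t Sigma5 must give the same set
    lo2, up2 = _interval_from_pencil(sigma6, sigma5 - sigma6)
    if not (np.isclose(lower, lo2, rtol=1e-6, atol=1e-9) and np.isclose(upper, up2, rtol=1e-6, atol=1e-9)):
        raise AssertionError(
            f"precision and covariance feasible sets disagree: "
            f"({lower}, {upper}) vs ({lo2}, {up2})"
        )
    interval = FeasibleInterval(lower=lower, upper=upper)
    for t in interval.shrunk():
        sigma_t(t, sigma5, sigma6)  # Cholesky confirmation just inside F
    return interval


def d_determinant(t: float, sys: CrossCorrelationSystem) -> float:
    """The target-block determinant d(t) along the geodesic."""
    q, r, p = sys.q, sys.r, sys.p
    n3 = sys.blocks.n3
    cross = r.T @ p.T @ q
    mat = (
        np.eye(n3)
        - t**2 * (q.T @ q)
        - t * (1.0 - t) * (cross + cross.T)
        - (1.0 - t) ** 2 * (r.T @ r)
    )
    return float(np.linalg.det(mat))


class _GeodesicProblem:
    """Cached quantities for repeated evaluation of g(t) on one system."""

    def __init__(self, sys: CrossCorrelationSystem):
        self.sys = sys
        self.sigma = assemble_sigma(sys)
        self.sigma5 = project(sys, 5)
        self.sigma6 = project(sys, 6)
        n2, n3 = sys.blocks.n2, sys.blocks.n3
        logdet_pp = chol_logdet(np.eye(n2) - sys.p.T @ sys.p, "I - P'P")
        logdet_qq = chol_logdet(np.eye(n3) - sys.q.T @ sys.q, "I - Q'Q")
        logdet_rr = chol_logdet(np.eye(n3) - sys.r.T @ sys.r, "I - R'R")
        logdet_sigma = chol_logdet(self.sigma, "Sigma")
        # constant part of g(t): 0.5 log(|I-P'P|^2 |I-Q'Q| |I-R'R| / |Sigma|)
        self.constant = 0.5 * (2.0 * logdet_pp + logdet_qq + logdet_rr - logdet_sigma)

    def g(self, t: float) -> float:
        mixture = (1.0 - t) * self.sigma6 + t * self.sigma5
        return self.constant - 0.5 * chol_logdet(mixture, f"covariance mixture at t={t}")

    def interval(self) -> FeasibleInterval:
        return feasible_interval(self.sigma5, self.sigma6)


def synergy_objective(t: float, sys: CrossCorrelationSystem) -> float:
    """The objective g(t) = D(p || p_t), evaluated in closed form.

    Equals the Gaussian KL divergence from the full system to the geodesic
    point at t; raises outside the feasible interval.
    """
    return _GeodesicProblem(sys).g(t)


def optimize_t(
    sys: CrossCorrelationSystem,
    xatol: float = 1e-12,
    max_iter: int = 1000,
) -> GeodesicSolution:
    """Minimise g over the feasible interval by bounded scalar minimisation.

    Strict convexity (positive joint mutual information assumed; the
    degenerate case is handled by the caller) guarantees a unique interior
    or endpoint minimiser.  If the search lands on a shrunken endpoint both
    ends are compared and the smaller is returned with ``at_endpoint`` set.
    Interior optima are certified by the first-order trace conditions
    trace(Sigma5^-1 Sigma_t*) = trace(Sigma6^-1 Sigma_t*) = m.
    """
    problem = _GeodesicProblem(sys)
    interval = problem.interval()
    lo, hi = interval.shrunk()
    result = minimize_scalar(
        problem.g,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol, "maxiter": max_iter},
    )
    if not result.success:
        raise RuntimeError(
            f"geodesic optimisation failed to converge: {result.message} "
            f"(interval=({interval.lower}, {interval.upper}), last t={result.x})"
        )
    t_star = float(result.x)
    g_min = float(result.fun)

    at_endpoint = False
    margin = 1e-6 * min(interval.width, 2.0 * UNBOUNDED_CAP)
    if t_star - lo < margin or hi - t_star < margin:
        g_lo, g_hi = problem.g(lo), problem.g(hi)
        if min(g_lo, g_hi) <= g_min:
            t_star, g_min = (lo, g_lo) if g_lo <= g_hi else (hi, g_hi)
        at_endpoint = True
    else:
        _certify_interior(problem, t_star)

    return GeodesicSolution(
        t_star=t_star,
        g_min=g_min,
        d_star=d_determinant(t_star, sys),
        at_endpoint=at_endpoint,
        interval=interval,
    )


def _certify_interior(problem: _GeodesicProblem, t_star: float) -> None:
    """First-order optimality: both endpoint precisions trace to m at t*."""
    m = problem.sys.blocks.m
    st = sigma_t(t_star, problem.sigma5, problem.sigma6)
    for sigma, label in ((problem.sigma5, "Sigma5"), (problem.sigma6, "Sigma6")):
        trace = float(np.trace(linalg.solve(sigma, st, assume_a="pos")))
        if abs(trace - m) > 1e-5 * m:
            raise RuntimeError(
                f"interior optimum failed the {label} trace certificate: "
                f"trace={trace}, expected {m} (t*={t_star})"
            )
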