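"""Assembly of the partial information decomposition.

Two decompositions are provided for a standardised Gaussian system with two
vector sources and a vector target:

``pid_ig``
    The information-geometric PID.  Shared information is read off the
    geodesic optimum, Shd = 0.5 log(1/d(t*)); the unique informations follow
    from the consistency equations Unq_k = I[Xk;X3] - Shd, and synergy is
    the residual KL divergence from the full system to the geodesic point,
    Syn = D(p || p_t*).

``pid_mmi``
    The minimum-mutual-information baseline: shared information is the
    smaller of the two source-target mutual informations, which forces at
    least one unique component to zero.

Both satisfy the Williams-Beer consistency equations

    I[X1;X3] = Unq1 + Shd          I[X1;X3|X2] = Unq1 + Syn
    I[X2;X3] = Unq2 + Shd          I[X2;X3|X1] = Unq2 + Syn
    I[X1,X2;X3] = Syn + Unq1 + Unq2 + Shd
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import (
    CrossCorrelationSystem,
    MIProfile,
    assemble_sigma,
    kl_gaussian,
    mutual_informations,
)
from .geodesic import optimize_t, sigma_t
from .projections import project

__all__ = ["PIDResult", "pid_ig", "pid_mmi", "as_percentages", "property_suite"]

#: Components more negative than this indicate a broken optimum, not roundoff.
NEGATIVE_RESIDUE_TOL = 1e-8

#: Joint MI below this is treated as exactly zero (degenerate system).
DEGENERATE_JOINT_MI = 1e-12

LN2 = math.log(2.0)


@dataclass(frozen=True)
class PIDResult:
    """The four PID components plus provenance and diagnostics.

    Components are nonnegative and satisfy the consistency equations against
    ``mi`` to within numerical tolerance.  ``t_star`` is ``None`` for
    methods without a geodesic parameter and for degenerate systems.
    """

    syn: float
    unq1: float
    unq2: float
    shd: float
    mi: MIProfile
    method: str
    units: str = "nats"
    t_star: float | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def components(self) -> dict[str, float]:
        return {"syn": self.syn, "unq1": self.unq1, "unq2": self.unq2, "shd": self.shd}

    def in_bits(self) -> "PIDResult":
        """Rescale all information quantities from nats to bits."""
        if self.units == "bits":
            return self
        mi = MIProfile(**{k: v / LN2 for k, v in vars(self.mi).items()})
        return PIDResult(
            syn=self.syn / LN2,
            unq1=self.unq1 / LN2,
            unq2=self.unq2 / LN2,
            shd=self.shd / LN2,
            mi=mi,
            method=self.method,
            units="bits",
            t_star=self.t_star,
            diagnostics=self.diagnostics,
        )


def _clip(value: float, label: str) -> float:
    if value < -NEGATIVE_RESIDUE_TOL:
        raise RuntimeError(
            f"PID component {label} = {value} is negative beyond numerical "
            "tolerance; the geodesic optimum is inconsistent"
        )
    return max(value, 0.0)


def _zero_result(mi: MIProfile, method: str) -> PIDResult:
    return PIDResult(syn=0.0, unq1=0.0, unq2=0.0, shd=0.0, mi=mi, method=method,
                     diagnostics={"degenerate": True})


def pid_ig(sys: CrossCorrelationSystem) -> PIDResult:
    """Information-geometric PID of a standardised Gaussian system.

    Runs the geodesic optimisation, assembles the components from the
    closed forms, and cross-validates each against its defining KL
    divergence (residuals are recorded in ``diagnostics``).
    """
    mi = mutual_informations(sys)
    if mi.joint < DEGENERATE_JOINT_MI:
        return _zero_result(mi, "iig")

    sol = optimize_t(sys)
    shd = -0.5 * math.log(sol.d_star)
    unq1 = mi.i13 - shd
    unq2 = mi.i23 - shd
    syn = sol.g_min

    # cross-checks against the KL-divergence definitions
    sigma = assemble_sigma(sys)
    sigma5, sigma6 = project(sys, 5), project(sys, 6)
    st = sigma_t(sol.t_star, sigma5, sigma6)
    residuals = {
        "syn_vs_kl": syn - kl_gaussian(sigma, st),
        "unq1_vs_kl": unq1 - kl_gaussian(st, sigma6),
        "unq2_vs_kl": unq2 - kl_gaussian(st, sigma5),
        "shd_consistency": (mi.i13 - unq1) - (mi.i23 - unq2),
        "pythagorean_5": kl_gaussian(sigma, sigma5) - (syn + kl_gaussian(st, sigma5)),
        "pythagorean_6": kl_gaussian(sigma, sigma6) - (syn + kl_gaussian(st, sigma6)),
    }
    return PIDResult(
        syn=_clip(syn, "Syn"),
        unq1=_clip(unq1, "Unq1"),
        unq2=_clip(unq2, "Unq2"),
        shd=_clip(shd, "Shd"),
        mi=mi,
        method="iig",
        t_star=sol.t_star,
        diagnostics={
            "at_endpoint": sol.at_endpoint,
            "feasible_interval": (sol.interval.lower, sol.interval.upper),
            "residuals": residuals,
        },
    )


def pid_mmi(sys: CrossCorrelationSystem) -> PIDResult:
    """Minimum-mutual-information PID baseline.

    Shd = min(I[X1;X3], I[X2;X3]); the remaining components follow from the
    consistency equations, so exactly one unique information is zero (both,
    on a tie).
    """
    mi = mutual_informations(sys)
    if mi.joint < DEGENERATE_JOINT_MI:
        return _zero_result(mi, "mmi")
    shd = min(mi.i13, mi.i23)
    unq1 = mi.i13 - shd
    unq2 = mi.i23 - shd
    syn = mi.i13_given_2 - unq1
    return PIDResult(
        syn=_clip(syn, "Syn"),
        unq1=_clip(unq1, "Unq1"),
        unq2=_clip(unq2, "Unq2"),
        shd=_clip(shd, "Shd"),
        mi=mi,
        method="mmi",
    )


def as_percentages(res: PIDResult) -> tuple[float, float, float, float]:
    """Components as percentages of the joint mutual information.

    Returned in the order (unq1, unq2, shd, syn); base-invariant, so the
    same in nats or bits.  Undefined when the joint MI is zero.
    """
    if res.mi.joint <= 0.0:
        raise ValueError("percentages are undefined when the joint MI is zero")
    scale = 100.0 / res.mi.joint
    return (res.unq1 * scale, res.unq2 * scale, res.shd * scale, res.syn * scale)


def property_suite(sys: CrossCorrelationSystem, tol: float = 1e-8) -> dict[str, bool]:
    """Check the Williams-Beer properties of the Iig PID on one system.

    Returns a pass/fail report for: non-negativity of all components; the
    self-redundancy surrogate Unq_k + Shd = I[Xk;X3]; source-exchange
    symmetry (swapping X1 and X2 swaps the unique informations and preserves
    Shd and Syn); and the monotonicity surrogate Shd <= min(I[X1;X3],
    I[X2;X3]), i.e. the geometric shared information never exceeds the MMI
    one.
    """
    res = pid_ig(sys)
    swapped = pid_ig(sys.swap_sources())
    mi = res.mi
    return {
        "non_negativity": all(v >= -tol for v in res.components.values()),
        "self_redundancy": (
            abs(res.unq1 + res.shd - mi.i13) < tol
            and abs(res.unq2 + res.shd - mi.i23) < tol
        ),
        "symmetry": (
            abs(res.unq1 - swapped.unq2) < 1e-6
            and abs(res.unq2 - swapped.unq1) < 1e-6
            and abs(res.shd - swapped.shd) < 1e-6
            and abs(res.syn - swapped.syn) < 1e-6
        ),
        "monotonicity": res.shd <= min(mi.i13, mi.i23) + tol,
    }
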