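"""Synthetic equi-cross-correlation systems and the replication harness.

The synthetic family fills each cross-correlation block with a single
constant: P = p 1 1', Q = q 1 1', R = r 1 1'.  With block sizes (3, 4, 3)
and (p, q, r) = (-0.15, 0.15, 0.15) this is the 10-dimensional benchmark
system used throughout the package's studies.  Two study modes exist:

* exact mode — the true covariance of a chosen submanifold projection is fed
  straight into the decompositions (no sampling error);
* sampling mode — replicate datasets are drawn from the true covariance,
  a covariance is estimated from each (mean-centred, unbiased n-1 divisor),
  standardised, and decomposed; components are normalised by the joint MI
  and summarised as median and (min, max) range across replicates.

Replicate seeds are spawned from the study seed via ``SeedSequence`` so the
study is reproducible and the replicates are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core import (
    BlockSpec,
    CrossCorrelationSystem,
    NotPositiveDefiniteError,
    PartitionedCovariance,
    standardize,
)
from .decomposition import PIDResult, as_percentages, pid_ig, pid_mmi
from .projections import normalize_submanifold, project

__all__ = [
    "EquiCorrParams",
    "StudyConfig",
    "StudySummary",
    "equicorr_system",
    "true_covariance",
    "sample_dataset",
    "estimate_covariance",
    "replicate_study",
]

_METHODS = {"iig": pid_ig, "mmi": pid_mmi}

#: Parameters of the benchmark study: (p, q, r) = (-0.15, 0.15, 0.15), blocks (3, 4, 3).
BENCHMARK = None  # set below, after EquiCorrParams is defined


@dataclass(frozen=True)
class EquiCorrParams:
    """Constant cross-correlations (p, q, r) with block sizes.

    Construction fails if the implied correlation matrix is not positive
    definite, so a held instance always describes a valid Gaussian.
    """

    p_val: float
    q_val: float
    r_val: float
    blocks: BlockSpec

    def __post_init__(self) -> None:
        try:
            equicorr_system(self)
        except NotPositiveDefiniteError as exc:
            raise NotPositiveDefiniteError(
                f"equi-correlation parameters (p={self.p_val}, q={self.q_val}, "
                f"r={self.r_val}) with blocks {self.blocks} do not define a "
                f"positive-definite system"
            ) from exc


def equicorr_system(params: EquiCorrParams) -> CrossCorrelationSystem:
    """Build the standardised system with constant-filled cross blocks."""
    b = params.blocks
    return CrossCorrelationSystem(
        p=np.full((b.n1, b.n2), params.p_val),
        q=np.full((b.n1, b.n3), params.q_val),
        r=np.full((b.n2, b.n3), params.r_val),
        blocks=b,
    )


BENCHMARK = EquiCorrParams(-0.15, 0.15, 0.15, BlockSpec(3, 4, 3))


def true_covariance(params: EquiCorrParams, sub: int | str = "M") -> np.ndarray:
    """Exact covariance of the projection of the synthetic system onto ``sub``."""
    return project(equicorr_system(params), sub)


def sample_dataset(cov: np.ndarray, n: int, seed: int | np.random.SeedSequence) -> np.ndarray:
    """Draw ``n`` zero-mean Gaussian rows with the given covariance.

    Bit-for-bit reproducible for a fixed (cov, n, seed, numpy generator
    version); uses the Cholesky factor so no eigendecomposition noise enters.
    """
    rng = np.random.default_rng(seed)
    cov = np.asarray(cov, dtype=float)
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n, method="cholesky")


def estimate_covariance(data: np.ndarray, blocks: BlockSpec) -> PartitionedCovariance:
    """Sample covariance (mean-centred, unbiased n-1 divisor) with block structure."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D samples x variables table")
    n, m = data.shape
    if n <= m:
        raise ValueError(
            f"need more samples than variables to estimate a covariance "
            f"({n} samples, {m} variables); increase the sample size"
        )
    sigma = np.cov(data, rowvar=False, ddof=1)
    try:
        return PartitionedCovariance(sigma=sigma, blocks=blocks)
    except NotPositiveDefiniteError as exc:
        raise NotPositiveDefiniteError(
            "estimated covariance is singular; increase the sample size"
        ) from exc


@dataclass(frozen=True)
class StudyConfig:
    """Design of a replication study.

    ``true_submanifold`` selects which projected distribution generates the
    data ("M" for the full model); ``exact`` skips sampling entirely and
    decomposes the true covariance once.
    """

    params: EquiCorrParams
    true_submanifold: int | str = "M"
    n_samples: int = 1000
    n_reps: int = 1000
    seed: int = 0
    methods: Sequence[str] = ("iig", "mmi")
    exact: bool = False

    def __post_init__(self) -> None:
        normalize_submanifold(self.true_submanifold)
        for method in self.methods:
            if method not in _METHODS:
                raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
        if not self.exact and self.n_samples <= self.params.blocks.m:
            raise ValueError("n_samples must exceed the total dimension m")


@dataclass
class StudySummary:
    """Median and (min, max) range of percentage components per method.

    ``per_method`` maps a method label to a dict with keys ``median`` and
    ``range``, each holding the four components (unq1, unq2, shd, syn) in
    percent of the joint MI; ``t_star`` summarises the geodesic parameter
    for the information-geometric method.
    """

    config: StudyConfig
    per_method: dict[str, dict[str, dict[str, float] | dict[str, tuple[float, float]]]]
    t_star: dict[str, Any]
    n_completed: int
    n_failed: int
    replicates: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        cfg = self.config
        return {
            "config": {
                "p": cfg.params.p_val,
                "q": cfg.params.q_val,
                "r": cfg.params.r_val,
                "blocks": [cfg.params.blocks.n1, cfg.params.blocks.n2, cfg.params.blocks.n3],
                "true_submanifold": str(cfg.true_submanifold),
                "n_samples": cfg.n_samples,
                "n_reps": cfg.n_reps,
                "seed": cfg.seed,
                "exact": cfg.exact,
                "centring": "sample-mean",
                "divisor": "n-1",
            },
            "per_method": self.per_method,
            "t_star": self.t_star,
            "n_completed": self.n_completed,
            "n_failed": self.n_failed,
        }


_COMPONENTS = ("unq1", "unq2", "shd", "syn")


def _decompose_replicate(sys: CrossCorrelationSystem, methods: Sequence[str]) -> dict[str, Any]:
    row: dict[str, Any] = {}
    for method in methods:
        res: PIDResult = _METHODS[method](sys)
        row[method] = as_percentages(res)
        if method == "iig":
            row["t_star"] = res.t_star
    return row


def replicate_study(cfg: StudyConfig) -> StudySummary:
    """Run the replication study described by ``cfg``.

    Sampling mode: per replicate, draw -> estimate -> standardise -> decompose
    -> normalise by the joint MI.  Replicate failures (singular estimates or
    optimisation breakdowns) are excluded and counted.  Exact mode runs the
    decompositions once on the true covariance.
    """
    truth = true_covariance(cfg.params, cfg.true_submanifold)
    blocks = cfg.params.blocks

    rows: list[dict[str, Any]] = []
    n_failed = 0
    if cfg.exact:
        sys = standardize(PartitionedCovariance(sigma=truth, blocks=blocks))
        rows.append(_decompose_replicate(sys, cfg.methods))
    else:
        children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
        for child in children:
            try:
                data = sample_dataset(truth, cfg.n_samples, child)
                est = estimate_covariance(data, blocks)
                rows.append(_decompose_replicate(standardize(est), cfg.methods))
            except (NotPositiveDefiniteError, RuntimeError, ValueError):
                n_failed += 1
    if not rows:
        raise RuntimeError("every replicate failed; check the study configuration")

    per_method: dict[str, Any] = {}
    replicates: dict[str, np.ndarray] = {}
    for method in cfg.methods:
        values = np.array([row[method] for row in rows])  # n_rows x 4
        replicates[method] = values
        per_method[method] = {
            "median": {c: float(np.median(values[:, k])) for k, c in enumerate(_COMPONENTS)},
            "range": {
                c: (float(values[:, k].min()), float(values[:, k].max()))
                for k, c in enumerate(_COMPONENTS)
            },
        }
    t_summary: dict[str, Any] = {}
    if "iig" in cfg.methods:
        t_vals = np.array([row["t_star"] for row in rows], dtype=float)
        replicates["t_star"] = t_vals
        t_summary = {
            "median": float(np.median(t_vals)),
            "range": (float(t_vals.min()), float(t_vals.max())),
            "n_outside_unit": int(np.sum((t_vals < 0.0) | (t_vals > 1.0))),
        }
    return StudySummary(
        config=cfg,
        per_method=per_method,
        t_star=t_summary,
        n_completed=len(rows),
        n_failed=n_failed,
        replicates=replicates,
    )
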