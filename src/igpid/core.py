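"""Partitioned Gaussian systems in correlation form.

A system of two vector sources ``X1`` (dim ``n1``), ``X2`` (dim ``n2``) and a
vector target ``X3`` (dim ``n3``) is described by an ``m x m`` covariance
matrix, ``m = n1 + n2 + n3``.  Because the Kullback--Leibler divergence
between two partitioned Gaussians that share diagonal blocks depends only on
the cross-correlation blocks, every computation in this package works on the
standardised form

    Sigma = [[I, P, Q],
             [P', I, R],
             [Q', R', I]]

where ``P`` (n1 x n2), ``Q`` (n1 x n3) and ``R`` (n2 x n3) are the pairwise
cross-correlation matrices.  :func:`standardize` maps a raw covariance onto
this canonical representation; means never enter any formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "BlockSpec",
    "PartitionedCovariance",
    "CrossCorrelationSystem",
    "MIProfile",
    "NotPositiveDefiniteError",
    "standardize",
    "assemble_sigma",
    "kl_gaussian",
    "mutual_informations",
    "chol_logdet",
]


class NotPositiveDefiniteError(ValueError):
    """Raised when a matrix required to be positive definite is not."""


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def _cholesky_or_none(a: np.ndarray) -> np.ndarray | None:
    try:
        return linalg.cholesky(_symmetrize(a), lower=True)
    except linalg.LinAlgError:
        return None


def chol_logdet(a: np.ndarray, what: str = "matrix") -> float:
    """Log-determinant of a symmetric positive-definite matrix via Cholesky.

    The Cholesky factorisation doubles as the positive-definiteness check:
    no eigenvalue clipping is applied, failure raises.
    """
    chol = _cholesky_or_none(a)
    if chol is None:
        raise NotPositiveDefiniteError(f"{what} is not positive definite")
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


@dataclass(frozen=True)
class BlockSpec:
    """Partition sizes ``(n1, n2, n3)`` of the stacked vector ``(X1, X2, X3)``."""

    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def m(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        """Row/column slices of the three blocks in the stacked ordering."""
        a, b = self.n1, self.n1 + self.n2
        return slice(0, a), slice(a, b), slice(b, self.m)


@dataclass(frozen=True)
class PartitionedCovariance:
    """An ``m x m`` symmetric positive-definite covariance with block structure."""

    sigma: np.ndarray
    blocks: BlockSpec

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise ValueError("covariance must be a square matrix")
        if sigma.shape[0] != self.blocks.m:
            raise ValueError(
                f"block sizes do not match matrix dimension: "
                f"matrix is {sigma.shape[0]}x{sigma.shape[0]}, blocks sum to {self.blocks.m}"
            )
        if not np.allclose(sigma, sigma.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if _cholesky_or_none(sigma) is None:
            raise NotPositiveDefiniteError("covariance is not positive definite")
        object.__setattr__(self, "sigma", _symmetrize(sigma))

    def block(self, i: int, j: int) -> np.ndarray:
        """Return block (i, j) with 1-based indices into the 3x3 partition."""
        s = self.blocks.slices
        return self.sigma[s[i - 1], s[j - 1]]


@dataclass(frozen=True)
class CrossCorrelationSystem:
    """The standardised system: cross-correlation blocks ``P``, ``Q``, ``R``.

    ``P`` couples the two sources, ``Q`` couples source 1 to the target and
    ``R`` couples source 2 to the target.  The assembled correlation matrix
    (identity diagonal blocks) must be positive definite, which forces every
    singular value of ``P``, ``Q``, ``R`` strictly below one.
    """

    p: np.ndarray
    q: np.ndarray
    r: np.ndarray
    blocks: BlockSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.p, dtype=float))
        q = np.atleast_2d(np.asarray(self.q, dtype=float))
        r = np.atleast_2d(np.asarray(self.r, dtype=float))
        blocks = self.blocks
        if blocks is None:
            blocks = BlockSpec(p.shape[0], p.shape[1], q.shape[1])
        if p.shape != (blocks.n1, blocks.n2):
            raise ValueError(f"P must be {blocks.n1}x{blocks.n2}, got {p.shape}")
        if q.shape != (blocks.n1, blocks.n3):
            raise ValueError(f"Q must be {blocks.n1}x{blocks.n3}, got {q.shape}")
        if r.shape != (blocks.n2, blocks.n3):
            raise ValueError(f"R must be {blocks.n2}x{blocks.n3}, got {r.shape}")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "blocks", blocks)
        # invariant: the assembled correlation matrix is PD
        chol_logdet(assemble_sigma(self), "assembled correlation matrix")

    def swap_sources(self) -> "CrossCorrelationSystem":
        """Exchange the roles of the two sources (X1 <-> X2)."""
        return CrossCorrelationSystem(
            p=self.p.T,
            q=self.r,
            r=self.q,
            blocks=BlockSpec(self.blocks.n2, self.blocks.n1, self.blocks.n3),
        )


@dataclass(frozen=True)
class MIProfile:
    """Classical Shannon mutual-information quantities, in nats.

    Attributes
    ----------
    i13, i23
        Source-target mutual informations I[X1;X3] and I[X2;X3].
    i13_given_2, i23_given_1
        Conditional mutual informations I[X1;X3|X2] and I[X2;X3|X1].
    joint
        Joint mutual information I[X1,X2;X3].
    interaction
        Interaction information II[X1;X2;X3] = joint - i13 - i23; equals
        synergy minus shared information in a Williams-Beer decomposition.
    """

    i13: float
    i23: float
    i13_given_2: float
    i23_given_1: float
    joint: float
    interaction: float


def standardize(cov: PartitionedCovariance) -> CrossCorrelationSystem:
    """Reduce a partitioned covariance to its cross-correlation system.

    Each off-diagonal block is whitened by the symmetric positive-definite
    inverse square roots of the adjoining diagonal blocks,
    ``Pij = Sii^{-1/2} Sij Sjj^{-1/2}``.  The result is invariant under any
    block-wise congruence of the diagonal blocks, so divergences computed
    downstream do not depend on the original scales (or means).
    """
    s = cov.blocks.slices
    inv_sqrts = []
    for k, sl in enumerate(s, start=1):
        block = _symmetrize(cov.sigma[sl, sl])
        w, v = linalg.eigh(block)
        if w[0] <= 1e-12 * max(abs(w[-1]), 1.0):
            raise NotPositiveDefiniteError(
                f"diagonal block {k} is not positive definite; cannot standardise"
            )
        inv_sqrts.append(v @ np.diag(1.0 / np.sqrt(w)) @ v.T)
    a, b, c = inv_sqrts
    return CrossCorrelationSystem(
        p=a @ cov.sigma[s[0], s[1]] @ b,
        q=a @ cov.sigma[s[0], s[2]] @ c,
        r=b @ cov.sigma[s[1], s[2]] @ c,
        blocks=cov.blocks,
    )


def assemble_sigma(sys: CrossCorrelationSystem) -> np.ndarray:
    """Assemble the full correlation matrix with blocks P, Q, R."""
    return assemble_blocks(sys.blocks, sys.p, sys.q, sys.r)


def assemble_blocks(
    blocks: BlockSpec, p: np.ndarray, q: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Place arbitrary cross-blocks into the identity-diagonal template."""
    s1, s2, s3 = blocks.slices
    sigma = np.eye(blocks.m)
    sigma[s1, s2] = p
    sigma[s2, s1] = p.T
    sigma[s1, s3] = q
    sigma[s3, s1] = q.T
    sigma[s2, s3] = r
    sigma[s3, s2] = r.T
    return sigma


def kl_gaussian(cov_a: np.ndarray, cov_b: np.ndarray) -> float:
    """KL divergence D( N(0, A) || N(0, B) ) in nats.

    Returns ``0.5 * [log(|B|/|A|) - m + trace(B^{-1} A)]``, the standard
    zero-mean Gaussian divergence.  Nonnegative; zero iff ``A == B``.
    """
    a = _symmetrize(np.asarray(cov_a, dtype=float))
    b = _symmetrize(np.asarray(cov_b, dtype=float))
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("covariances must be square matrices of equal size")
    m = a.shape[0]
    logdet_a = chol_logdet(a, "first covariance")
    chol_b = _cholesky_or_none(b)
    if chol_b is None:
        raise NotPositiveDefiniteError("second covariance is not positive definite")
    logdet_b = 2.0 * float(np.sum(np.log(np.diag(chol_b))))
    trace = float(np.trace(linalg.cho_solve((chol_b, True), a)))
    return 0.5 * (logdet_b - logdet_a - m + trace)


def mutual_informations(sys: CrossCorrelationSystem) -> MIProfile:
    """Classical mutual informations of the standardised system, in nats.

    Closed forms: I[X1;X3] = -0.5 log|I - Q'Q|, I[X2;X3] = -0.5 log|I - R'R|,
    and I[X1,X2;X3] = 0.5 log(|I - P'P| / |Sigma|); the conditional terms
    follow from the chain rule.
    """
    n2, n3 = sys.blocks.n2, sys.blocks.n3
    i13 = -0.5 * chol_logdet(np.eye(n3) - sys.q.T @ sys.q, "I - Q'Q")
    i23 = -0.5 * chol_logdet(np.eye(n3) - sys.r.T @ sys.r, "I - R'R")
    logdet_sigma = chol_logdet(assemble_sigma(sys), "assembled correlation matrix")
    logdet_pp = chol_logdet(np.eye(n2) - sys.p.T @ sys.p, "I - P'P")
    joint = 0.5 * (logdet_pp - logdet_sigma)
    return MIProfile(
        i13=i13,
        i23=i23,
        i13_given_2=joint - i23,
        i23_given_1=joint - i13,
        joint=joint,
        interaction=joint - i13 - i23,
    )
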