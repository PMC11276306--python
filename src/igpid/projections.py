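"""Information projections onto the lattice of Gaussian graphical submanifolds.

Zeroing an off-diagonal block of the precision matrix of a partitioned
Gaussian encodes a conditional independence.  The seven submanifolds S1..S7
of the model lattice are defined by zeroing the source-source block (K12),
the source1-target block (K13), the source2-target block (K23), or
combinations thereof.  The m-projection (KL-closest member) of the full
distribution onto each submanifold has a closed-form covariance obtained by
substituting products of P, Q, R into the cross-correlation slots:

    S1: (0, 0, 0)      S5: (P, Q, P'Q)   [K23 = 0]
    S2: (P, 0, 0)      S6: (P, PR, R)    [K13 = 0]
    S3: (0, Q, 0)      S7: (QR', Q, R)   [K12 = 0]
    S4: (0, 0, R)      M:  (P, Q, R)
"""

from __future__ import annotations

import numpy as np

from .core import (
    CrossCorrelationSystem,
    NotPositiveDefiniteError,
    assemble_blocks,
    chol_logdet,
)

__all__ = ["SUBMANIFOLDS", "normalize_submanifold", "project", "det_identities"]

#: Valid submanifold identifiers: integers 1..7 and "M" for the full manifold.
SUBMANIFOLDS = (1, 2, 3, 4, 5, 6, 7, "M")


def normalize_submanifold(sub: int | str) -> int | str:
    """Coerce user input ("S5", "5", 5, "m") to a canonical identifier."""
    if isinstance(sub, str):
        token = sub.strip().upper().removeprefix("S")
        if token == "M":
            return "M"
        if token.isdigit():
            sub = int(token)
    if sub in SUBMANIFOLDS:
        return sub
    raise ValueError(f"unknown submanifold {sub!r}; expected 1..7 or 'M'")


def _projected_blocks(
    sys: CrossCorrelationSystem, sub: int | str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p, q, r = sys.p, sys.q, sys.r
    zp, zq, zr = np.zeros_like(p), np.zeros_like(q), np.zeros_like(r)
    table = {
        1: (zp, zq, zr),
        2: (p, zq, zr),
        3: (zp, q, zr),
        4: (zp, zq, r),
        5: (p, q, p.T @ q),
        6: (p, p @ r, r),
        7: (q @ r.T, q, r),
        "M": (p, q, r),
    }
    return table[normalize_submanifold(sub)]


def project(sys: CrossCorrelationSystem, sub: int | str) -> np.ndarray:
    """Covariance of the m-projection of the system onto submanifold ``sub``.

    The result is symmetric and certified positive definite; for a valid
    system every projection is automatically PD, so a failure here signals
    an inconsistent input.
    """
    sigma = assemble_blocks(sys.blocks, *_projected_blocks(sys, sub))
    try:
        chol_logdet(sigma, f"projection onto S{sub}")
    except NotPositiveDefiniteError as exc:  # pragma: no cover - guarded path
        raise NotPositiveDefiniteError(
            f"projection onto submanifold {sub} lost positive definiteness: {exc}"
        ) from exc
    return sigma


def det_identities(sys: CrossCorrelationSystem) -> tuple[float, float]:
    """Determinants of the S5 and S6 projections, with their factorisations.

    ``|Sigma5| = |I - P'P| |I - Q'Q|`` and ``|Sigma6| = |I - P'P| |I - R'R|``;
    both identities are asserted against direct determinants before the pair
    is returned.
    """
    n2, n3 = sys.blocks.n2, sys.blocks.n3
    det5 = float(np.linalg.det(project(sys, 5)))
    det6 = float(np.linalg.det(project(sys, 6)))
    f_p = float(np.linalg.det(np.eye(n2) - sys.p.T @ sys.p))
    f_q = float(np.linalg.det(np.eye(n3) - sys.q.T @ sys.q))
    f_r = float(np.linalg.det(np.eye(n3) - sys.r.T @ sys.r))
    for direct, factored, label in ((det5, f_p * f_q, "S5"), (det6, f_p * f_r, "S6")):
        if not np.isclose(direct, factored, rtol=1e-9, atol=1e-12):
            raise AssertionError(
                f"determinant factorisation failed for {label}: {direct} vs {factored}"
            )
    return det5, det6
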