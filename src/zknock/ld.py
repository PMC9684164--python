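"""Linkage-disequilibrium matrices: estimation, validation and PSD repair.

The knockoff machinery consumes a per-block variant correlation matrix
(the LD matrix Sigma). When Sigma is estimated from a finite external
reference panel it is noisy and frequently indefinite, so every matrix
passes through :func:`psd_repair` before model building.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = ["LDMatrix", "psd_repair", "estimate_ld"]

#: smallest eigenvalue tolerated in a matrix considered PSD
PSD_TOL = 1e-8
#: eigenvalue floor applied during repair
PSD_FLOOR = 1e-10


@dataclasses.dataclass
class LDMatrix:
    """A p x p variant correlation matrix for one genomic block.

    Attributes
    ----------
    variants:
        Ordered variant identifiers (any hashable labels).
    R:
        Symmetric correlation matrix with unit diagonal.
    repaired:
        True when eigenvalue clipping was applied during construction.
    shrinkage:
        Shrinkage intensity toward the identity used during estimation.
    """

    variants: list
    R: np.ndarray
    repaired: bool = False
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(self.variants) != self.R.shape[0]:
            raise ValueError(
                f"{len(self.variants)} variant ids for a "
                f"{self.R.shape[0]}x{self.R.shape[1]} matrix"
            )

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.R)[0])

    def is_psd(self, tol: float = PSD_TOL) -> bool:
        return self.min_eigenvalue() >= -tol

    def subset(self, idx: Sequence[int]) -> "LDMatrix":
        """Restrict to the given variant indices (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return LDMatrix(
            variants=[self.variants[i] for i in idx],
            R=self.R[np.ix_(idx, idx)],
            repaired=self.repaired,
            shrinkage=self.shrinkage,
        )


def psd_repair(
    R: np.ndarray,
    floor: float = PSD_FLOOR,
    variants: Sequence | None = None,
    shrinkage: float = 0.0,
) -> LDMatrix:
    """Project a noisy correlation matrix onto the PSD cone.

    Eigenvalues below ``floor`` are clipped up to it and the result is
    rescaled back to unit diagonal. Already-PSD input is returned
    unchanged (``repaired=False``); the operation is idempotent.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("input must be symmetric (within 1e-8)")
    R = 0.5 * (R + R.T)
    if variants is None:
        variants = list(range(R.shape[0]))
    else:
        variants = list(variants)

    w, U = np.linalg.eigh(R)
    # tolerance band below the floor: keeps the operation idempotent after
    # the unit-diagonal rescale nudges eigenvalues by machine epsilon
    if w[0] >= floor - PSD_TOL and np.allclose(np.diag(R), 1.0, atol=1e-8):
        out = R.copy()
        np.fill_diagonal(out, 1.0)
        return LDMatrix(variants, out, repaired=False, shrinkage=shrinkage)

    w_clipped = np.maximum(w, floor)
    fixed = (U * w_clipped) @ U.T
    # rescale to exact unit diagonal
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = 0.5 * (fixed + fixed.T)
    np.fill_diagonal(fixed, 1.0)
    return LDMatrix(variants, fixed, repaired=True, shrinkage=shrinkage)


def estimate_ld(
    G: np.ndarray,
    shrinkage: float = 0.1,
    variants: Sequence | None = None,
) -> LDMatrix:
    """Estimate the LD matrix of one block from reference genotypes.

    Genotype dosages (n samples x p variants) are centered and
    standardized per variant; the sample correlation is shrunk toward
    the identity, ``R = (1 - shrinkage) * cor(G) + shrinkage * I``, and
    PSD-repaired. Shrinkage regularises the near-singular estimates
    that small external panels produce.

    Raises
    ------
    ValueError
        If fewer than two samples are supplied or any variant is
        monomorphic in the panel (zero variance).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-d genotype matrix with >= 2 samples")
    if not 0.0 <= shrinkage < 1.0:
        raise ValueError("shrinkage must be in [0, 1)")
    sd = G.std(axis=0)
    mono = np.flatnonzero(sd == 0.0)
    if mono.size:
        labels = (
            [variants[i] for i in mono] if variants is not None else mono.tolist()
        )
        raise ValueError(
            f"monomorphic variants must be filtered before LD estimation: {labels}"
        )
    R = np.corrcoef(G, rowvar=False)
    p = R.shape[0] if R.ndim == 2 else 1
    R = np.atleast_2d(R)
    R = (1.0 - shrinkage) * R + shrinkage * np.eye(p)
    return psd_repair(R, variants=variants, shrinkage=shrinkage)
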