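"""Per-block knockoff models for GWAS Z-scores.

Given the LD matrix Sigma of a block, a knockoff copy of the score-test
Z-vector can be sampled directly as ``Z~ = P Z + E`` with
``E ~ N(0, V)``, where ``P = I - D Sigma^-1`` stacked M times and V is
the exchangeable block covariance built from ``C = 2D - D Sigma^-1 D``.
The diagonal decoupling matrix ``D = diag(s)`` comes from the convex
program

    minimize sum_j |1 - s_j|   s.t.  ((M+1)/M) Sigma - D >= 0,  s >= 0.

Sampling knockoff Z-scores this way is equivalent in distribution to
computing score statistics on individual-level second-order knockoff
genotypes, but needs only summary statistics plus a reference LD panel.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
from typing import Literal

import numpy as np
from scipy import optimize

from .ld import LDMatrix, PSD_TOL

__all__ = [
    "KnockoffModel",
    "KnockoffZ",
    "solve_s",
    "build_knockoff_model",
    "sample_knockoff_z",
    "save_models",
    "load_models",
]

log = logging.getLogger(__name__)

#: eigenvalue floor applied to V before factoring
V_FLOOR = 1e-10


@dataclasses.dataclass
class KnockoffModel:
    """Bundle of matrices enabling knockoff Z sampling for one block."""

    variants: list
    M: int
    s: np.ndarray              # length p, diagonal of D
    P: np.ndarray              # pM x p projection
    V: np.ndarray              # pM x pM noise covariance
    V_factor: np.ndarray       # V_factor @ V_factor.T == V
    method: str                # "equi" | "sdp"
    shrinkage: float = 0.0
    Sigma_inv: np.ndarray | None = None  # cached solve, used by meta module

    @property
    def p(self) -> int:
        return self.s.shape[0]

    def decorrelate(self, z: np.ndarray) -> np.ndarray:
        """Return D Sigma^-1 z = z - (I - D Sigma^-1) z.

        This is the expected gap between the original and knockoff
        Z-score; it quantifies direct (LD-adjusted) effects and is the
        quantity correlated across studies to estimate sample overlap.
        """
        z = np.asarray(z, dtype=float)
        if self.Sigma_inv is not None:
            return self.s * (self.Sigma_inv @ z)
        # P rows are M copies of I - D Sigma^-1
        return z - self.P[: self.p] @ z


@dataclasses.dataclass
class KnockoffZ:
    """Original and sampled knockoff Z-scores for one block."""

    z: np.ndarray          # length p
    z_knock: np.ndarray    # p x M
    seed: int


def _check_sigma(Sigma: LDMatrix) -> None:
    if not isinstance(Sigma, LDMatrix):
        raise TypeError("expected an LDMatrix; wrap raw arrays with psd_repair")
    if not Sigma.is_psd(PSD_TOL):
        raise ValueError(
            "LD matrix is not PSD (lambda_min = "
            f"{Sigma.min_eigenvalue():.3e}); run psd_repair first"
        )


def solve_s(
    Sigma: LDMatrix,
    M: int = 5,
    method: Literal["equi", "sdp"] = "equi",
) -> np.ndarray:
    """Solve for the diagonal decoupling vector s.

    ``equi`` uses the equicorrelated closed form
    ``s_j = min(1, ((M+1)/M) lambda_min(Sigma))`` for all j; ``sdp``
    maximises ``sum_j s_j`` subject to ``0 <= s <= 1`` and
    ``((M+1)/M) Sigma - diag(s) >= 0`` with a smallest-eigenvalue
    constraint (sequential quadratic programming). Both satisfy the
    semidefinite feasibility constraint within 1e-8.
    """
    _check_sigma(Sigma)
    if M < 1:
        raise ValueError("M must be >= 1")
    p = Sigma.p
    scale = (M + 1) / M
    lam_min = np.linalg.eigvalsh(Sigma.R)[0]
    s_equi = np.full(p, min(1.0, scale * max(lam_min, 0.0)))
    if method == "equi":
        return s_equi
    if method != "sdp":
        raise ValueError(f"unknown method {method!r}")

    A = scale * Sigma.R

    def neg_total(s: np.ndarray) -> float:
        return -float(s.sum())

    def min_eig(s: np.ndarray) -> float:
        return float(np.linalg.eigvalsh(A - np.diag(s))[0])

    def min_eig_jac(s: np.ndarray) -> np.ndarray:
        # d lambda_min / d s_j = -v_j^2 for the bottom eigenvector v
        w, U = np.linalg.eigh(A - np.diag(s))
        return -(U[:, 0] ** 2)

    res = None
    for x0 in (np.minimum(s_equi * 0.999, 0.999), 0.5 * s_equi, np.zeros(p)):
        res = optimize.minimize(
            neg_total,
            x0=x0,
            jac=lambda s: -np.ones_like(s),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * p,
            constraints=[{
                "type": "ineq", "fun": min_eig, "jac": min_eig_jac,
            }],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success:
            break
    if res is None or not res.success:
        raise RuntimeError(f"SDP solver failed: {res.message}")
    s = np.clip(res.x, 0.0, 1.0)
    # pull back inside the cone if SLSQP overshot the boundary
    lo = np.linalg.eigvalsh(A - np.diag(s))[0]
    if lo < -PSD_TOL:
        s *= (scale * lam_min) / (scale * lam_min - lo) if lam_min > 0 else 0.0
        s = np.clip(s, 0.0, 1.0)
    return s


def build_knockoff_model(
    Sigma: LDMatrix,
    M: int = 5,
    method: Literal["equi", "sdp"] = "equi",
    s: np.ndarray | None = None,
) -> KnockoffModel:
    """Assemble the per-block knockoff model (D, P, V and a factor of V).

    V is factored through a symmetric eigendecomposition with
    eigenvalues clipped at 1e-10; V is rank deficient for legitimate
    inputs (e.g. p=2, s=1), so a Cholesky factor does not exist in
    general. A clip that moves any eigenvalue by more than 1e-6 is
    logged as a warning since it signals a poorly conditioned LD block.
    """
    _check_sigma(Sigma)
    if s is None:
        s = solve_s(Sigma, M=M, method=method)
    s = np.asarray(s, dtype=float)
    p = Sigma.p

    # Sigma^-1 via a solve; ridge if the repaired matrix is still near singular
    R = Sigma.R
    cond = np.linalg.cond(R)
    if cond > 1e12:
        log.warning("LD block condition number %.2e; adding 1e-10 ridge", cond)
        R = R + 1e-10 * np.eye(p)
    Sigma_inv = np.linalg.solve(R, np.eye(p))
    Sigma_inv = 0.5 * (Sigma_inv + Sigma_inv.T)

    DSi = s[:, None] * Sigma_inv              # D Sigma^-1
    P_single = np.eye(p) - DSi                # I - D Sigma^-1
    P = np.tile(P_single, (M, 1))             # pM x p

    C = 2.0 * np.diag(s) - DSi * s[None, :]   # 2D - D Sigma^-1 D
    C = 0.5 * (C + C.T)
    CmD = C - np.diag(s)
    V = np.empty((p * M, p * M))
    for a in range(M):
        for b in range(M):
            V[a * p:(a + 1) * p, b * p:(b + 1) * p] = C if a == b else CmD
    V = 0.5 * (V + V.T)

    w, U = np.linalg.eigh(V)
    if w[0] < -1e-6:
        log.warning(
            "noise covariance clipped by %.3e; LD/constraint mismatch", -w[0]
        )
    w = np.maximum(w, V_FLOOR)
    V_factor = U * np.sqrt(w)

    return KnockoffModel(
        variants=list(Sigma.variants),
        M=M,
        s=s,
        P=P,
        V=V,
        V_factor=V_factor,
        method=method,
        shrinkage=Sigma.shrinkage,
        Sigma_inv=Sigma_inv,
    )


def sample_knockoff_z(
    model: KnockoffModel,
    z: np.ndarray,
    gamma: float = 1.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> KnockoffZ:
    """Sample M knockoff Z-score copies for one block.

    ``z_knock = reshape(P z + gamma * V_factor eps)`` with eps standard
    normal. ``gamma >= 1`` is the meta-analysis dependency factor that
    inflates the knockoff noise when studies share samples; a single
    independent study uses gamma = 1. Identical seed and inputs give
    bitwise-identical output.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (model.p,):
        raise ValueError(f"z has shape {z.shape}, model expects ({model.p},)")
    if gamma < 1.0:
        raise ValueError("dependency factor gamma must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.standard_normal(model.p * model.M)
    flat = model.P @ z + gamma * (model.V_factor @ eps)
    z_knock = flat.reshape(model.M, model.p).T     # p x M
    return KnockoffZ(z=z, z_knock=z_knock, seed=seed if seed is not None else -1)


# ---------------------------------------------------------------------------
# model cache


def save_models(models: dict[str, KnockoffModel], path: str | pathlib.Path) -> None:
    """Write a dict of per-block models to one .npz container.

    Arrays round-trip bit-exactly; variant ids are stored as strings.
    """
    path = pathlib.Path(path)
    arrays: dict[str, np.ndarray] = {}
    for block_id, m in models.items():
        pre = f"{block_id}/"
        arrays[pre + "variants"] = np.asarray([str(v) for v in m.variants])
        arrays[pre + "M"] = np.asarray(m.M)
        arrays[pre + "s"] = m.s
        arrays[pre + "P"] = m.P
        arrays[pre + "V_factor"] = m.V_factor
        arrays[pre + "V"] = m.V
        arrays[pre + "Sigma_inv"] = (
            m.Sigma_inv if m.Sigma_inv is not None else np.zeros((0, 0))
        )
        arrays[pre + "method"] = np.asarray(m.method)
        arrays[pre + "shrinkage"] = np.asarray(m.shrinkage)
    np.savez(path, **arrays)


def load_models(path: str | pathlib.Path) -> dict[str, KnockoffModel]:
    """Read a model cache written by :func:`save_models`."""
    out: dict[str, KnockoffModel] = {}
    with np.load(pathlib.Path(path), allow_pickle=False) as data:
        block_ids = sorted({k.split("/", 1)[0] for k in data.files})
        for bid in block_ids:
            g = lambda name: data[f"{bid}/{name}"]
            Sigma_inv = g("Sigma_inv")
            out[bid] = KnockoffModel(
                variants=list(g("variants")),
                M=int(g("M")),
                s=g("s"),
                P=g("P"),
                V=g("V"),
                V_factor=g("V_factor"),
                method=str(g("method")),
                shrinkage=float(g("shrinkage")),
                Sigma_inv=Sigma_inv if Sigma_inv.size else None,
            )
    return out
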