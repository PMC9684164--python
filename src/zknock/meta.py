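"""Overlap-aware meta-analysis of GWAS Z-scores via knockoffs.

Studies sharing samples produce correlated Z-scores. The study
correlation matrix cor.S is estimated from decorrelated null Z-scores
(``D Sigma^-1 Z``, the LD-adjusted direct-effect component), turned
into either sample-size weights ``w_k = sqrt(n_k / N)`` or optimal
weights minimising ``w' cor.S w`` subject to ``sum_k w_k sqrt(n_k) = 1,
w >= 0``, and into a dependency factor

    gamma = sqrt(1 + N / N_eff - N_eff / N),   gamma >= 1,

that inflates the knockoff sampling noise so that the meta-analysis
mimics knockoff generation on the pooled unique samples. Independent
studies give cor.S = I, N_eff = N and gamma = 1.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize

from .knockoff import KnockoffModel, sample_knockoff_z
from .ld import psd_repair

__all__ = [
    "StudyPanel",
    "MetaWeights",
    "estimate_study_correlation",
    "optimal_weights",
    "size_weights",
    "effective_size_and_gamma",
    "effective_cc_n",
    "meta_z",
    "meta_knockoff_z",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class StudyPanel:
    """K studies' aligned Z-vectors over a common variant index.

    ``Z`` is p x K; ``mask`` flags observation (1) vs missing (0) per
    variant and study; missing entries of Z are ignored. ``group``
    assigns each study to an LD group (heterogeneous ancestry); all
    studies in a group share one knockoff model.
    """

    Z: np.ndarray
    n: np.ndarray
    mask: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("Z must be p x K")
        if self.n.shape != (self.K,):
            raise ValueError("one sample size per study required")
        if np.any(self.n <= 0):
            raise ValueError("sample sizes must be positive")
        if self.mask is None:
            self.mask = np.ones_like(self.Z, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.Z.shape:
                raise ValueError("mask must match Z's shape")
        if self.group is None:
            self.group = np.zeros(self.K, dtype=int)
        else:
            self.group = np.asarray(self.group)
        bad = ~np.isfinite(np.where(self.mask, self.Z, 0.0))
        if bad.any():
            raise ValueError("non-finite Z-scores at observed entries")

    @property
    def p(self) -> int:
        return self.Z.shape[0]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    @property
    def N(self) -> float:
        return float(self.n.sum())


@dataclasses.dataclass
class MetaWeights:
    """Study weights plus the overlap summary used for gamma."""

    corS: np.ndarray
    w: np.ndarray
    N_eff: float
    gamma: float
    scheme: str  # "size" | "optimal"


def estimate_study_correlation(
    panel: StudyPanel,
    models: Mapping | KnockoffModel,
    z_cap: float = 1.96,
    min_shared: int = 100,
) -> np.ndarray:
    """Estimate the K x K study-correlation matrix from null Z-scores.

    For each study the decorrelated vector ``D Sigma^-1 Z_k`` is
    computed per LD group; each pair of studies is correlated over
    variants observed in both with |Z| <= z_cap in both (the cap
    removes polygenic signal so the residual correlation reflects
    sample overlap). The result is forced to unit diagonal and
    PSD-repaired.
    """
    if isinstance(models, KnockoffModel):
        models = {g: models for g in np.unique(panel.group)}
    U = np.empty_like(panel.Z)
    for k in range(panel.K):
        model = models[panel.group[k]]
        if model.p != panel.p:
            raise ValueError("model dimension does not match panel")
        U[:, k] = model.decorrelate(np.where(panel.mask[:, k], panel.Z[:, k], 0.0))

    corS = np.eye(panel.K)
    for i in range(panel.K):
        for j in range(i + 1, panel.K):
            keep = (
                panel.mask[:, i]
                & panel.mask[:, j]
                & (np.abs(panel.Z[:, i]) <= z_cap)
                & (np.abs(panel.Z[:, j]) <= z_cap)
            )
            m = int(keep.sum())
            if m < min_shared:
                raise ValueError(
                    f"studies {i} and {j} share only {m} null variants "
                    f"(< {min_shared}); cannot estimate their correlation"
                )
            ui, uj = U[keep, i], U[keep, j]
            denom = ui.std() * uj.std()
            c = float(np.mean((ui - ui.mean()) * (uj - uj.mean())) / denom) if denom > 0 else 0.0
            corS[i, j] = corS[j, i] = np.clip(c, -1.0, 1.0)
    return psd_repair(corS).R


def size_weights(n: np.ndarray) -> np.ndarray:
    """Conventional sample-size weights w_k = sqrt(n_k / N)."""
    n = np.asarray(n, dtype=float)
    return np.sqrt(n / n.sum())


def effective_cc_n(n_case: np.ndarray, n_control: np.ndarray) -> np.ndarray:
    """Effective sample size 4 / (1/n_case + 1/n_control) per study.

    Standard correction for case-control imbalance; equals the total
    sample size when cases and controls are balanced.
    """
    n_case = np.asarray(n_case, dtype=float)
    n_control = np.asarray(n_control, dtype=float)
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


def optimal_weights(
    corS: np.ndarray,
    n: np.ndarray,
    n_case: np.ndarray | None = None,
    n_control: np.ndarray | None = None,
) -> np.ndarray:
    """Power-optimal nonnegative study weights.

    Solves ``minimize w' cor.S w`` subject to
    ``sum_k w_k sqrt(n_k) = 1`` and ``w >= 0``. Duplicated studies
    (cor.S singular) make the optimum non-unique; a 1e-8 ridge is then
    added so the minimum-norm optimum is returned, deterministically.
    When case/control counts are given, n_k is replaced by the
    effective count ``4 / (1/n_case + 1/n_control)``.
    """
    corS = np.asarray(corS, dtype=float)
    if n_case is not None:
        if n_control is None:
            raise ValueError("both n_case and n_control are required")
        n = effective_cc_n(n_case, n_control)
    n = np.asarray(n, dtype=float)
    K = n.shape[0]
    if corS.shape != (K, K):
        raise ValueError("cor.S must be K x K")
    sqrt_n = np.sqrt(n)

    Q = corS.copy()
    if np.linalg.eigvalsh(Q)[0] < 1e-8:
        Q = Q + 1e-8 * np.eye(K)  # selects the minimum-norm optimum

    w0 = sqrt_n / (sqrt_n @ sqrt_n)  # feasible start (size weights rescaled)
    res = optimize.minimize(
        lambda w: float(w @ Q @ w),
        x0=w0,
        jac=lambda w: 2.0 * (Q @ w),
        method="SLSQP",
        bounds=[(0.0, None)] * K,
        constraints=[{
            "type": "eq",
            "fun": lambda w: float(w @ sqrt_n) - 1.0,
            "jac": lambda w: sqrt_n,
        }],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"weight QP failed: {res.message}")
    w = np.maximum(res.x, 0.0)
    w = w / (w @ sqrt_n)  # re-project onto the equality constraint exactly
    # KKT sanity: gradient must be aligned with the constraint normal on the support
    grad = 2.0 * (Q @ w)
    active = w > 1e-10
    if active.any():
        lam = (grad[active] / sqrt_n[active]).mean()
        kkt = np.max(np.abs(grad[active] - lam * sqrt_n[active]))
        if kkt > 1e-4:
            log.warning("weight QP KKT residual %.2e", kkt)
    return w


def effective_size_and_gamma(
    corS: np.ndarray,
    n: np.ndarray,
    w: np.ndarray | None = None,
    scheme: Literal["size", "optimal"] = "size",
) -> MetaWeights:
    """Effective sample size and dependency factor gamma.

    Size scheme: ``N_eff = N * N / sum_ij sqrt(n_i n_j) cor.S_ij``.
    Optimal scheme: ``N_eff / N = sum_k w_k^2 / (w' cor.S w)``.
    Either way ``gamma = sqrt(1 + N/N_eff - N_eff/N)``; gamma = 1
    exactly for cor.S = I under size weights. N_eff estimates above N
    (possible through noise in cor.S) are clipped to N with a warning.
    """
    corS = np.asarray(corS, dtype=float)
    n = np.asarray(n, dtype=float)
    N = float(n.sum())
    sqrt_n = np.sqrt(n)
    if scheme == "size":
        w = sqrt_n / np.sqrt(N)
        denom = float(sqrt_n @ corS @ sqrt_n)
        ratio = N / denom  # N_eff / N
    elif scheme == "optimal":
        if w is None:
            w = optimal_weights(corS, n)
        w = np.asarray(w, dtype=float)
        quad = float(w @ corS @ w)
        ratio = float(w @ w) / quad
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    # N_eff > N arises from noise in cor.S; clip, warning only on gross overshoot
    if ratio > 1.2:
        warnings.warn(
            f"estimated N_eff exceeds N by factor {ratio:.4f}; clipping "
            "(study-correlation estimation noise)",
            stacklevel=2,
        )
    ratio = min(ratio, 1.0)
    N_eff = ratio * N
    gamma = float(np.sqrt(1.0 + 1.0 / ratio - ratio))
    return MetaWeights(corS=corS, w=w, N_eff=N_eff, gamma=max(gamma, 1.0), scheme=scheme)


def meta_z(panel: StudyPanel, weights: MetaWeights) -> np.ndarray:
    """Meta-analysis Z-score ``sum_k w_k C_k Z_k``.

    ``C_k`` zeroes variants unobserved in study k; no rescaling for
    missingness is applied because the knockoff contrast is scale-free.
    Variants observed in no study are flagged with a warning (their
    meta Z is 0 and they carry no evidence either way).
    """
    Zm = np.where(panel.mask, panel.Z, 0.0)
    nobs = panel.mask.sum(axis=1)
    if np.any(nobs == 0):
        warnings.warn(
            f"{int((nobs == 0).sum())} variants observed in zero studies",
            stacklevel=2,
        )
    return Zm @ weights.w


def meta_knockoff_z(
    panel: StudyPanel,
    weights: MetaWeights,
    models: Mapping | KnockoffModel,
    seed: int = 0,
    gammas: Mapping | None = None,
) -> np.ndarray:
    """Meta-analysis knockoff Z-scores (p x M).

    Homogeneous LD (one group): ``Z~ = sum_k w_k C_k (P Z_k + gamma E_k)``
    with E_k drawn independently per study. Heterogeneous LD: knockoff
    Z-scores are formed per group with the group's P_l, V_l and
    gamma_l, then combined with sqrt(n_l / N) weights. Fully seeded.
    """
    if isinstance(models, KnockoffModel):
        models = {g: models for g in np.unique(panel.group)}
    groups = np.unique(panel.group)
    for g in groups:
        if g not in models:
            raise ValueError(f"no knockoff model for LD group {g!r}")
    if gammas is None:
        gammas = {g: weights.gamma for g in groups}
    M = models[groups[0]].M
    rng = np.random.default_rng(seed)

    if len(groups) == 1:
        model = models[groups[0]]
        gamma = gammas[groups[0]]
        zt = np.zeros((panel.p, M))
        for k in range(panel.K):
            zk = np.where(panel.mask[:, k], panel.Z[:, k], 0.0)
            kz = sample_knockoff_z(model, zk, gamma=gamma, rng=rng, seed=None)
            zt += weights.w[k] * (panel.mask[:, k, None] * kz.z_knock)
        return zt

    # heterogeneous: per-group knockoffs with the group's P_l, V_l, gamma_l;
    # with size weights w_k = sqrt(n_k/N) this is exactly the sqrt(n_l/N)
    # combination of per-group knockoff Z-scores
    zt = np.zeros((panel.p, M))
    for g in groups:
        model = models[g]
        for k in np.flatnonzero(panel.group == g):
            zk = np.where(panel.mask[:, k], panel.Z[:, k], 0.0)
            kz = sample_knockoff_z(model, zk, gamma=gammas[g], rng=rng, seed=None)
            zt += weights.w[k] * (panel.mask[:, k, None] * kz.z_knock)
    return zt
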