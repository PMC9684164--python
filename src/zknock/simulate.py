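"""Synthetic cohorts for power/FDR/stability experiments.

Genotypes are generated as thresholded latent Gaussians: each of two
haplotypes per sample is a draw from N(0, C) for a block-AR(1) latent
correlation C, dichotomised at the MAF quantile, and summed to a 0/1/2
dosage. The latent-to-dosage correlation attenuation is therefore
realized, not assumed — the knockoff model in the experiment harness is
always built from the realized genotype correlations.

Phenotypes follow a sparse architecture with 10 causal variants whose
standardized effects ``beta_j = a / sqrt(2 m_j (1 - m_j))`` are scaled
so the variance contributed by the causal set equals a target (1 by
default). A quantitative trait adds an observed covariate X1 ~ N(0,1)
and unobserved noise eps ~ N(0,3); a dichotomous trait passes
``beta_0 + X1 + X2 + sum_j beta_j G_j`` through a logistic link with the
intercept calibrated to a 10% marginal prevalence. Only X1 is adjusted
in the analysis, so the generator deliberately includes unobserved
variance components.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy.stats import norm

from .filter import feature_stats, select
from .knockoff import KnockoffModel, build_knockoff_model, sample_knockoff_z
from .ld import estimate_ld
from .meta import (
    StudyPanel,
    effective_size_and_gamma,
    estimate_study_correlation,
    meta_knockoff_z,
    meta_z,
)
from .prep import prune_clusters

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "make_overlapping_studies",
    "simulate_phenotype",
    "compute_zscores",
    "evaluate_power_fdr",
    "stability_sd",
    "run_replicate",
    "run_experiment",
]


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one simulated two-study experiment.

    Defaults are a desk-scale profile of the reference design
    (n_study=1000, p=300, 100 replicates; the full-scale design used
    2500 samples/study, 2000 variants and 1000 replicates and remains
    one config change away). Everything else follows the reference
    conditions: 10 causal variants, total causal variance 1,
    eps ~ N(0,3), prevalence 10%, MAC > 25 filter, |r| >= 0.75 pruning,
    M = 5 knockoff copies.
    """

    n_study: int = 1000
    p: int = 300
    overlap: float = 0.25
    n_causal: int = 10
    trait: Literal["quantitative", "dichotomous"] = "quantitative"
    prevalence: float = 0.10
    total_causal_variance: float = 1.0
    ld_rho: float = 0.5          # AR(1) latent correlation within a block
    ld_block_size: int = 20      # latent blocks are independent of each other
    maf_range: tuple[float, float] = (0.05, 0.45)
    mac_min: int = 25
    prune_threshold: float = 0.75
    shrinkage: float = 0.05
    M: int = 5
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.n_causal > self.p:
            raise ValueError("more causal variants than variants")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")


def _latent_cov(p: int, rho: float, block_size: int) -> np.ndarray:
    """Block-diagonal AR(1) latent correlation."""
    C = np.eye(p)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        idx = np.arange(start, stop)
        C[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
    return C


def simulate_genotypes(
    n: int,
    p: int,
    rho: float = 0.5,
    block_size: int = 20,
    maf_range: tuple[float, float] = (0.05, 0.45),
    seed: int = 0,
):
    """Simulate 0/1/2 genotype dosages with block-AR(1) LD.

    Two independent latent-Gaussian haplotypes per sample are
    dichotomised at the per-variant MAF quantile and summed. Returns
    ``(G, maf)`` where ``maf`` holds the model (target) MAFs.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 0.5):
        raise ValueError("MAFs must lie strictly inside (0, 0.5)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=p)
    thresholds = norm.ppf(maf)
    C = _latent_cov(p, rho, block_size)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(p))
    hap1 = (rng.standard_normal((n, p)) @ L.T) < thresholds
    hap2 = (rng.standard_normal((n, p)) @ L.T) < thresholds
    G = hap1.astype(np.int8) + hap2.astype(np.int8)
    return G.astype(float), maf


def make_overlapping_studies(
    n_pool: int,
    n_study: int,
    overlap: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two study index sets with a controlled shared fraction.

    ``round(overlap * n_study)`` samples appear in both studies; the
    remaining members are disjoint.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    n_shared = int(round(overlap * n_study))
    n_unique = 2 * n_study - n_shared
    if n_unique > n_pool:
        raise ValueError(
            f"pool of {n_pool} too small for two studies of {n_study} "
            f"with {n_shared} shared samples ({n_unique} unique needed)"
        )
    rng = np.random.default_rng(seed)
    draw = rng.choice(n_pool, size=n_unique, replace=False)
    shared = draw[:n_shared]
    rest = draw[n_shared:]
    s1 = np.concatenate([shared, rest[: n_study - n_shared]])
    s2 = np.concatenate([shared, rest[n_study - n_shared:]])
    return np.sort(s1), np.sort(s2)


def _causal_effects(maf: np.ndarray, total_var: float) -> np.ndarray:
    """Per-variant effects beta_j = a / sqrt(2 m_j (1 - m_j)).

    Under Hardy-Weinberg the model variance of dosage j is
    2 m_j (1 - m_j), so each causal variant contributes exactly a^2 and
    ``a = sqrt(total_var / n_causal)``.
    """
    a = np.sqrt(total_var / maf.shape[0])
    return a / np.sqrt(2.0 * maf * (1.0 - maf))


def simulate_phenotype(
    G: np.ndarray,
    causal_idx: np.ndarray,
    causal_maf: np.ndarray,
    trait: str = "quantitative",
    prevalence: float = 0.10,
    total_var: float = 1.0,
    seed: int = 0,
):
    """Simulate a phenotype with the given causal set.

    Returns ``(Y, X1, beta)`` with ``beta`` the full-length effect
    vector (zeros off the causal set). The dichotomous intercept is
    calibrated by bisection on the Monte-Carlo marginal prevalence of
    the realized linear predictor (tolerance 0.002).
    """
    n = G.shape[0]
    rng = np.random.default_rng(seed)
    causal_idx = np.asarray(causal_idx, dtype=int)
    beta = np.zeros(G.shape[1])
    if causal_idx.size:
        beta[causal_idx] = _causal_effects(
            np.asarray(causal_maf, dtype=float), total_var
        )
    Gc = G[:, causal_idx] - G[:, causal_idx].mean(axis=0)
    genetic = Gc @ beta[causal_idx]
    X1 = rng.standard_normal(n)

    if trait == "quantitative":
        eps = rng.standard_normal(n) * np.sqrt(3.0)
        Y = X1 + genetic + eps
        return Y, X1, beta
    if trait != "dichotomous":
        raise ValueError(f"unknown trait type {trait!r}")

    X2 = rng.standard_normal(n)
    eta = X1 + X2 + genetic

    def prev(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    lo, hi = -30.0, 30.0
    if not (prev(lo) < prevalence < prev(hi)):
        raise RuntimeError("prevalence calibration failed to bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prev(mid) < prevalence:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    b0 = 0.5 * (lo + hi)
    if abs(prev(b0) - prevalence) > 0.002:
        raise RuntimeError("prevalence calibration did not converge")
    mu = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    Y = (rng.random(n) < mu).astype(float)
    return Y, X1, beta


def compute_zscores(G: np.ndarray, Y: np.ndarray, X: np.ndarray | None = None) -> np.ndarray:
    """Score-test Z-scores ``Z = G' Y / sqrt(n)``.

    Y is first residualized on the observed covariates (with an
    intercept) and standardized; genotype columns are standardized.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = G.shape[0]
    if X is not None:
        X = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
        Y = Y - X @ np.linalg.lstsq(X, Y, rcond=None)[0]
    else:
        Y = Y - Y.mean()
    sd_y = Y.std()
    if sd_y == 0:
        raise ValueError("phenotype has zero variance after residualization")
    Y = Y / sd_y
    sd_g = G.std(axis=0)
    if np.any(sd_g == 0):
        raise ValueError(
            f"zero-variance genotype columns: {np.flatnonzero(sd_g == 0).tolist()}"
        )
    Gs = (G - G.mean(axis=0)) / sd_g
    return (Gs.T @ Y) / np.sqrt(n)


def evaluate_power_fdr(selected, causal) -> tuple[float, float]:
    """Empirical power and false discovery proportion of one selection.

    power = |selected & causal| / |causal|;
    fdp = |selected \\ causal| / max(|selected|, 1) (empty selection
    counts as zero false discoveries).
    """
    selected = set(np.asarray(selected).tolist())
    causal = set(np.asarray(causal).tolist())
    if not causal:
        raise ValueError("causal set must be nonempty")
    power = len(selected & causal) / len(causal)
    fdp = len(selected - causal) / max(len(selected), 1)
    return power, fdp


def stability_sd(
    z: np.ndarray,
    model: KnockoffModel,
    gamma: float = 1.0,
    n_draws: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-variant SD of W across repeated knockoff draws for fixed data.

    Quantifies the randomness introduced purely by sampling knockoff
    copies; more copies per variant average this randomness down.
    """
    if n_draws < 2:
        raise ValueError("need at least two draws to estimate an SD")
    rng = np.random.default_rng(seed)
    Ws = np.empty((n_draws, model.p))
    for d in range(n_draws):
        kz = sample_knockoff_z(model, z, gamma=gamma, rng=rng, seed=None)
        st = feature_stats(z, kz.z_knock, tie_seed=int(rng.integers(2**31)))
        Ws[d] = st.W
    return Ws.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# experiment harness


def run_replicate(
    config: SimConfig,
    seed: int,
    target_fdrs: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2),
    rare_unobserved_frac: float = 0.0,
) -> dict:
    """One end-to-end two-study replicate of the power/FDR experiment.

    Generates a genotype pool, draws two overlapping studies, simulates
    one phenotype per unique individual, computes per-study Z-scores
    adjusted for X1 only, estimates the study correlation and the
    dependency factor, samples meta knockoff Z-scores and runs the
    filter at each target FDR. Returns per-target power/FDP plus the
    estimated overlap summary.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    n_pool = 2 * config.n_study

    G_pool, maf_model = simulate_genotypes(
        n_pool, config.p, rho=config.ld_rho, block_size=config.ld_block_size,
        maf_range=config.maf_range, seed=seeds[0],
    )
    # MAC filter on the pool
    mac = np.minimum(G_pool.sum(axis=0), 2 * n_pool - G_pool.sum(axis=0))
    keep = np.flatnonzero(mac > config.mac_min)
    G_pool = G_pool[:, keep]
    maf_model = maf_model[keep]

    # realized LD + tight-cluster pruning: analyze representatives only
    Sigma_all = estimate_ld(G_pool, shrinkage=config.shrinkage)
    cmap = prune_clusters(Sigma_all, threshold=config.prune_threshold, seed=seeds[1])
    rep = cmap.representative_indices(Sigma_all.variants)
    G = G_pool[:, rep]
    maf = maf_model[rep]
    Sigma = Sigma_all.subset(rep)
    model = build_knockoff_model(Sigma, M=config.M, method="equi")
    p = rep.size

    rng = np.random.default_rng(seeds[2])
    causal = np.sort(rng.choice(p, size=config.n_causal, replace=False))
    Y, X1, _ = simulate_phenotype(
        G, causal, maf[causal], trait=config.trait,
        prevalence=config.prevalence,
        total_var=config.total_causal_variance, seed=seeds[3],
    )

    s1, s2 = make_overlapping_studies(
        n_pool, config.n_study, config.overlap, seed=seeds[4]
    )
    Z = np.column_stack([
        compute_zscores(G[s1], Y[s1], X1[s1]),
        compute_zscores(G[s2], Y[s2], X1[s2]),
    ])
    mask = np.ones((p, 2), dtype=bool)
    if rare_unobserved_frac > 0:
        mrng = np.random.default_rng(seeds[5] + 1)
        rare = np.flatnonzero(maf < 0.01)
        for k in range(2):
            hide = mrng.random(rare.size) < rare_unobserved_frac
            mask[rare[hide], k] = False
    n_vec = np.full(2, config.n_study, dtype=float)
    panel = StudyPanel(Z=Z, n=n_vec, mask=mask)

    corS = estimate_study_correlation(panel, model, min_shared=min(100, p // 2))
    weights = effective_size_and_gamma(corS, n_vec, scheme="size")
    zm = meta_z(panel, weights)
    zt = meta_knockoff_z(panel, weights, model, seed=seeds[5])
    stats = feature_stats(zm, zt, tie_seed=seeds[5])

    out = {
        "corS12": float(corS[0, 1]),
        "gamma": weights.gamma,
        "n_analyzed": p,
        "per_target": {},
    }
    for q in target_fdrs:
        res = select(stats, q)
        power, fdp = evaluate_power_fdr(res.selected, causal)
        out["per_target"][q] = {"power": power, "fdp": fdp}
    return out


def run_experiment(
    config: SimConfig,
    target_fdrs: tuple[float, ...] = (0.05, 0.1, 0.15, 0.2),
    rare_unobserved_frac: float = 0.0,
):
    """Replicate loop: aggregate mean power/FDP and Monte-Carlo SEs.

    Returns a dict keyed by target FDR with mean_power, mean_fdp and
    their standard errors over ``config.replicates`` seeded replicates.
    """
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(config.replicates)]
    rows = {q: {"power": [], "fdp": []} for q in target_fdrs}
    gammas = []
    for rs in rep_seeds:
        rep = run_replicate(config, rs, target_fdrs, rare_unobserved_frac)
        gammas.append(rep["gamma"])
        for q in target_fdrs:
            rows[q]["power"].append(rep["per_target"][q]["power"])
            rows[q]["fdp"].append(rep["per_target"][q]["fdp"])
    summary = {}
    R = config.replicates
    for q in target_fdrs:
        pw = np.asarray(rows[q]["power"])
        fd = np.asarray(rows[q]["fdp"])
        summary[q] = {
            "mean_power": float(pw.mean()),
            "mean_fdp": float(fd.mean()),
            "se_power": float(pw.std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0,
            "se_fdp": float(fd.std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0,
        }
    summary["mean_gamma"] = float(np.mean(gammas))
    return summary
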