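"""Multiple-knockoff filter: kappa/tau/W statistics, threshold, q-values.

The importance score is the squared Z-score. For each variant the
original score and its M knockoff scores are compared: ``kappa`` is the
index of the winner (0 = original), ``tau`` is the gap between the
winner and the median of the remaining M ordered scores, and
``W = tau * 1{kappa = 0}`` is the reported evidence of a direct effect.
Selection at target FDR q keeps variants whose tau clears the
data-dependent threshold

    min{ t > 0 : (1/M + #{kappa>=1, tau>=t}/M) / #{kappa=0, tau>=t} <= q }.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "FeatureStats",
    "SelectionResult",
    "feature_stats",
    "knockoff_threshold",
    "q_values",
    "select",
    "write_results",
]


@dataclasses.dataclass
class FeatureStats:
    """Per-variant importance scores and knockoff contrast statistics."""

    T: np.ndarray        # length p, original importance (z^2)
    T_knock: np.ndarray  # p x M
    kappa: np.ndarray    # length p ints in {0..M}
    tau: np.ndarray      # length p, >= 0
    W: np.ndarray        # length p, tau * 1{kappa == 0}

    @property
    def M(self) -> int:
        return self.T_knock.shape[1]

    @property
    def p(self) -> int:
        return self.T.shape[0]


@dataclasses.dataclass
class SelectionResult:
    """Outcome of the knockoff filter at one target FDR."""

    threshold: float
    qvalue: np.ndarray
    selected: np.ndarray   # indices, ascending
    target_fdr: float


def feature_stats(
    z: np.ndarray,
    z_knock: np.ndarray,
    tie_seed: int = 0,
) -> FeatureStats:
    """Compute kappa, tau and W from original and knockoff Z-scores.

    Ties for the maximum score are broken uniformly at random with
    ``tie_seed``; a deterministic tie-to-original rule would bias the
    false discovery proportion upward on quantized scores.
    """
    z = np.asarray(z, dtype=float)
    z_knock = np.asarray(z_knock, dtype=float)
    if z_knock.ndim != 2 or z_knock.shape[0] != z.shape[0]:
        raise ValueError("z_knock must be p x M with matching p")
    M = z_knock.shape[1]
    if M < 1:
        raise ValueError("need at least one knockoff copy (M >= 1)")
    bad = ~np.isfinite(z) | ~np.isfinite(z_knock).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite Z-scores at variant indices {np.flatnonzero(bad).tolist()}")

    T = z ** 2
    T_knock = z_knock ** 2
    scores = np.column_stack([T, T_knock])         # p x (M+1), col 0 = original

    rng = np.random.default_rng(tie_seed)
    # uniform random tie-break among the columns attaining the row maximum
    is_max = scores == scores.max(axis=1, keepdims=True)
    keys = np.where(is_max, rng.random(scores.shape), -1.0)
    kappa = np.argmax(keys, axis=1).astype(np.int64)

    sorted_scores = np.sort(scores, axis=1)        # ascending
    top = sorted_scores[:, -1]
    rest = sorted_scores[:, :-1]                   # the remaining M scores
    tau = top - np.median(rest, axis=1)
    tau = np.maximum(tau, 0.0)
    W = tau * (kappa == 0)
    return FeatureStats(T=T, T_knock=T_knock, kappa=kappa, tau=tau, W=W)


def _fdp_hat(kappa: np.ndarray, tau: np.ndarray, t: float, M: int) -> float:
    """Knockoff FDR estimate at candidate threshold t."""
    at = tau >= t
    num = (1.0 + np.count_nonzero(at & (kappa >= 1))) / M
    den = np.count_nonzero(at & (kappa == 0))
    return num / den if den > 0 else np.inf


def knockoff_threshold(
    kappa: np.ndarray,
    tau: np.ndarray,
    target_fdr: float,
    M: int,
) -> float:
    """Data-dependent selection threshold at the target FDR.

    Scans the observed positive tau values (the estimate is piecewise
    constant between them) and returns the smallest t whose estimated
    FDP is <= target; +inf when no candidate qualifies (empty
    selection).
    """
    kappa = np.asarray(kappa)
    tau = np.asarray(tau, dtype=float)
    if kappa.size == 0:
        raise ValueError("empty input")
    if not 0.0 < target_fdr < 1.0:
        raise ValueError("target FDR must be in (0, 1)")
    candidates = np.unique(tau[tau > 0])
    for t in candidates:                            # ascending: first hit is min
        if _fdp_hat(kappa, tau, t, M) <= target_fdr:
            return float(t)
    return np.inf


def q_values(kappa: np.ndarray, tau: np.ndarray, M: int) -> np.ndarray:
    """Per-variant knockoff q-values.

    For kappa=0, ``q_j = min_{0 < t <= tau_j} fdp_hat(t)`` capped at 1;
    variants with kappa != 0 get q = 1 and are never selected.
    Selecting {q <= alpha} equals thresholding at target FDR alpha.
    """
    kappa = np.asarray(kappa)
    tau = np.asarray(tau, dtype=float)
    q = np.ones(kappa.shape[0])
    candidates = np.unique(tau[tau > 0])            # ascending
    if candidates.size == 0:
        return q
    ratios = np.array([_fdp_hat(kappa, tau, t, M) for t in candidates])
    prefix_min = np.minimum.accumulate(ratios)      # min over t' <= t
    orig = (kappa == 0) & (tau > 0)
    pos = np.searchsorted(candidates, tau[orig], side="right") - 1
    q[orig] = np.minimum(prefix_min[pos], 1.0)
    return q


def select(stats: FeatureStats, target_fdr: float) -> SelectionResult:
    """Apply the knockoff filter, returning threshold, q-values and the set.

    The selected set is {kappa = 0, tau >= threshold}, identically
    {q <= target_fdr}. The filter is a function of the pooled kappa/tau
    only, so statistics from several genomic blocks must be
    concatenated before calling (one global threshold).
    """
    thr = knockoff_threshold(stats.kappa, stats.tau, target_fdr, stats.M)
    q = q_values(stats.kappa, stats.tau, stats.M)
    selected = np.flatnonzero(q <= target_fdr)
    return SelectionResult(
        threshold=thr, qvalue=q, selected=selected, target_fdr=target_fdr
    )


def write_results(
    path,
    table: pd.DataFrame,
    stats: FeatureStats,
    result: SelectionResult,
) -> pd.DataFrame:
    """Write the per-variant results table (tab-separated).

    ``table`` carries CHR, POS, REF, ALT and Z for the analyzed
    representative variants, in the same order as the statistics.
    """
    out = table.loc[:, ["CHR", "POS", "REF", "ALT", "Z"]].copy()
    out["W"] = stats.W
    out["KAPPA"] = stats.kappa
    out["TAU"] = stats.tau
    out["QVALUE"] = result.qvalue
    sel = np.zeros(stats.p, dtype=int)
    sel[result.selected] = 1
    out["SELECTED"] = sel
    out.to_csv(path, sep="\t", index=False)
    return out
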