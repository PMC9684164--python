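"""Preprocessing: p-to-Z conversion, variant filtering, LD pruning, blocks.

Variant tables are plain pandas DataFrames with VCF-convention 1-based
coordinates and columns CHR, POS, REF, ALT plus whatever the step needs
(MAF, MAC, Z, ...), sorted by (CHR, POS) with unique
(CHR, POS, REF, ALT) keys.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .ld import LDMatrix

__all__ = [
    "z_from_pvalue",
    "filter_variants",
    "ClusterMap",
    "prune_clusters",
    "partition_blocks",
    "harmonize",
]

P_FLOOR = 1e-300


def z_from_pvalue(p, direction, floor: float = P_FLOOR):
    """Signed Z-score from a two-sided p-value and an effect direction.

    Returns ``direction * |Phi^-1(p/2)|``: the magnitude recovers the
    two-sided test statistic and the sign carries the direction of
    effect. p = 1 maps to 0. Vectorised.
    """
    p = np.asarray(p, dtype=float)
    direction = np.sign(np.asarray(direction, dtype=float))
    if np.any((p <= 0) | (p > 1)):
        bad = np.flatnonzero((p <= 0) | (p > 1))
        raise ValueError(
            f"p-values must lie in (0, 1]; offending indices {bad.tolist()} "
            f"(floor exact zeros at {floor:g} upstream)"
        )
    if np.any(direction == 0):
        raise ValueError("direction of effect must be nonzero")
    z = direction * np.abs(norm.ppf(np.maximum(p, floor) / 2.0))
    return z if z.ndim else float(z)


def filter_variants(
    table: pd.DataFrame,
    maf_min: float = 0.01,
    mac_min: int = 25,
) -> pd.DataFrame:
    """Drop variants failing the MAF/MAC thresholds.

    Keeps rows with ``MAF > maf_min`` and ``MAC > mac_min`` (both
    strict, matching the common/low-frequency restriction MAF > 1% and
    the simulation filter MAC > 25). Pass 0 for either to disable it.
    """
    keep = np.ones(len(table), dtype=bool)
    if maf_min > 0:
        keep &= table["MAF"].to_numpy() > maf_min
    if mac_min > 0:
        keep &= table["MAC"].to_numpy() > mac_min
    out = table.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("no variants survive the MAF/MAC filter")
    return out


@dataclasses.dataclass
class ClusterMap:
    """Tight-LD clusters and their randomly chosen representatives."""

    representative: list                 # one variant id per cluster
    members: dict                        # cluster index -> list of variant ids
    labels: np.ndarray                   # per-variant cluster index
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.representative)

    def representative_indices(self, variants: list) -> np.ndarray:
        """Positions of the representatives within ``variants``."""
        lookup = {v: i for i, v in enumerate(variants)}
        return np.asarray([lookup[v] for v in self.representative], dtype=int)


def prune_clusters(
    Sigma: LDMatrix,
    threshold: float = 0.75,
    seed: int = 0,
) -> ClusterMap:
    """Cluster tightly linked variants and pick one representative each.

    Complete-linkage hierarchical clustering on distance 1 - |r|, cut
    at 1 - threshold: complete linkage is the one standard linkage that
    guarantees every within-cluster pair satisfies |r| >= threshold.
    The representative of each cluster is drawn uniformly at random
    (seeded) so the analyzed set is unbiased with respect to position.
    """
    p = Sigma.p
    rng = np.random.default_rng(seed)
    if p == 1:
        return ClusterMap(
            representative=[Sigma.variants[0]],
            members={0: [Sigma.variants[0]]},
            labels=np.zeros(1, dtype=int),
            threshold=threshold,
        )
    dist = 1.0 - np.abs(Sigma.R)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    labels = hierarchy.fcluster(link, t=1.0 - threshold, criterion="distance")
    labels = np.asarray(labels) - 1  # zero-based

    members: dict[int, list] = {}
    representative: list = []
    for c in range(labels.max() + 1):
        idx = np.flatnonzero(labels == c)
        members[c] = [Sigma.variants[i] for i in idx]
        representative.append(Sigma.variants[idx[rng.integers(idx.size)]])
    return ClusterMap(
        representative=representative,
        members=members,
        labels=labels,
        threshold=threshold,
    )


def partition_blocks(
    table: pd.DataFrame,
    block_span: int = 1_000_000,
    block_max: int = 1000,
    cluster_labels: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Split a sorted variant table into contiguous analysis blocks.

    Blocks are non-overlapping index ranges covering all rows, each
    holding at most ``block_max`` variants and spanning at most
    ``block_span`` base pairs; a new chromosome always starts a new
    block. When ``cluster_labels`` is given, a block boundary is never
    placed inside a cluster: the block is extended until the open
    cluster closes (clusters are assumed position-contiguous, which
    complete-linkage LD clusters are in practice).
    """
    chroms = table["CHR"].to_numpy()
    pos = table["POS"].to_numpy()
    n = len(table)
    if n == 0:
        return []

    def splittable(i: int) -> bool:
        # a boundary may be placed before row i
        if cluster_labels is None:
            return True
        return cluster_labels[i] != cluster_labels[i - 1]

    blocks: list[np.ndarray] = []
    start = 0
    for i in range(1, n + 1):
        if i == n:
            blocks.append(np.arange(start, n))
            break
        new_chrom = chroms[i] != chroms[start]
        too_big = (i - start) >= block_max
        too_wide = (pos[i] - pos[start]) > block_span
        if new_chrom or ((too_big or too_wide) and splittable(i)):
            blocks.append(np.arange(start, i))
            start = i
    return blocks


def harmonize(ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Align a study's summary statistics onto a reference variant table.

    Matching is on (CHR, POS, REF, ALT); a study row whose alleles are
    swapped relative to the reference is kept with its Z sign flipped.
    Strand-ambiguous A/T and C/G variants are dropped (their
    orientation cannot be resolved from alleles alone). Returns the
    reference table with a Z column (NaN where the study lacks the
    variant) and an OBSERVED flag.
    """
    key = ["CHR", "POS", "REF", "ALT"]
    other = other.copy()
    ambiguous = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    amb = other.apply(lambda r: (r["REF"], r["ALT"]) in ambiguous, axis=1)
    if amb.any():
        import warnings

        warnings.warn(
            f"dropping {int(amb.sum())} strand-ambiguous A/T or C/G variants",
            stacklevel=2,
        )
        other = other.loc[~amb]

    direct = other.set_index(key)["Z"]
    flipped = other.rename(columns={"REF": "ALT", "ALT": "REF"}).set_index(key)["Z"]

    out = ref.copy()
    idx = pd.MultiIndex.from_frame(ref[key])
    z = pd.Series(np.nan, index=idx)
    hit = idx.isin(direct.index)
    z[hit] = direct.reindex(idx[hit]).to_numpy()
    flip = idx.isin(flipped.index) & ~hit
    z[flip] = -flipped.reindex(idx[flip]).to_numpy()
    out["Z"] = z.to_numpy()
    out["OBSERVED"] = ~np.isnan(out["Z"].to_numpy())
    return out
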