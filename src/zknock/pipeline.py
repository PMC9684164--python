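"""End-to-end workflows: model building, single-study and meta analysis.

The genome is processed in blocks (a practical memory bound; inter-block
LD is not modelled) but the knockoff filter is applied once to the
pooled per-block statistics — one global threshold, never per-block
thresholding. All randomness derives from one run-level seed; per-block
seeds are spawned deterministically so block order cannot change
results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .filter import FeatureStats, feature_stats, select, write_results
from .knockoff import KnockoffModel, build_knockoff_model, sample_knockoff_z, save_models
from .ld import estimate_ld
from .meta import (
    StudyPanel,
    effective_size_and_gamma,
    estimate_study_correlation,
    meta_knockoff_z,
    meta_z,
    optimal_weights,
)
from .prep import filter_variants, partition_blocks, prune_clusters

log = logging.getLogger(__name__)

__all__ = ["build_model_cache", "run_single", "run_meta", "RunResult"]


@dataclasses.dataclass
class RunResult:
    """Everything a pipeline run produces, before or after writing."""

    table: pd.DataFrame          # analyzed representatives with stats
    stats: FeatureStats
    selection: object
    manifest: dict
    pruned: pd.DataFrame         # member -> representative mapping


def _block_seed(run_seed: int, block_index: int) -> int:
    """Deterministic per-block seed independent of block order."""
    return int(
        np.random.SeedSequence([run_seed, block_index + 1]).generate_state(1)[0]
        % 2**31
    )


def build_model_cache(
    table: pd.DataFrame,
    G: np.ndarray,
    out_path,
    M: int = 5,
    method: str = "equi",
    shrinkage: float = 0.1,
    maf_min: float = 0.01,
    mac_min: int = 0,
    prune_threshold: float = 0.75,
    block_span: int = 1_000_000,
    block_max: int = 1000,
    seed: int = 0,
):
    """Build per-block knockoff models from a reference panel and cache them.

    Filters variants, estimates per-block LD, prunes tight clusters
    (|r| >= threshold) to representatives, solves the knockoff program
    per block and writes one .npz container keyed by block id. Returns
    ``(models, rep_table, pruned_map)``.
    """
    n_before = len(table)
    table = filter_variants(table, maf_min=maf_min, mac_min=mac_min)
    keep_idx = table.index.to_numpy()
    log.info("variant filter kept %d / %d", len(table), n_before)
    G = G[:, keep_idx] if G.shape[1] == n_before else G
    table = table.reset_index(drop=True)

    blocks = partition_blocks(table, block_span=block_span, block_max=block_max)
    models: dict[str, KnockoffModel] = {}
    rep_rows, pruned_rows = [], []
    for b, idx in enumerate(blocks):
        sub = table.iloc[idx]
        vids = [
            f"{r.CHR}:{r.POS}:{r.REF}:{r.ALT}" for r in sub.itertuples()
        ]
        Sigma = estimate_ld(G[:, idx], shrinkage=shrinkage, variants=vids)
        cmap = prune_clusters(Sigma, threshold=prune_threshold, seed=_block_seed(seed, b))
        rep_idx = cmap.representative_indices(Sigma.variants)
        Sigma_rep = Sigma.subset(rep_idx)
        log.info(
            "block %d: %d variants, %d representatives, lambda_min=%.3e",
            b, len(idx), rep_idx.size, Sigma_rep.min_eigenvalue(),
        )
        models[f"block{b:05d}"] = build_knockoff_model(Sigma_rep, M=M, method=method)
        rep_rows.append(sub.iloc[rep_idx].assign(BLOCK=f"block{b:05d}"))
        for c, mem in cmap.members.items():
            rep = cmap.representative[c]
            for v in mem:
                pruned_rows.append({"VARIANT": v, "REPRESENTATIVE": rep, "BLOCK": f"block{b:05d}"})

    rep_table = pd.concat(rep_rows, ignore_index=True)
    pruned_map = pd.DataFrame(pruned_rows)
    if out_path is not None:
        save_models(models, out_path)
    return models, rep_table, pruned_map


def _align(study: pd.DataFrame, rep_table: pd.DataFrame):
    """Z-vector and observation mask of one study over the representative set."""
    key = ["CHR", "POS", "REF", "ALT"]
    z = study.set_index(key)["Z"]
    idx = pd.MultiIndex.from_frame(rep_table[key].astype({"CHR": str}))
    aligned = z.reindex(idx).to_numpy(dtype=float)
    mask = ~np.isnan(aligned)
    return np.where(mask, aligned, 0.0), mask


def _pooled_stats(models, rep_table, Z_fn, tie_seed):
    """Sample knockoffs per block, concatenate, compute pooled stats."""
    zs, zks = [], []
    for bid in sorted(models):
        z_b, zk_b = Z_fn(bid)
        zs.append(z_b)
        zks.append(zk_b)
    z = np.concatenate(zs)
    zk = np.vstack(zks)
    return feature_stats(z, zk, tie_seed=tie_seed), z


def run_single(
    study: pd.DataFrame,
    models: dict[str, KnockoffModel],
    rep_table: pd.DataFrame,
    target_fdr: float = 0.1,
    seed: int = 0,
) -> RunResult:
    """Single-study knockoff analysis over cached per-block models."""
    order = sorted(models)
    block_tables = {bid: rep_table[rep_table["BLOCK"] == bid] for bid in order}
    for bid in order:
        if len(block_tables[bid]) != models[bid].p:
            raise ValueError(
                f"{bid}: model has {models[bid].p} variants but the table has "
                f"{len(block_tables[bid])}; rebuild the cache"
            )

    def per_block(bid):
        b = order.index(bid)
        z, mask = _align(study, block_tables[bid])
        kz = sample_knockoff_z(models[bid], z, gamma=1.0, seed=_block_seed(seed, b))
        return z, mask[:, None] * kz.z_knock

    stats, z = _pooled_stats(models, rep_table, per_block, tie_seed=_block_seed(seed, -1))
    sel = select(stats, target_fdr)
    table = rep_table.copy()
    table["Z"] = z
    manifest = {
        "version": __version__,
        "mode": "single",
        "seed": seed,
        "target_fdr": target_fdr,
        "M": models[order[0]].M,
        "n_blocks": len(order),
        "n_variants": int(len(table)),
        "n_selected": int(sel.selected.size),
        "threshold": float(sel.threshold),
    }
    return RunResult(table=table, stats=stats, selection=sel, manifest=manifest, pruned=pd.DataFrame())


def run_meta(
    studies: list[pd.DataFrame],
    n: np.ndarray,
    models: dict[str, KnockoffModel],
    rep_table: pd.DataFrame,
    target_fdr: float = 0.1,
    weights_scheme: str = "size",
    n_case: np.ndarray | None = None,
    n_control: np.ndarray | None = None,
    seed: int = 0,
    min_shared: int = 100,
) -> RunResult:
    """Meta-analysis of K aligned studies with overlap-aware knockoffs.

    Estimates the study correlation once from all blocks pooled,
    derives weights (size or optimal) and the dependency factor gamma,
    then samples meta knockoff Z-scores per block and applies the
    global filter.
    """
    order = sorted(models)
    n = np.asarray(n, dtype=float)
    K = len(studies)
    block_tables = {bid: rep_table[rep_table["BLOCK"] == bid] for bid in order}

    # align all studies per block
    aligned = {}
    for bid in order:
        Zb = np.empty((len(block_tables[bid]), K))
        Mb = np.empty((len(block_tables[bid]), K), dtype=bool)
        for k, st in enumerate(studies):
            Zb[:, k], Mb[:, k] = _align(st, block_tables[bid])
        aligned[bid] = (Zb, Mb)

    # genome-wide study correlation from pooled decorrelated Z-scores
    U_all, Z_all, M_all = [], [], []
    for bid in order:
        Zb, Mb = aligned[bid]
        Ub = np.column_stack([
            models[bid].decorrelate(np.where(Mb[:, k], Zb[:, k], 0.0))
            for k in range(K)
        ])
        U_all.append(Ub)
        Z_all.append(Zb)
        M_all.append(Mb)
    panel_all = StudyPanel(Z=np.vstack(Z_all), n=n, mask=np.vstack(M_all))
    # one pooled pseudo-model is impossible across blocks; correlate directly
    corS = _cor_from_decorrelated(
        np.vstack(U_all), panel_all.Z, panel_all.mask, z_cap=1.96,
        min_shared=min_shared,
    )

    if weights_scheme == "optimal":
        w = optimal_weights(corS, n, n_case=n_case, n_control=n_control)
        weights = effective_size_and_gamma(corS, n, w=w, scheme="optimal")
    else:
        weights = effective_size_and_gamma(corS, n, scheme="size")

    def per_block(bid):
        b = order.index(bid)
        Zb, Mb = aligned[bid]
        panel = StudyPanel(Z=Zb, n=n, mask=Mb)
        zm = meta_z(panel, weights)
        zt = meta_knockoff_z(panel, weights, models[bid], seed=_block_seed(seed, b))
        return zm, zt

    stats, z = _pooled_stats(models, rep_table, per_block, tie_seed=_block_seed(seed, -1))
    sel = select(stats, target_fdr)
    table = rep_table.copy()
    table["Z"] = z
    manifest = {
        "version": __version__,
        "mode": "meta",
        "seed": seed,
        "target_fdr": target_fdr,
        "M": models[order[0]].M,
        "K": K,
        "weights_scheme": weights_scheme,
        "n": n.tolist(),
        "corS": weights.corS.tolist(),
        "weights": np.asarray(weights.w).tolist(),
        "N_eff": weights.N_eff,
        "gamma": weights.gamma,
        "n_blocks": len(order),
        "n_variants": int(len(table)),
        "n_selected": int(sel.selected.size),
        "threshold": float(sel.threshold),
    }
    return RunResult(table=table, stats=stats, selection=sel, manifest=manifest, pruned=pd.DataFrame())


def _cor_from_decorrelated(U, Z, mask, z_cap=1.96, min_shared=100):
    """Pairwise study correlation of decorrelated scores over shared nulls."""
    K = U.shape[1]
    corS = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            keep = (
                mask[:, i] & mask[:, j]
                & (np.abs(Z[:, i]) <= z_cap) & (np.abs(Z[:, j]) <= z_cap)
            )
            if int(keep.sum()) < min_shared:
                raise ValueError(
                    f"studies {i} and {j} share only {int(keep.sum())} null variants"
                )
            c = np.corrcoef(U[keep, i], U[keep, j])[0, 1]
            corS[i, j] = corS[j, i] = float(np.clip(c, -1.0, 1.0))
    from .ld import psd_repair

    return psd_repair(corS).R


def write_run(out_dir, result: RunResult, pruned_map: pd.DataFrame | None = None) -> None:
    """Write results table, JSON manifest and the pruned-variant map."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results(out_dir / "results.tsv", result.table, result.stats, result.selection)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    if pruned_map is not None and len(pruned_map):
        pruned_map.to_csv(out_dir / "pruned_variants.tsv", sep="\t", index=False)
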