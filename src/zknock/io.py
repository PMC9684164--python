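"""Readers for summary statistics and reference genotype panels."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .prep import z_from_pvalue

__all__ = ["read_sumstats", "read_vcf_panel", "read_plink_panel"]

REQUIRED = ["CHR", "POS", "REF", "ALT"]


def read_sumstats(path) -> pd.DataFrame:
    """Read one study's tab-separated summary statistics.

    Requires a header with CHR, POS, REF, ALT and either a Z column or
    P plus DIR (direction of effect); optional N, N_CASE, N_CONTROL
    are carried through. When only P/DIR are given, Z is derived as
    ``direction * |Phi^-1(p/2)|``. Gzip-transparent. Duplicate
    (CHR, POS, REF, ALT) keys and unparseable rows are rejected with
    the offending line numbers.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "REF": str, "ALT": str})
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "Z" not in df.columns:
        if not {"P", "DIR"}.issubset(df.columns):
            raise ValueError(f"{path}: need either a Z column or both P and DIR")
        df["Z"] = z_from_pvalue(df["P"].to_numpy(), df["DIR"].to_numpy())

    bad = df["POS"].isna() | df["Z"].isna() | ~np.isfinite(df["Z"].to_numpy(dtype=float))
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable rows at lines {lines[:20]}")

    dup = df.duplicated(subset=REQUIRED)
    if dup.any():
        lines = (np.flatnonzero(dup.to_numpy()) + 2).tolist()
        raise ValueError(f"{path}: duplicated variant keys at lines {lines[:20]}")

    df = df.sort_values(["CHR", "POS"], kind="stable").reset_index(drop=True)
    df["POS"] = df["POS"].astype(np.int64)
    return df


def read_vcf_panel(path, region: str | None = None):
    """Load reference genotypes from a VCF.

    Returns ``(table, G)`` where ``table`` has CHR/POS/REF/ALT/MAF/MAC
    and ``G`` is an n x p dosage matrix (0/1/2) with missing genotypes
    mean-imputed. Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    rows, cols = [], []
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1:
            continue
        # gt_types with gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        g = np.asarray(rec.gt_types, dtype=float)
        g = np.where(g == 3, np.nan, g)
        if np.all(np.isnan(g)):
            continue
        m = np.nanmean(g)
        g = np.where(np.isnan(g), m, g)
        ac = float(g.sum())
        n2 = 2.0 * g.shape[0]
        maf = min(ac, n2 - ac) / n2
        rows.append({
            "CHR": str(rec.CHROM), "POS": int(rec.POS),
            "REF": rec.REF, "ALT": rec.ALT[0],
            "MAF": maf, "MAC": int(round(min(ac, n2 - ac))),
        })
        cols.append(g)
    table = pd.DataFrame(rows)
    G = np.column_stack(cols) if cols else np.empty((0, 0))
    return table, G


def read_plink_panel(prefix):
    """Load reference genotypes from PLINK bed/bim/fam files.

    Minimal reader for the SNP-major 2-bit .bed encoding (magic bytes
    0x6c 0x1b 0x01). Dosages count ALT (bim allele 1) copies; missing
    genotypes are mean-imputed. Returns ``(table, G)`` as for
    :func:`read_vcf_panel`.
    """
    prefix = pathlib.Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["CHR", "ID", "CM", "POS", "A1", "A2"],
        dtype={"CHR": str, "A1": str, "A2": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n, p = len(fam), len(bim)

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or tuple(raw[:3]) != (0x6C, 0x1B, 0x01):
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:].reshape(p, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within each byte
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(p, -1)[:, :n]
    # PLINK codes: 00=hom A1, 01=missing, 10=het, 11=hom A2
    dosage = np.select(
        [codes == 0, codes == 2, codes == 3], [2.0, 1.0, 0.0], default=np.nan
    )
    G = dosage.T  # n x p, counting A1 (ALT) copies
    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    G[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    ac = G.sum(axis=0)
    n2 = 2.0 * n
    mac = np.minimum(ac, n2 - ac)
    table = bim.rename(columns={"A1": "ALT", "A2": "REF"})[
        ["CHR", "POS", "REF", "ALT"]
    ].copy()
    table["MAF"] = mac / n2
    table["MAC"] = np.round(mac).astype(int)
    return table, G
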