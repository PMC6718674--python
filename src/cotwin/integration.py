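"""Cis methylation-expression integration.

Probe-gene pairs within a +/-5 kb window of the gene's transcription start
site are scored with covariate-adjusted partial Pearson correlations across
all samples. Significance uses an empirical threshold: expression sample
labels are permuted B times (breaking any probe-gene linkage while keeping
covariates attached to the methylation samples), all cis-pair partial
correlations are recomputed, and the pooled null distribution's symmetric
two-tail quantiles at level alpha give (lower, upper). A config switch
selects the literal one-tail fifth-percentile reading instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cotwin.errors import ConfigError, ValidationError
from cotwin.io import log

__all__ = [
    "map_cis_pairs",
    "partial_corr",
    "permutation_threshold",
    "classify_cis_pairs",
    "robustness_with_mdd",
    "tss_offset_profile",
]


def map_cis_pairs(
    manifest: pd.DataFrame, gene_anno: pd.DataFrame, window: int = 5000
) -> pd.DataFrame:
    """All (probe, gene) pairs with |probe pos - gene TSS| <= window.

    The reported offset is strand-aware: positive when the probe lies
    downstream of the TSS in the gene's reading direction, negative when
    upstream.
    """
    rows = []
    for chrom, genes in gene_anno.groupby("chrom"):
        probes = manifest[manifest["chrom"] == chrom]
        if probes.empty:
            continue
        pos = probes["pos"].to_numpy()
        ids = probes["probe_id"].to_numpy()
        order = np.argsort(pos)
        pos, ids = pos[order], ids[order]
        for _, g in genes.iterrows():
            if pd.isna(g["tss"]):
                log.warning("gene %s has no TSS; skipped", g["gene_id"])
                continue
            tss = int(g["tss"])
            lo = np.searchsorted(pos, tss - window, side="left")
            hi = np.searchsorted(pos, tss + window, side="right")
            for k in range(lo, hi):
                raw = int(pos[k]) - tss
                offset = raw if g["strand"] == "+" else -raw
                rows.append(
                    {
                        "probe_id": ids[k],
                        "gene_id": g["gene_id"],
                        "offset": offset,
                    }
                )
    pairs = pd.DataFrame(rows, columns=["probe_id", "gene_id", "offset"])
    pairs = pairs.drop_duplicates(["probe_id", "gene_id"]).reset_index(drop=True)
    log.info("cis mapping: %d probe-gene pairs within +/-%d bp", len(pairs), window)
    return pairs


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each row of M after least-squares projection on [1, C]."""
    n = M.shape[-1]
    design = np.column_stack([np.ones(n), C]) if C.size else np.ones((n, 1))
    Q, _ = np.linalg.qr(design)
    return M - (M @ Q) @ Q.T


def partial_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> float:
    """Partial Pearson correlation of x and y given covariates.

    Equals the plain Pearson correlation of the residuals of x and y after
    projection on an intercept plus the covariate columns; with no
    covariates it reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = np.empty((len(x), 0)) if covariates is None else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    k = C.shape[1]
    if len(x) < k + 3:
        raise ValidationError("need at least k+3 samples for k covariates")
    rx = _residualize(x[None, :], C)[0]
    ry = _residualize(y[None, :], C)[0]
    # zero residual variance (constant or fully explained input) is undefined
    if np.linalg.norm(rx) <= 1e-10 * max(1.0, np.linalg.norm(x)) or np.linalg.norm(
        ry
    ) <= 1e-10 * max(1.0, np.linalg.norm(y)):
        return float("nan")
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    return float(np.clip(rx @ ry / denom, -1.0, 1.0))


def _pair_correlations(
    meth_r: np.ndarray,
    expr_r: np.ndarray,
    probe_idx: np.ndarray,
    gene_idx: np.ndarray,
) -> np.ndarray:
    """Correlations of pre-residualized rows for each (probe, gene) pair."""
    mn = meth_r / np.maximum(np.linalg.norm(meth_r, axis=1, keepdims=True), 1e-300)
    en = expr_r / np.maximum(np.linalg.norm(expr_r, axis=1, keepdims=True), 1e-300)
    return np.clip(np.einsum("ij,ij->i", mn[probe_idx], en[gene_idx]), -1.0, 1.0)


def _prepare(meth, expr, covariates, pairs):
    probe_index = pd.Index(meth.index)
    gene_index = pd.Index(expr.index)
    known = pairs["probe_id"].isin(probe_index) & pairs["gene_id"].isin(gene_index)
    pairs = pairs[known].reset_index(drop=True)
    probe_idx = probe_index.get_indexer(pairs["probe_id"])
    gene_idx = gene_index.get_indexer(pairs["gene_id"])
    C = np.asarray(covariates, float) if covariates is not None else np.empty((meth.shape[1], 0))
    return pairs, probe_idx, gene_idx, C


def permutation_threshold(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    covariates: np.ndarray | None,
    pairs: pd.DataFrame,
    B: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    tail: str = "two-sided",
) -> tuple[float, float]:
    """Empirical correlation threshold from expression-label permutations.

    For each of B permutations the expression matrix's sample labels are
    shuffled and every cis-pair partial correlation recomputed; the pooled
    null gives the alpha/2 and 1-alpha/2 quantiles (``tail="two-sided"``,
    default) or the +/- one-tail alpha quantile magnitude
    (``tail="one-sided"``).
    """
    if B < 20:
        raise ConfigError("at least 20 permutations are required")
    if meth.shape[1] != expr.shape[1]:
        raise ValidationError("methylation and expression sample counts differ")
    pairs, probe_idx, gene_idx, C = _prepare(meth, expr, covariates, pairs)
    if not len(pairs):
        raise ValidationError("no cis pairs present in the matrices")
    rng = np.random.default_rng(seed)
    meth_r = _residualize(meth.to_numpy(float), C)
    expr_vals = np.log2(expr.to_numpy(float) + 1.0)
    n = meth.shape[1]
    null = np.empty((B, len(pairs)))
    for b in range(B):
        perm = rng.permutation(n)
        expr_r = _residualize(expr_vals[:, perm], C)
        null[b] = _pair_correlations(meth_r, expr_r, probe_idx, gene_idx)
    pooled = null.ravel()
    if tail == "one-sided":
        upper = float(np.quantile(pooled, 1.0 - alpha))
        lower = -upper
    else:
        lower = float(np.quantile(pooled, alpha / 2.0))
        upper = float(np.quantile(pooled, 1.0 - alpha / 2.0))
    log.info(
        "permutation threshold (B=%d, alpha=%g, seed=%d): (%.4f, %.4f)",
        B, alpha, seed, lower, upper,
    )
    return lower, upper


def classify_cis_pairs(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    covariates: np.ndarray | None,
    pairs: pd.DataFrame,
    thresholds: tuple[float, float],
    offset_bin_bp: int = 500,
    window: int = 5000,
) -> tuple[pd.DataFrame, dict]:
    """Score every cis pair and classify against the permutation thresholds.

    Returns the classified pair table (partial_r, significant, sign) and a
    summary dict with the count, negative fraction among significant pairs,
    unique probes/genes, and the TSS-offset profile (mean partial_r per
    ``offset_bin_bp`` bin across [-window, +window]).
    """
    lower, upper = thresholds
    pairs, probe_idx, gene_idx, C = _prepare(meth, expr, covariates, pairs)
    meth_r = _residualize(meth.to_numpy(float), C)
    expr_r = _residualize(np.log2(expr.to_numpy(float) + 1.0), C)
    r = _pair_correlations(meth_r, expr_r, probe_idx, gene_idx)
    out = pairs.copy()
    out["partial_r"] = r
    out["significant"] = (r < lower) | (r > upper)
    out["sign"] = np.where(r < 0, "negative", "positive")

    sig = out[out["significant"]]
    edges = np.arange(-window, window + offset_bin_bp, offset_bin_bp)
    bin_idx = np.clip(np.digitize(out["offset"], edges) - 1, 0, len(edges) - 2)
    profile = (
        pd.DataFrame({"bin_start": edges[bin_idx], "partial_r": out["partial_r"]})
        .groupby("bin_start")["partial_r"]
        .mean()
        .reset_index()
    )
    summary = {
        "n_pairs": int(len(out)),
        "n_significant": int(len(sig)),
        "negative_fraction": float((sig["sign"] == "negative").mean()) if len(sig) else float("nan"),
        "n_unique_probes": int(sig["probe_id"].nunique()),
        "n_unique_genes": int(sig["gene_id"].nunique()),
        "offset_profile": profile,
    }
    return out, summary


def robustness_with_mdd(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    covariates: np.ndarray | None,
    classified: pd.DataFrame,
    mdd_status: np.ndarray,
    thresholds: tuple[float, float],
) -> float:
    """Fraction of significant cis pairs that stay beyond the thresholds
    after adding the MDD indicator to the covariates."""
    sig = classified[classified["significant"]]
    if not len(sig):
        return float("nan")
    mdd = np.asarray(mdd_status, float)[:, None]
    C = mdd if covariates is None else np.column_stack([np.asarray(covariates, float), mdd])
    pairs, probe_idx, gene_idx, C = _prepare(meth, expr, C, sig)
    meth_r = _residualize(meth.to_numpy(float), C)
    expr_r = _residualize(np.log2(expr.to_numpy(float) + 1.0), C)
    r = _pair_correlations(meth_r, expr_r, probe_idx, gene_idx)
    lower, upper = thresholds
    return float(np.mean((r < lower) | (r > upper)))


def tss_offset_profile(classified: pd.DataFrame, offset_bin_bp: int = 500, window: int = 5000) -> pd.DataFrame:
    """Mean partial correlation per TSS-offset bin (negative = upstream)."""
    edges = np.arange(-window, window + offset_bin_bp, offset_bin_bp)
    bin_idx = np.clip(np.digitize(classified["offset"], edges) - 1, 0, len(edges) - 2)
    return (
        pd.DataFrame({"bin_start": edges[bin_idx], "partial_r": classified["partial_r"]})
        .groupby("bin_start")["partial_r"]
        .mean()
        .reset_index()
    )
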