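"""DMR calling: cluster adjacent probes, score regions, apply the criteria.

Candidate regions are maximal runs of same-chromosome probes with
inter-probe gaps of at most ``max_gap_bp`` (default 1000 bp); singletons
are discarded. Each candidate is scored with the probe-level scan results:
the peak (minimum) probe p, a region p from an equal-weight signed Stouffer
combination of probe z-scores, the mean fold change 2**(mean alpha), the
mean within-pair percent methylation difference over probes, and the mean
pairwise Pearson correlation of probe betas across all samples.

A DMR must contain at least ``min_probes`` probes with peak probe
p < ``peak_p_max`` and probe correlation >= ``min_corr``; significance is
a Benjamini-Hochberg q < 0.05 over the region p-values of all scored
candidates (the candidate count is the correction denominator).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from cotwin.errors import ValidationError
from cotwin.io import log
from cotwin.pair_model import bh_fdr

__all__ = [
    "form_candidate_regions",
    "probe_correlation",
    "score_region",
    "call_dmrs",
    "feature_enrichment",
]


def form_candidate_regions(
    manifest: pd.DataFrame,
    probe_ids: list[str] | pd.Index,
    max_gap_bp: int = 1000,
) -> list[dict]:
    """Cluster retained probes into candidate regions.

    Returns a list of candidates, each ``{"chrom", "start", "end",
    "probe_ids"}`` with probes ordered by position; singletons are dropped.
    """
    man = manifest.set_index("probe_id")
    missing = set(probe_ids) - set(man.index)
    if missing:
        raise ValidationError(f"probes absent from manifest: {sorted(missing)[:3]}")
    sub = man.loc[list(probe_ids)].reset_index()
    for chrom, grp in sub.groupby("chrom"):
        if not grp["pos"].is_monotonic_increasing:
            raise ValidationError(f"manifest not sorted by position on {chrom}")
    candidates = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        breaks = np.where(np.diff(pos) > max_gap_bp)[0]
        for run in np.split(np.arange(len(pos)), breaks + 1):
            if len(run) < 2:
                continue
            candidates.append(
                {
                    "chrom": chrom,
                    "start": int(pos[run[0]]),
                    "end": int(pos[run[-1]]),
                    "probe_ids": list(ids[run]),
                }
            )
    log.info("region clustering: %d candidate regions", len(candidates))
    return candidates


def probe_correlation(
    candidate: dict, betas: pd.DataFrame, method: str = "mean"
) -> float:
    """Correlation among the candidate's probes across all samples.

    ``method="mean"`` (default) averages all pairwise Pearson correlations;
    ``method="min"`` takes the minimum. A zero-variance probe contributes 0
    to its pairs.
    """
    vals = betas.loc[candidate["probe_ids"]].to_numpy(float)
    if vals.shape[0] < 2:
        raise ValidationError("probe correlation needs at least 2 probes")
    sd = vals.std(axis=1)
    if (sd == 0).any():
        log.warning("zero-variance probe in region %s:%d", candidate["chrom"], candidate["start"])
    rs = []
    for i, j in itertools.combinations(range(vals.shape[0]), 2):
        if sd[i] == 0 or sd[j] == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(vals[i], vals[j])[0, 1]))
    return float(np.min(rs) if method == "min" else np.mean(rs))


def _pair_beta_diff(betas: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe within-pair beta difference (depressed - nondepressed)."""
    pair_ids = list(dict.fromkeys(sample_sheet["pair_id"]))
    sheet = sample_sheet.set_index(["pair_id", "role"])["sample_id"]
    dep = [sheet[p, "depressed"] for p in pair_ids]
    ctrl = [sheet[p, "nondepressed"] for p in pair_ids]
    return pd.DataFrame(
        betas[dep].to_numpy(float) - betas[ctrl].to_numpy(float),
        index=betas.index,
        columns=pair_ids,
    )


def score_region(
    candidate: dict,
    results: pd.DataFrame,
    betas: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    corr_method: str = "mean",
) -> dict | None:
    """Attach summary statistics to a candidate region.

    Region p combines the probes' two-sided p-values as signed z-scores
    (sign of alpha) with equal weights (Stouffer), converted back to a
    two-sided p. Percent differences are means over pairs of the
    depressed-minus-nondepressed beta difference, x100.
    """
    res = results.set_index("feature_id")
    ids = candidate["probe_ids"]
    if not set(ids) <= set(res.index):
        log.warning("region %s:%d skipped: missing probe results", candidate["chrom"], candidate["start"])
        return None
    sub = res.loc[ids]
    if sub["p"].isna().any():
        log.warning("region %s:%d skipped: failed probe fits", candidate["chrom"], candidate["start"])
        return None
    p = sub["p"].to_numpy(float)
    alpha = sub["alpha"].to_numpy(float)
    z = np.sign(alpha) * stats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    z_comb = z.sum() / np.sqrt(len(z))
    region_p = float(2.0 * stats.norm.sf(abs(z_comb)))

    # peak probe: smallest p, ties by larger |alpha|, then position order
    order = np.lexsort((np.arange(len(ids)), -np.abs(alpha), p))
    peak_idx = int(order[0])
    diffs = _pair_beta_diff(betas.loc[ids], sample_sheet)
    per_probe_diff = diffs.mean(axis=1).to_numpy(float)

    mean_alpha = float(alpha.mean())
    region = dict(candidate)
    region.update(
        n_probes=len(ids),
        peak_probe_id=ids[peak_idx],
        peak_p=float(p.min()),
        mean_probe_corr=probe_correlation(candidate, betas, method=corr_method),
        region_p=region_p,
        mean_fc=float(2.0**mean_alpha),
        mean_diff_pct=float(100.0 * per_probe_diff.mean()),
        peak_diff_pct=float(100.0 * per_probe_diff[peak_idx]),
        direction="hyper" if mean_alpha >= 0 else "hypo",
        direction_tie=bool(mean_alpha == 0),
    )
    return region


def call_dmrs(
    scored: list[dict],
    min_probes: int = 5,
    peak_p_max: float = 0.01,
    min_corr: float = 0.30,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Filter scored candidates by the DMR criteria and apply the region FDR.

    The BH correction runs over the region p-values of *all* scored
    candidates (m = candidate count); the criteria (probe count, peak p,
    probe correlation) then select which regions may be reported, and
    significance requires q < ``q_max``. Output is sorted by region p.
    """
    if not scored:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "size", "gene", "n_probes", "peak_probe_id",
                     "peak_p", "region_p", "region_q", "mean_probe_corr", "mean_fc",
                     "mean_diff_pct", "peak_diff_pct", "direction", "significant"]
        )
    df = pd.DataFrame(scored)
    df["region_q"] = bh_fdr(df["region_p"].to_numpy())
    df["size"] = df["end"] - df["start"] + 1
    meets = (
        (df["n_probes"] >= min_probes)
        & (df["peak_p"] < peak_p_max)
        & (df["mean_probe_corr"] >= min_corr)
    )
    df["meets_criteria"] = meets
    df["significant"] = meets & (df["region_q"] < q_max)
    df = df.sort_values("region_p", kind="stable").reset_index(drop=True)
    log.info(
        "DMR calling: %d candidates, %d meet criteria, %d significant at q<%g",
        len(df), int(meets.sum()), int(df["significant"].sum()), q_max,
    )
    return df


def feature_enrichment(
    dmr_probe_ids: list[str],
    manifest: pd.DataFrame,
    background_probe_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Genomic-feature and CGI-context enrichment of DMR probes.

    For each feature class and CGI context, a 2x2 Fisher exact test of DMR
    probes against the background probe set, with fold enrichment =
    observed fraction / background fraction and BH q over categories.
    """
    if len(dmr_probe_ids) == 0:
        return pd.DataFrame(
            columns=["category_type", "category", "n_dmr", "n_background",
                     "fold_enrichment", "odds_ratio", "p", "q"]
        )
    man = manifest.set_index("probe_id")
    background = list(background_probe_ids) if background_probe_ids is not None else list(man.index)
    dmr = man.loc[list(dmr_probe_ids)]
    bg = man.loc[background]
    rows = []
    for col, ctype in (("feature_class", "feature_class"), ("cgi_context", "cgi_context")):
        for cat in sorted(bg[col].unique()):
            a = int((dmr[col] == cat).sum())  # DMR probes in category
            b = len(dmr) - a
            c = int((bg[col] == cat).sum()) - a  # background-only in category
            d = len(bg) - len(dmr) - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            bg_frac = (a + c) / len(bg)
            obs_frac = a / len(dmr)
            rows.append(
                {
                    "category_type": ctype,
                    "category": cat,
                    "n_dmr": a,
                    "n_background": a + c,
                    "fold_enrichment": obs_frac / bg_frac if bg_frac > 0 else np.nan,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
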