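"""Case-control replication scan for putative DMR probes and DEGs.

In an unpaired replication dataset each feature is tested with a logistic
regression of case status on the feature value plus covariates (maximum
likelihood, Wald p for the value coefficient). Region-level replication
uses each region's minimum probe p with Benjamini-Hochberg correction over
the number of tested regions; a region replicates when any of its probes
reaches q < 0.05 with a direction concordant with the discovery effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from cotwin.errors import ValidationError
from cotwin.io import log
from cotwin.pair_model import bh_fdr

__all__ = ["casecontrol_scan", "region_replication"]


def casecontrol_scan(
    values: pd.DataFrame,
    case_labels: np.ndarray,
    covariates: np.ndarray | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Logistic regression of case status on each feature.

    Returns one row per feature with the value coefficient, its Wald p,
    and a status column; non-converged or separated fits are flagged and
    excluded from downstream FDR.
    """
    y = np.asarray(case_labels, int)
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValidationError("need at least 10 cases and 10 controls")
    feats = list(features) if features is not None else list(values.index)
    missing = set(feats) - set(values.index)
    if missing:
        raise ValidationError(f"features absent from matrix: {sorted(missing)[:3]}")
    C = np.empty((values.shape[1], 0)) if covariates is None else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    rows = []
    for feat in feats:
        x = values.loc[feat].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append({"feature_id": feat, "coef": np.nan, "se": np.nan,
                         "p": np.nan, "status": "non-converged"})
            continue
        X = np.column_stack([np.ones_like(x), x, C])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", False) or not np.isfinite(fit.bse[1]):
                raise ValueError("no convergence")
            rows.append({"feature_id": feat, "coef": float(fit.params[1]),
                         "se": float(fit.bse[1]), "p": float(fit.pvalues[1]),
                         "status": "ok"})
        except Exception:
            log.warning("logistic fit failed for %s (separation?)", feat)
            rows.append({"feature_id": feat, "coef": np.nan, "se": np.nan,
                         "p": np.nan, "status": "non-converged"})
    return pd.DataFrame(rows)


def region_replication(
    scan: pd.DataFrame,
    probe_regions: pd.Series,
    discovery_direction: pd.Series,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Aggregate the probe scan to region-level replication calls.

    ``probe_regions`` maps probe id -> region id; ``discovery_direction``
    maps probe id -> sign of the discovery effect (+1 hyper, -1 hypo). A
    region's p is its minimum converged probe p; q is BH over the number
    of tested regions; replication requires a q < ``q_max`` probe whose
    coefficient sign matches discovery.
    """
    df = scan.merge(
        probe_regions.rename("region_id"), left_on="feature_id", right_index=True
    )
    df = df.merge(
        discovery_direction.rename("discovery_sign"), left_on="feature_id", right_index=True
    )
    ok = df[df["status"] == "ok"].copy()
    region_p = ok.groupby("region_id")["p"].min()
    region_q = pd.Series(
        bh_fdr(region_p.to_numpy(), m=len(region_p)), index=region_p.index
    )
    ok["region_q"] = ok["region_id"].map(region_q)
    ok["concordant"] = np.sign(ok["coef"]) == np.sign(ok["discovery_sign"])
    rows = []
    for region, grp in ok.groupby("region_id"):
        best = grp.loc[grp["p"].idxmin()]
        rows.append(
            {
                "region_id": region,
                "min_p": float(best["p"]),
                "q": float(grp["region_q"].iloc[0]),
                "replicates": bool(
                    (grp["region_q"] < q_max) .any()
                    and grp.loc[grp["region_q"] < q_max, "concordant"].any()
                ),
                "best_probe": best["feature_id"],
                "direction_concordant": bool(best["concordant"]),
            }
        )
    return pd.DataFrame(rows)
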