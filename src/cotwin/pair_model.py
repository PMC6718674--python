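"""Per-feature within-pair association model for discordant twin pairs.

For each feature (CpG probe or gene), the response is the within-pair log2
ratio (depressed over non-depressed co-twin) and the model is

    ratio_j = alpha + sum_i beta_i x_ij + b_{batch(j)} + e_j

with a random batch intercept b ~ N(0, sigma_b^2) and residual
e ~ N(0, sigma^2). The intercept alpha is the adjusted mean within-pair
log2 fold change; 2**alpha is the fold change, alpha > 0 hypermethylation
(or upregulation), alpha < 0 hypomethylation. Twin-varying covariates are
coded as raw within-pair differences (zero = co-twins equally exposed, so
a confounded effect is absorbed by its covariate); pair-shared covariates
(age, sex) enter mean-centered so the intercept keeps its
mean-fold-change interpretation.

The random-intercept fit is by restricted maximum likelihood, profiling the
variance ratio lambda = sigma_b^2 / sigma^2 with closed-form block inverses
(each batch block of V = I + lambda Z Z' inverts analytically). When the
batch-variance estimate is zero or there are fewer than 3 batches the fit
falls back to ordinary least squares. Coefficients are tested with Wald t
statistics; by default the degrees of freedom come from a Satterthwaite
approximation based on the REML information matrix of the variance
components (plugging the estimated variance ratio into a residual-df t test
is anti-conservative at realistic batch counts), with
``df_method="residual"`` (df = n_pairs - n_fixed) available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from cotwin.errors import ValidationError
from cotwin.io import log
from cotwin.preprocess import PairRatioMatrix
from cotwin.simulate import SHARED_COVARIATES, STANDARD_COVARIATES

__all__ = [
    "FeatureResult",
    "PairedTwinScan",
    "fit_pair_model",
    "run_feature_scan",
    "bh_fdr",
    "sensitivity_rerun",
]


@dataclass
class FeatureResult:
    """Fit summary for one feature."""

    feature_id: str
    alpha: float
    fc: float
    se: float
    p: float
    batch_var: float
    n_pairs: int
    status: str = "ok"  # "ok", "ols" (fallback), or a failure reason
    covariate_betas: dict = field(default_factory=dict)  # name -> (beta, p)
    q: float = float("nan")


def bh_fdr(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the total number of tests used for the correction; it defaults
    to ``len(p)`` and may be larger when only a subset of a known test
    family is supplied.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValidationError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop constant and linearly dependent columns (never the intercept)."""
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.ptp(X[:, j]) == 0:
            log.warning("dropping constant covariate %r", names[j])
            continue
        if np.linalg.matrix_rank(cand) < len(keep) + 1:
            log.warning("dropping collinear covariate %r", names[j])
            continue
        keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def _reml_random_intercept(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Profiled REML for y = X b + Zu + e with one random intercept factor.

    Returns (coef, cov_unscaled, sigma2, lambda) where the coefficient
    covariance is sigma2 * cov_unscaled and lambda = sigma_b^2 / sigma2.
    """
    n, p = X.shape
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group sums
    U = np.zeros((n_groups, p))
    np.add.at(U, codes, X)
    s = np.bincount(codes, weights=y, minlength=n_groups)

    def crit(lam: float) -> float:
        c = lam / (1.0 + lam * counts)
        A = XtX - (U.T * c) @ U
        b_vec = Xty - U.T @ (c * s)
        yVy = yty - float(c @ (s * s))
        try:
            coef = np.linalg.solve(A, b_vec)
        except np.linalg.LinAlgError:
            return np.inf
        rss = yVy - float(coef @ b_vec)
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - p)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(sigma2)
            + float(np.sum(np.log1p(lam * counts)))
            + logdet_A
        )

    res = optimize.minimize_scalar(crit, bounds=(0.0, 200.0), method="bounded")
    lam = float(res.x) if res.fun < crit(0.0) else 0.0
    c = lam / (1.0 + lam * counts)
    A = XtX - (U.T * c) @ U
    b_vec = Xty - U.T @ (c * s)
    coef = np.linalg.solve(A, b_vec)
    yVy = yty - float(c @ (s * s))
    rss = yVy - float(coef @ b_vec)
    sigma2 = max(rss, 1e-300) / (n - p)
    cov_unscaled = np.linalg.inv(A)
    return coef, cov_unscaled, sigma2, lam


def _satterthwaite_df(
    X: np.ndarray,
    codes: np.ndarray,
    sigma2: float,
    lam: float,
    fallback_df: float,
) -> np.ndarray:
    """Per-coefficient Satterthwaite degrees of freedom.

    df_j = 2 (Var beta_j)^2 / Var(Var-hat beta_j), with the variance of the
    variance estimate obtained from the expected REML information matrix of
    (sigma^2, sigma_b^2).
    """
    n, p = X.shape
    if lam <= 0:
        return np.full(p, fallback_df)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    V = sigma2 * (np.eye(n) + lam * (Z @ Z.T))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    C = np.linalg.inv(XtViX)
    P = Vi - Vi @ X @ C @ X.T @ Vi
    ZZt = Z @ Z.T
    PZ = P @ ZZt
    info = 0.5 * np.array(
        [
            [np.trace(P @ P), np.trace(P @ PZ)],
            [np.trace(PZ.T @ P), np.trace(PZ @ PZ)],
        ]
    )
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.full(p, fallback_df)
    # gradient of Var(beta_j) = C_jj wrt (sigma^2, sigma_b^2)
    M1 = C @ X.T @ Vi @ Vi @ X @ C  # dV/dsigma2 = I
    M2 = C @ X.T @ Vi @ ZZt @ Vi @ X @ C  # dV/dsigma_b2 = ZZ'
    df = np.empty(p)
    for j in range(p):
        g = np.array([M1[j, j], M2[j, j]])
        denom = float(g @ info_inv @ g)
        df[j] = 2.0 * C[j, j] ** 2 / denom if denom > 0 else fallback_df
    return np.clip(df, 1.0, fallback_df)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    n, p = X.shape
    coef, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    cov_unscaled = np.linalg.inv(X.T @ X)
    return coef, cov_unscaled, sigma2


class PairedTwinScan(BaseEstimator):
    """Mass-univariate within-pair regression with a random batch intercept.

    Parameters
    ----------
    covariates : sequence of str
        Covariate columns of the pair table to adjust for as fixed effects.
    use_batch : bool
        Include the batch random intercept (REML) when at least
        ``min_batches`` batches are present; otherwise OLS.
    min_batches : int
        Minimum batch count for the mixed fit.
    fdr_m : int or None
        Total test count for the BH correction (defaults to the number of
        features scanned).
    df_method : str
        ``"satterthwaite"`` (default) or ``"residual"``
        (df = n_pairs - n_fixed).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per feature: alpha, fc, se, p, q, batch_var, per-covariate
        beta/p, status.
    feature_names_ : list of str
    n_pairs_ : int
    """

    def __init__(
        self,
        covariates: tuple = STANDARD_COVARIATES,
        use_batch: bool = True,
        min_batches: int = 3,
        fdr_m: int | None = None,
        df_method: str = "satterthwaite",
    ):
        self.covariates = covariates
        self.use_batch = use_batch
        self.min_batches = min_batches
        self.fdr_m = fdr_m
        self.df_method = df_method

    def fit(self, ratio_matrix: PairRatioMatrix, y=None) -> "PairedTwinScan":
        """Fit the model to every feature of a :class:`PairRatioMatrix`."""
        R = ratio_matrix.ratios
        n_pairs = R.shape[1]
        if n_pairs < 3:
            raise ValidationError("at least 3 pairs are required")
        missing = [c for c in self.covariates if c not in ratio_matrix.covariates.columns]
        if missing:
            raise ValidationError(f"covariates absent from pair table: {missing}")

        names = ["intercept"] + list(self.covariates)
        X = np.column_stack(
            [np.ones(n_pairs)]
            + [ratio_matrix.covariates[c].to_numpy(float) for c in self.covariates]
        )
        # pair-shared covariates centered (their raw zero is meaningless);
        # twin-difference covariates raw, so zero = equally exposed co-twins
        for j, name in enumerate(names):
            if name in SHARED_COVARIATES:
                X[:, j] -= X[:, j].mean()
        X, names = _drop_collinear(X, names)

        codes = pd.Categorical(ratio_matrix.batch).codes.astype(int)
        n_batches = int(codes.max()) + 1 if len(codes) else 0
        mixed = self.use_batch and n_batches >= self.min_batches
        if not mixed and self.use_batch:
            log.info("fewer than %d batches: OLS fallback", self.min_batches)

        df = n_pairs - X.shape[1]
        if df < 1:
            raise ValidationError("not enough pairs for the fixed-effect count")

        rows = []
        values = R.to_numpy(float)
        for i, feature in enumerate(R.index):
            if i and i % 1000 == 0:
                log.info("scanned %d/%d features", i, len(R.index))
            yvec = values[i]
            row = {"feature_id": feature, "n_pairs": n_pairs}
            if not np.isfinite(yvec).all():
                row.update(
                    alpha=np.nan, fc=np.nan, se=np.nan, p=np.nan, batch_var=np.nan,
                    status="non-finite response",
                )
                rows.append(row)
                continue
            dfs = np.full(X.shape[1], float(df))
            try:
                if mixed:
                    coef, covu, sigma2, lam = _reml_random_intercept(
                        yvec, X, codes, n_batches
                    )
                    status = "ok" if lam > 0 else "ols"
                    batch_var = lam * sigma2
                    if self.df_method == "satterthwaite" and lam > 0:
                        dfs = _satterthwaite_df(X, codes, sigma2, lam, float(df))
                else:
                    coef, covu, sigma2 = _ols(yvec, X)
                    status, batch_var = "ols", 0.0
            except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
                row.update(
                    alpha=np.nan, fc=np.nan, se=np.nan, p=np.nan, batch_var=np.nan,
                    status=f"fit failed: {exc}",
                )
                rows.append(row)
                continue
            se = np.sqrt(sigma2 * np.diag(covu))
            with np.errstate(divide="ignore", invalid="ignore"):
                tvals = coef / se
            pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
            row.update(
                alpha=coef[0],
                fc=2.0 ** coef[0],
                se=se[0],
                p=float(pvals[0]),
                batch_var=batch_var,
                status=status,
            )
            for j, name in enumerate(names[1:], start=1):
                row[f"beta_{name}"] = coef[j]
                row[f"p_{name}"] = float(pvals[j])
            rows.append(row)

        results = pd.DataFrame(rows)
        if len(results):
            ok = results["p"].notna()
            q = np.full(len(results), np.nan)
            if ok.any():
                q[ok.to_numpy()] = bh_fdr(
                    results.loc[ok, "p"].to_numpy(),
                    m=self.fdr_m if self.fdr_m is not None else int(ok.sum()),
                )
            results["q"] = q
        else:
            results = pd.DataFrame(
                columns=["feature_id", "alpha", "fc", "se", "p", "q", "batch_var",
                         "n_pairs", "status"]
            )
        self.results_ = results
        self.feature_names_ = list(R.index)
        self.n_pairs_ = n_pairs
        self.fixed_effect_names_ = names
        return self


def fit_pair_model(
    ratios: np.ndarray,
    covariates: pd.DataFrame,
    batch: pd.Series,
    feature_id: str = "feature",
    covariate_names: tuple | None = None,
) -> FeatureResult:
    """Fit the within-pair model for a single feature."""
    pairs = covariates.index
    rm = PairRatioMatrix(
        ratios=pd.DataFrame([np.asarray(ratios, float)], index=[feature_id], columns=pairs),
        covariates=covariates,
        batch=batch,
    )
    use = tuple(covariate_names if covariate_names is not None else covariates.columns)
    scan = PairedTwinScan(covariates=use).fit(rm)
    r = scan.results_.iloc[0]
    cov_betas = {
        name: (r[f"beta_{name}"], r[f"p_{name}"])
        for name in scan.fixed_effect_names_[1:]
    }
    return FeatureResult(
        feature_id=feature_id,
        alpha=float(r["alpha"]),
        fc=float(r["fc"]),
        se=float(r["se"]),
        p=float(r["p"]),
        q=float(r["q"]),
        batch_var=float(r["batch_var"]),
        n_pairs=int(r["n_pairs"]),
        status=str(r["status"]),
        covariate_betas=cov_betas,
    )


def run_feature_scan(
    ratio_matrix: PairRatioMatrix,
    covariates: tuple = STANDARD_COVARIATES,
    fdr_m: int | None = None,
) -> pd.DataFrame:
    """Scan every feature; returns the results table (one row per feature)."""
    return PairedTwinScan(covariates=covariates, fdr_m=fdr_m).fit(ratio_matrix).results_


def sensitivity_rerun(
    ratio_matrix: PairRatioMatrix,
    base_results: pd.DataFrame,
    extra_covariates: tuple,
    covariates: tuple = STANDARD_COVARIATES,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Re-run the scan with additional covariates and report changes.

    Returns one row per feature with p/q before and after and whether the
    q < ``q_max`` significance call flipped.
    """
    augmented = tuple(covariates) + tuple(
        c for c in extra_covariates if c not in covariates
    )
    after = run_feature_scan(ratio_matrix, covariates=augmented)
    merged = base_results[["feature_id", "p", "q"]].merge(
        after[["feature_id", "p", "q"]], on="feature_id", suffixes=("_before", "_after")
    )
    merged["significant_before"] = merged["q_before"] < q_max
    merged["significant_after"] = merged["q_after"] < q_max
    merged["flipped"] = merged["significant_before"] != merged["significant_after"]
    return merged
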