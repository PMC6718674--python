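"""Probe/gene QC filters, zygosity confirmation, and within-pair log ratios.

The filters follow standard EPIC-array practice: drop probes failing
detection in more than 20% of samples, probes with aberrant raw signal
intensity (|z| strictly greater than 3 SD), sex-chromosome probes, and
probes that are multi-mapped or overlap known SNPs. Genes are kept when
log2(TPM+1) reaches 1 in at least 95% of samples.

The association model consumes within-pair log2 ratios: for each feature
and pair, log2 of the depressed member's value over the non-depressed
co-twin's value. Methylation ratios use an epsilon floor (beta = 0 is
representable); expression ratios use a +1 offset on TPM, matching the
log2(TPM+1) filtering scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cotwin.errors import ConfigError, ConsistencyError, ValidationError
from cotwin.io import log
from cotwin.simulate import SHARED_COVARIATES, TWIN_COVARIATES

PROBE_FILTER_RULES = (
    "detection_fail",
    "intensity_outlier",
    "sex_chrom",
    "multi_mapped",
    "snp_overlap",
)


@dataclass
class PairRatioMatrix:
    """Within-pair log2 ratios (features x pairs) with covariate differences.

    ``covariates`` holds one row per pair: the depressed-minus-nondepressed
    difference for twin-varying covariates and the shared pair value for
    pair-level covariates (age, sex).
    """

    ratios: pd.DataFrame  # features x pairs
    covariates: pd.DataFrame  # pairs x covariates
    batch: pd.Series  # batch id per pair


def filter_probes(
    manifest: pd.DataFrame,
    betas: pd.DataFrame,
    detect_fail_max: float = 0.20,
    intensity_z_max: float = 3.0,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the probe QC rules; return retained probe ids and a report.

    Exclusion uses strict inequalities: detection failure in *more than*
    ``detect_fail_max`` of samples, intensity *strictly beyond* ±3 SD.
    Rules are applied in a fixed order and each probe is counted under the
    first rule it fails.
    """
    unknown = set(betas.index) - set(manifest["probe_id"])
    if unknown:
        raise ConsistencyError(
            f"{len(unknown)} matrix probes absent from manifest, e.g. {sorted(unknown)[:3]}"
        )
    man = manifest.set_index("probe_id").loc[betas.index]
    fails = {
        "detection_fail": man["detection_fail_fraction"] > detect_fail_max,
        "intensity_outlier": man["intensity_z"].abs() > intensity_z_max,
        "sex_chrom": man["sex_chrom"].astype(bool),
        "multi_mapped": man["multi_mapped"].astype(bool),
        "snp_overlap": man["snp_overlap"].astype(bool),
    }
    excluded = pd.Series(False, index=betas.index)
    rows = []
    for rule in PROBE_FILTER_RULES:
        hit = fails[rule] & ~excluded
        rows.append(
            {
                "rule": rule,
                "n_excluded": int(hit.sum()),
                "example_ids": ",".join(list(betas.index[hit])[:3]),
            }
        )
        excluded |= fails[rule]
    retained = list(betas.index[~excluded])
    report = pd.DataFrame(rows)
    log.info(
        "probe QC: %d/%d probes retained (%s)",
        len(retained),
        len(betas),
        "; ".join(f"{r['rule']}={r['n_excluded']}" for r in rows),
    )
    return retained, report


def filter_genes(
    tpm: pd.DataFrame, floor: float = 1.0, max_low_fraction: float = 0.05
) -> list[str]:
    """Retain genes whose log2(TPM+1) falls below ``floor`` in at most
    ``max_low_fraction`` of samples."""
    low = np.log2(tpm.to_numpy(float) + 1.0) < floor
    keep = low.mean(axis=1) <= max_low_fraction
    retained = list(tpm.index[keep])
    log.info("gene filter: %d/%d genes retained", len(retained), len(tpm))
    return retained


def zygosity_check(
    betas: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    snp_probe_ids: list[str],
    min_concordance: float = 0.9,
    min_probes: int = 10,
) -> pd.DataFrame:
    """Per-pair monozygosity verdict from SNP-probe beta concordance.

    Genotype-tracking probes are tri-modal in beta; MZ co-twins share
    genotype, so their SNP-probe betas correlate near 1.
    """
    present = [p for p in snp_probe_ids if p in betas.index]
    pairs = sorted(sample_sheet["pair_id"].unique())
    if len(present) < min_probes:
        log.warning("zygosity: only %d SNP probes available", len(present))
        return pd.DataFrame(
            {"pair_id": pairs, "snp_corr": np.nan, "verdict": "insufficient"}
        )
    sheet = sample_sheet.set_index(["pair_id", "role"])["sample_id"]
    rows = []
    for pair in pairs:
        a = betas.loc[present, sheet[pair, "depressed"]].to_numpy(float)
        b = betas.loc[present, sheet[pair, "nondepressed"]].to_numpy(float)
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append(
            {
                "pair_id": pair,
                "snp_corr": r,
                "verdict": "MZ" if r >= min_concordance else "not_MZ",
            }
        )
    return pd.DataFrame(rows)


def within_pair_logratio(
    values: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    offset: float,
) -> PairRatioMatrix:
    """Compute log2((depressed + offset) / (nondepressed + offset)) per pair.

    ``offset`` must be positive for data where zeros occur (beta or TPM).
    The companion covariate table carries within-pair differences for
    twin-varying covariates and pair values for shared ones.
    """
    if offset < 0:
        raise ConfigError("offset must be non-negative")
    pair_ids = list(dict.fromkeys(sample_sheet["pair_id"]))
    sheet = sample_sheet.set_index(["pair_id", "role"])
    dep_ids, ctrl_ids = [], []
    for pair in pair_ids:
        try:
            dep_ids.append(sheet.loc[(pair, "depressed"), "sample_id"])
            ctrl_ids.append(sheet.loc[(pair, "nondepressed"), "sample_id"])
        except KeyError:
            raise ValidationError(f"pair {pair!r} is incomplete") from None
    missing = set(dep_ids + ctrl_ids) - set(values.columns)
    if missing:
        raise ConsistencyError(f"samples missing from matrix: {sorted(missing)[:5]}")

    dep = values[dep_ids].to_numpy(float) + offset
    ctrl = values[ctrl_ids].to_numpy(float) + offset
    if (dep <= 0).any() or (ctrl <= 0).any():
        raise ValidationError("zero or negative values; use a positive offset")
    ratios = pd.DataFrame(
        np.log2(dep) - np.log2(ctrl), index=values.index, columns=pair_ids
    )

    dep_rows = sample_sheet[sample_sheet["role"] == "depressed"].set_index("pair_id").loc[pair_ids]
    ctrl_rows = (
        sample_sheet[sample_sheet["role"] == "nondepressed"].set_index("pair_id").loc[pair_ids]
    )
    cov = {}
    for name in SHARED_COVARIATES:
        cov[name] = dep_rows[name].to_numpy(float)
    for name in TWIN_COVARIATES:
        cov[name] = dep_rows[name].to_numpy(float) - ctrl_rows[name].to_numpy(float)
    covariates = pd.DataFrame(cov, index=pd.Index(pair_ids, name="pair_id"))
    batch = pd.Series(dep_rows["batch_id"].to_numpy(), index=covariates.index, name="batch_id")
    return PairRatioMatrix(ratios=ratios, covariates=covariates, batch=batch)
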