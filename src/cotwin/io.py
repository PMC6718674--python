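"""Readers and writers for every on-disk artifact, plus run configuration.

All tabular artifacts are TSV with a fixed column order; floats are
serialized with 6 significant digits. Manifest and region tables use
1-based inclusive coordinates; BED export follows the BED convention
(0-based half-open).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cotwin.errors import ConfigError, InvalidRegionError, ValidationError

log = logging.getLogger("cotwin")

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "gene_symbol",
    "feature_class",
    "cgi_context",
    "sex_chrom",
    "multi_mapped",
    "snp_overlap",
    "detection_fail_fraction",
    "intensity_z",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "pair_id",
    "role",
    "batch_id",
    "age",
    "sex",
    "bmi",
    "smoking",
    "alcohol",
    "income",
    "education",
    "ace",
    "ptsd",
    "antidepressant",
]

FLOAT_FORMAT = "%.6g"


def setup_logging(level: str = "INFO") -> None:
    """Timestamped per-stage logging to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s [%(name)s] %(message)s")
    )
    log.handlers[:] = [handler]
    log.setLevel(level.upper())


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a feature x sample value matrix from TSV.

    Parameters
    ----------
    path : path to a TSV with a header row of sample ids, first column the
        feature id.
    kind : ``"beta"`` (values validated in [0, 1]) or ``"tpm"``
        (values validated >= 0).
    """
    if kind not in ("beta", "tpm"):
        raise ConfigError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file, not a matrix") from None
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric entries (ragged or malformed rows?)")
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    bad = (values < 0) | (values > 1) if kind == "beta" else (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: out-of-range {kind} value {values[i, j]!r} at "
            f"feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a probe manifest (sorted by chrom, pos; unique ids)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate probe ids")
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: positions must be >= 1 (1-based)")
    grouped = df.groupby("chrom", sort=False)["pos"]
    if not grouped.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValidationError(f"{path}: manifest not sorted by (chrom, pos)")
    return df[MANIFEST_COLUMNS]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet; every pair must have exactly one depressed and
    one nondepressed member sharing age and sex."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: sample sheet missing columns {sorted(missing)}")
    for pair_id, grp in df.groupby("pair_id"):
        roles = sorted(grp["role"])
        if roles != ["depressed", "nondepressed"]:
            raise ValidationError(
                f"{path}: pair {pair_id!r} must have one depressed and one "
                f"nondepressed member, got {roles}"
            )
        for col in ("age", "sex", "batch_id"):
            if grp[col].nunique() != 1:
                raise ValidationError(f"{path}: pair {pair_id!r} differs in {col}")
    return df[SAMPLE_SHEET_COLUMNS]


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: gene annotation missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return df


def write_dmr_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write called regions as BED6.

    Input coordinates are 1-based inclusive; BED output is 0-based
    half-open (start-1, end). Score is ``-10*log10(region_q)`` capped at
    1000; name is the nearest gene; strand is ".".
    """
    if (regions["end"] < regions["start"]).any():
        bad = regions[regions["end"] < regions["start"]].iloc[0]
        raise InvalidRegionError(
            f"region {bad['chrom']}:{bad['start']}-{bad['end']} has end < start"
        )
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            q = max(float(r["region_q"]), 1e-300)
            score = min(1000, int(round(-10.0 * np.log10(q))))
            name = r.get("gene", ".") or "."
            fh.write(
                f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{name}\t{score}\t.\n"
            )


# ---------------------------------------------------------------------------
# run configuration

DEFAULT_CONFIG: dict = {
    "preprocess": {
        "detect_fail_max": 0.20,
        "intensity_z_max": 3.0,
        "gene_floor": 1.0,
        "gene_max_low_fraction": 0.05,
        "meth_offset": 1e-6,
        "expr_offset": 1.0,
    },
    "model": {
        "p_method": "t",  # t statistic with df = n_pairs - n_fixed
        "q_max": 0.05,
    },
    "regions": {
        "max_gap_bp": 1000,
        "min_probes": 5,
        "peak_p": 0.01,
        "min_corr": 0.30,
        "q_max": 0.05,
        "corr_method": "mean",  # or "min"
    },
    "integration": {
        "cis_window": 5000,
        "permutations": 100,
        "alpha": 0.05,
        "tail": "two-sided",  # or "one-sided" for the literal 5th percentile
        "offset_bin_bp": 500,
    },
    "networks": {
        "nominal_p": 0.001,
        "min_module_size": 50,
        "edge_cutoff": 0.1,
        "tree_cut_height": 0.99,
        "permutations": 200,
    },
    "replication": {"q_max": 0.05},
    "simulate": {},
    "paths": {},
    "seed": 0,
}


def _merge(defaults: dict, user: dict, trail: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        where = f"{trail}.{key}" if trail else key
        if key not in defaults:
            raise ConfigError(f"unknown config key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load the YAML run configuration, fill defaults, reject unknown keys."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        user = loaded
    if overrides:
        for key, value in overrides.items():
            if isinstance(value, dict):
                user[key] = {**user.get(key, {}), **value}
            else:
                user[key] = value
    # "paths" and "simulate" are free-form sections, exempt from key checking
    free = {name: user.pop(name, {}) for name in ("paths", "simulate")}
    config = _merge(DEFAULT_CONFIG, user)
    config.update(free)
    for section, values in config.items():
        if isinstance(values, dict) and section not in ("paths", "simulate"):
            for key, value in values.items():
                log.info("config %s.%s = %r", section, key, value)
    return config
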