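"""Synthetic twin-cohort generator with planted ground truth.

Emulates the data structure of a discordant monozygotic twin study: paired
samples sharing pair-level covariates and array batch, probe-level
methylation beta values with spatially correlated CpG blocks and planted
within-pair fold changes, gene-level TPM expression with planted
differential expression, and signed cis methylation-expression couplings
whose transcription start site (TSS) offset is configurable.

Methylation is generated on the logit scale, which guarantees valid beta
values; the planted within-pair effect ``alpha`` (so that the fold change is
``2**alpha``) is transferred to the logit scale by local linearization of
``log2(sigmoid(x))`` at the pair baseline. Batch random intercepts and the
residual noise are planted directly on the log2-ratio scale, matching the
response of the downstream within-pair model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cotwin.errors import ConfigError

LN2 = np.log(2.0)

#: covariates shared by both members of a pair
SHARED_COVARIATES = ("age", "sex")
#: covariates that may differ between co-twins
TWIN_COVARIATES = (
    "bmi",
    "smoking",
    "alcohol",
    "income",
    "education",
    "ace",
    "ptsd",
    "antidepressant",
)
#: the default fixed-effect adjustment set of the association model
STANDARD_COVARIATES = ("age", "sex", "bmi", "smoking", "alcohol", "income", "education")
#: covariates reserved for sensitivity reruns
SENSITIVITY_COVARIATES = ("ace", "ptsd", "antidepressant")

FEATURE_CLASSES = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "Intergenic")
CGI_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")

# Rough EPIC-like category proportions; configurable via SimulationConfig.
DEFAULT_FEATURE_PROPS = (0.13, 0.08, 0.09, 0.04, 0.36, 0.03, 0.27)
DEFAULT_CGI_PROPS = (0.31, 0.25, 0.10, 0.34)


@dataclass(frozen=True)
class PlantedBlock:
    """A spatially adjacent CpG block with a planted within-pair fold change."""

    n_probes: int
    corr: float  # target within-block sample correlation of beta values
    fc: float  # planted fold change, 2**alpha
    gap_bp: int = 200  # distance between adjacent probes of the block

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ConfigError("planted block must contain at least one probe")
        if not 0.0 <= self.corr < 1.0:
            raise ConfigError("block correlation target must be in [0, 1)")
        if self.fc <= 0:
            raise ConfigError("planted fold change must be positive")


@dataclass(frozen=True)
class PlantedCoupling:
    """A probe-gene cis coupling with a target partial correlation."""

    probe: int  # probe index
    gene: int  # gene index
    r: float  # signed target partial correlation
    tss_offset: int  # strand-aware probe offset from the gene TSS (negative = upstream)

    def __post_init__(self) -> None:
        if not -1.0 < self.r < 1.0:
            raise ConfigError("coupling target correlation must be in (-1, 1)")


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical config + seed gives bit-identical output."""

    n_pairs: int = 79
    n_probes: int = 2000
    n_genes: int = 500
    n_batches: int = 20  # EPIC chips hold 8 arrays = 4 pairs; 79 pairs ~ 20 chips
    batch_sd: float = 0.1  # SD of batch random intercept, log2-ratio scale
    noise_sd: float = 0.2  # within-pair log2-ratio residual SD
    planted_dmrs: list[PlantedBlock] = field(default_factory=list)
    planted_degs: list[tuple[int, float]] = field(default_factory=list)  # (gene idx, FC)
    cis_couplings: list[PlantedCoupling] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)  # beta per covariate
    seed: int = 0
    # secondary knobs
    baseline_logit_sd: float = 1.8  # spread of per-probe mean methylation (logit scale)
    pair_logit_sd: float = 0.6  # between-pair variation of a probe (logit scale)
    expr_base_mean: float = 5.0  # mean log2(TPM+1) of gene baselines
    expr_base_sd: float = 1.5
    expr_pair_sd: float = 1.0  # pair-level expression random effect (log2 scale)
    expr_noise_sd: float = 0.5  # per-sample expression noise (log2 scale)
    cis_gene_window: int = 4500  # uncoupled gene TSS placed within this of a probe
    probe_gap_bp: int | None = None  # fixed background inter-probe gap (None: lognormal)
    feature_class_props: tuple[float, ...] = DEFAULT_FEATURE_PROPS
    cgi_props: tuple[float, ...] = DEFAULT_CGI_PROPS
    flagged_fraction: float = 0.0  # fraction of probes given each QC flag

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ConfigError("n_pairs must be at least 2")
        if self.n_probes < 1 or self.n_genes < 1 or self.n_batches < 1:
            raise ConfigError("n_probes, n_genes and n_batches must be positive")
        if sum(b.n_probes for b in self.planted_dmrs) > self.n_probes:
            raise ConfigError("planted blocks exceed n_probes")
        for gene, fc in self.planted_degs:
            if not 0 <= gene < self.n_genes:
                raise ConfigError(f"planted DEG references absent gene index {gene}")
            if fc <= 0:
                raise ConfigError("planted expression fold change must be positive")
        for c in self.cis_couplings:
            if not 0 <= c.probe < self.n_probes:
                raise ConfigError(f"coupling references absent probe index {c.probe}")
            if not 0 <= c.gene < self.n_genes:
                raise ConfigError(f"coupling references absent gene index {c.gene}")
        unknown = set(self.covariate_effects) - set(SHARED_COVARIATES) - set(TWIN_COVARIATES)
        if unknown:
            raise ConfigError(f"unknown covariates in covariate_effects: {sorted(unknown)}")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage substream of the global seed."""
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class PlantedTruth:
    """Ground-truth labels for every planted signal."""

    probe_alpha: np.ndarray  # per-probe true alpha (log2 FC)
    probe_block: np.ndarray  # block index per probe, -1 outside blocks
    gene_log2fc: np.ndarray  # per-gene true log2 expression FC
    couplings: list[PlantedCoupling] = field(default_factory=list)

    @property
    def coupling_signs(self) -> np.ndarray:
        return np.sign([c.r for c in self.couplings]).astype(int)

    @property
    def negative_coupling_fraction(self) -> float:
        signs = self.coupling_signs
        return float(np.mean(signs < 0)) if signs.size else float("nan")


@dataclass
class PairedCohort:
    """Twin pairs with depressed-member designation, covariates and batch."""

    samples: pd.DataFrame  # one row per sample (two per pair)

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    @property
    def pair_ids(self) -> list[str]:
        return list(dict.fromkeys(self.samples["pair_id"]))

    def members(self, role: str) -> pd.DataFrame:
        """Rows of one twin per pair, ordered by pair id."""
        sub = self.samples[self.samples["role"] == role]
        return sub.set_index("pair_id").loc[self.pair_ids].reset_index()


def generate_cohort(config: SimulationConfig) -> PairedCohort:
    """Draw the twin pairs, their covariates and batch assignment.

    Pair-level covariates (age, sex) are identical within a pair;
    twin-varying covariates are drawn independently per twin; twins of a
    pair always share a batch (pairs are hybridized on the same chip).
    """
    rng = config.rng(1)
    n = config.n_pairs
    age = np.round(rng.uniform(18, 70, size=n), 1)
    sex = rng.binomial(1, 0.684, size=n)
    # pairs fill chips in order; each chip holds ceil(n_pairs / n_batches) pairs
    per_batch = -(-n // config.n_batches)
    batch = np.arange(n) // per_batch

    rows = []
    for j in range(n):
        pair = f"pair{j:03d}"
        for role in ("depressed", "nondepressed"):
            rows.append(
                {
                    "sample_id": f"{pair}_{'d' if role == 'depressed' else 'n'}",
                    "pair_id": pair,
                    "role": role,
                    "batch_id": f"chip{batch[j]:02d}",
                    "age": age[j],
                    "sex": int(sex[j]),
                    "bmi": float(np.round(rng.normal(27.0, 6.0), 2)),
                    "smoking": float(np.round(np.abs(rng.normal(0.0, 8.0)), 2)),
                    "alcohol": float(np.round(np.clip(rng.normal(3.5, 2.7), 0, 12), 1)),
                    "income": int(rng.integers(1, 6)),
                    "education": int(rng.integers(1, 5)),
                    "ace": int(rng.binomial(1, 0.11)),
                    "ptsd": int(rng.binomial(1, 0.05)),
                    "antidepressant": int(rng.binomial(1, 0.5 if role == "depressed" else 0.15)),
                }
            )
    return PairedCohort(samples=pd.DataFrame(rows))


def _covariate_ratio_effect(config: SimulationConfig, cohort: PairedCohort) -> np.ndarray:
    """Per-pair contribution of configured covariate effects to the log2 ratio."""
    out = np.zeros(config.n_pairs)
    if not config.covariate_effects:
        return out
    dep = cohort.members("depressed")
    ctrl = cohort.members("nondepressed")
    for name, beta in config.covariate_effects.items():
        if name in SHARED_COVARIATES:
            x = dep[name].to_numpy(float)
        else:
            x = dep[name].to_numpy(float) - ctrl[name].to_numpy(float)
        out += beta * x
    return out


def _build_manifest(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Lay probes on chr1: planted blocks first (adjacent, configured gaps),
    then background probes with lognormal gaps."""
    n = config.n_probes
    block_id = np.full(n, -1)
    if config.probe_gap_bp is not None:
        gaps = np.full(n, int(config.probe_gap_bp))
    else:
        gaps = np.asarray(
            np.round(rng.lognormal(mean=6.4, sigma=1.0, size=n)), dtype=int
        )  # median ~600 bp
    gaps = np.clip(gaps, 10, None)
    i = 0
    for b, blk in enumerate(config.planted_dmrs):
        for k in range(blk.n_probes):
            block_id[i] = b
            if k > 0:
                gaps[i] = blk.gap_bp
            elif i > 0:
                gaps[i] = 50_000  # keep blocks well separated from neighbours
            i += 1
    if 0 < i < n:
        gaps[i] = 50_000
    pos = 1 + np.cumsum(gaps)

    fclass = rng.choice(FEATURE_CLASSES, size=n, p=np.asarray(config.feature_class_props))
    cgi = rng.choice(CGI_CONTEXTS, size=n, p=np.asarray(config.cgi_props))
    flagged = config.flagged_fraction
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i:07d}" for i in range(n)],
            "chrom": "chr1",
            "pos": pos,
            "gene_symbol": ".",
            "feature_class": fclass,
            "cgi_context": cgi,
            "sex_chrom": rng.random(n) < flagged,
            "multi_mapped": rng.random(n) < flagged,
            "snp_overlap": rng.random(n) < flagged,
            "detection_fail_fraction": np.where(rng.random(n) < flagged, 0.5, 0.0),
            "intensity_z": np.zeros(n),
        }
    )
    return manifest, block_id


def generate_methylation(
    config: SimulationConfig, cohort: PairedCohort
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate the beta matrix (probes x samples), manifest and truth labels.

    Per probe and pair, a pair baseline on the logit scale carries the
    between-pair variation and, within planted blocks, a shared per-pair
    block factor that induces the target probe-probe sample correlation.
    The within-pair log2-ratio signal (planted alpha, covariate effects,
    batch intercept, residual noise) is converted to a logit half-difference
    by linearization and applied with opposite sign to the two twins.
    """
    if cohort.n_pairs != config.n_pairs:
        raise ConfigError("cohort does not match config (n_pairs differs)")
    rng = config.rng(2)
    n_probes, n_pairs = config.n_probes, config.n_pairs
    manifest, block_id = _build_manifest(config, rng)

    alpha = np.zeros(n_probes)
    for b, blk in enumerate(config.planted_dmrs):
        alpha[block_id == b] = np.log2(blk.fc)

    # Baselines kept below ~0.8 methylation so a planted twin ratio of
    # beta values is realizable without saturating at 1.
    mu = rng.normal(-0.5, config.baseline_logit_sd, size=n_probes)
    mu = np.clip(mu, -3.0, 1.4)
    # probes of a block share a baseline (CpG islands are coherently methylated)
    for b in range(len(config.planted_dmrs)):
        mask = block_id == b
        if mask.any():
            mu[mask] = np.clip(mu[mask][0], -2.5, 1.0)

    dep = cohort.members("depressed")
    batch_codes = pd.Categorical(dep["batch_id"]).codes
    n_batches = batch_codes.max() + 1

    # log2-ratio-scale components, one column per pair
    batch_eff = rng.normal(0.0, config.batch_sd, size=(n_probes, n_batches))
    cov_eff = _covariate_ratio_effect(config, cohort)  # (n_pairs,)
    noise = rng.normal(0.0, config.noise_sd, size=(n_probes, n_pairs))
    d_ratio = alpha[:, None] + cov_eff[None, :] + batch_eff[:, batch_codes] + noise

    # pair baseline: logit-normal around mu, block factor shared within pair
    sg = config.pair_logit_sd
    pair_dev = rng.normal(0.0, 1.0, size=(n_probes, n_pairs))
    g = sg * pair_dev
    beta0 = _sigmoid(mu)
    var_d = config.noise_sd**2 + config.batch_sd**2 + alpha**2
    for b, blk in enumerate(config.planted_dmrs):
        mask = block_id == b
        if not mask.any():
            continue
        shared = rng.normal(0.0, 1.0, size=n_pairs)
        # delta-method correction: the +/- d/2 term dilutes the beta-scale
        # correlation relative to the shared-factor fraction
        b0 = float(beta0[mask][0])
        dil = (LN2 / 2.0) ** 2 * float(np.mean(var_d[mask])) / ((1.0 - b0) ** 2 * sg**2)
        w = min(0.98, blk.corr * (1.0 + dil))
        g[mask, :] = sg * (
            np.sqrt(w) * shared[None, :] + np.sqrt(1.0 - w) * pair_dev[mask, :]
        )

    # exact multiplicative planting: log2 beta = log2(baseline) +/- d/2
    y0 = np.log2(_sigmoid(mu[:, None] + g))
    beta_dep = np.clip(2.0 ** (y0 + d_ratio / 2.0), 1e-6, 1 - 1e-6)
    beta_ctrl = np.clip(2.0 ** (y0 - d_ratio / 2.0), 1e-6, 1 - 1e-6)

    cols, data = [], []
    ctrl = cohort.members("nondepressed")
    for j in range(n_pairs):
        cols.extend([dep["sample_id"].iloc[j], ctrl["sample_id"].iloc[j]])
        data.extend([beta_dep[:, j], beta_ctrl[:, j]])
    betas = pd.DataFrame(np.column_stack(data), index=manifest["probe_id"], columns=cols)
    betas = betas[list(cohort.samples["sample_id"])]

    truth = PlantedTruth(
        probe_alpha=alpha,
        probe_block=block_id,
        gene_log2fc=np.zeros(config.n_genes),
    )
    return betas, manifest, truth


def generate_expression(
    config: SimulationConfig,
    cohort: PairedCohort,
    truth: PlantedTruth,
    betas: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate the TPM matrix, gene annotation and updated truth.

    Expression is drawn on the log2(TPM+1) scale: gene baseline + pair
    random effect + per-sample noise; planted fold changes are added to the
    depressed twin. A configured cis coupling replaces part of the gene's
    variance with the standardized beta values of the coupled probe so that
    the correlation matches the target, and places the gene's TSS at the
    configured offset from the probe.
    """
    if config.cis_couplings and (betas is None or manifest is None):
        raise ConfigError("cis couplings configured but no methylation data supplied")
    rng = config.rng(3)
    n_genes, n_pairs = config.n_genes, config.n_pairs
    n_samples = 2 * n_pairs
    sample_ids = list(cohort.samples["sample_id"])
    is_dep = (cohort.samples["role"] == "depressed").to_numpy()
    pair_codes = pd.Categorical(
        cohort.samples["pair_id"], categories=cohort.pair_ids
    ).codes

    base = rng.normal(config.expr_base_mean, config.expr_base_sd, size=n_genes)
    pair_eff = rng.normal(0.0, config.expr_pair_sd, size=(n_genes, n_pairs))
    noise = rng.normal(0.0, config.expr_noise_sd, size=(n_genes, n_samples))
    log2fc = np.zeros(n_genes)
    for gene, fc in config.planted_degs:
        log2fc[gene] = np.log2(fc)

    L = base[:, None] + pair_eff[:, pair_codes] + noise
    L += np.where(is_dep[None, :], log2fc[:, None], 0.0)

    sigma_l = np.sqrt(config.expr_pair_sd**2 + config.expr_noise_sd**2)
    for c in config.cis_couplings:
        b = betas.iloc[c.probe].to_numpy(float)[
            [betas.columns.get_loc(s) for s in sample_ids]
        ]
        z = (b - b.mean()) / b.std()
        L[c.gene] = (
            base[c.gene]
            + np.where(is_dep, log2fc[c.gene], 0.0)
            + c.r * sigma_l * z
            + np.sqrt(1 - c.r**2) * sigma_l * rng.normal(size=n_samples)
        )

    tpm = np.clip(2.0**L - 1.0, 0.0, None)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    tpm_df = pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    anno = _place_genes(config, manifest, rng)
    truth.gene_log2fc = log2fc
    truth.couplings = list(config.cis_couplings)
    return tpm_df, anno, truth


def _place_genes(
    config: SimulationConfig, manifest: pd.DataFrame | None, rng: np.random.Generator
) -> pd.DataFrame:
    """Place each gene TSS near a random probe; couplings pin the offset."""
    n_genes = config.n_genes
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    if manifest is not None:
        anchor = rng.integers(0, len(manifest), size=n_genes)
        pos = manifest["pos"].to_numpy()[anchor]
        chrom = manifest["chrom"].to_numpy()[anchor]
    else:
        pos = rng.integers(1_000_000, 50_000_000, size=n_genes)
        chrom = np.full(n_genes, "chr1")
    offset = rng.integers(-config.cis_gene_window, config.cis_gene_window + 1, size=n_genes)
    tss = np.where(strand == "+", pos - offset, pos + offset)
    if manifest is not None:
        for c in config.cis_couplings:
            p = int(manifest["pos"].iloc[c.probe])
            chrom[c.gene] = manifest["chrom"].iloc[c.probe]
            if strand[c.gene] == "+":
                tss[c.gene] = p - c.tss_offset
            else:
                tss[c.gene] = p + c.tss_offset
    tss = np.clip(tss, 1, None)
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": strand,
        }
    )


def annotate_manifest_genes(
    manifest: pd.DataFrame, gene_anno: pd.DataFrame, max_distance: int = 100_000
) -> pd.DataFrame:
    """Assign each probe the nearest gene's id (by TSS distance, same chromosome)."""
    out = manifest.copy()
    for chrom, sub in gene_anno.groupby("chrom"):
        mask = out["chrom"] == chrom
        if not mask.any():
            continue
        tss = sub["tss"].to_numpy()
        order = np.argsort(tss)
        tss_sorted = tss[order]
        names = sub["gene_id"].to_numpy()[order]
        pos = out.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(tss_sorted, pos)
        idx_lo = np.clip(idx - 1, 0, len(tss_sorted) - 1)
        idx_hi = np.clip(idx, 0, len(tss_sorted) - 1)
        d_lo = np.abs(pos - tss_sorted[idx_lo])
        d_hi = np.abs(pos - tss_sorted[idx_hi])
        best = np.where(d_hi < d_lo, idx_hi, idx_lo)
        dist = np.minimum(d_lo, d_hi)
        assigned = np.where(dist <= max_distance, names[best], ".")
        out.loc[mask, "gene_symbol"] = assigned
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
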