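"""Cis mapping, partial correlation, permutation threshold, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cotwin.errors import ConfigError, ValidationError
from cotwin.integration import (
    classify_cis_pairs,
    map_cis_pairs,
    partial_corr,
    permutation_threshold,
    robustness_with_mdd,
)
from cotwin.simulate import (
    PlantedCoupling,
    SimulationConfig,
    generate_cohort,
    generate_expression,
    generate_methylation,
)


def probe_manifest(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
        }
    )


def analytic_critical_r(n, k, alpha=0.05):
    df = n - 2 - k
    t = stats.t.ppf(1 - alpha / 2, df)
    return t / np.sqrt(t**2 + df)


class TestCisMapping:
    def test_offset_sign_plus_strand(self):
        man = probe_manifest([10_000])
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [14_000], "strand": ["+"]})
        pairs = map_cis_pairs(man, genes, window=5000)
        assert len(pairs) == 1
        assert pairs["offset"].iloc[0] == -4000  # probe upstream of TSS

    def test_window_boundary(self):
        man = probe_manifest([10_000])
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [15_001], "strand": ["+"]})
        assert len(map_cis_pairs(man, genes, window=5000)) == 0
        genes["tss"] = 15_000
        assert len(map_cis_pairs(man, genes, window=5000)) == 1

    def test_minus_strand_flips_offset(self):
        man = probe_manifest([14_000])
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["-"]})
        pairs = map_cis_pairs(man, genes, window=5000)
        # probe 3' of the TSS in genome coordinates, upstream in gene direction
        assert pairs["offset"].iloc[0] == -4000


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert partial_corr(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_exact_linear_relation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        c = rng.normal(size=50)
        y = x + c
        assert partial_corr(x, y, c) == pytest.approx(1.0, abs=1e-9)

    def test_matches_pingouin(self):
        # independent implementation as oracle
        import pingouin as pg

        rng = np.random.default_rng(2)
        n = 80
        C = rng.normal(size=(n, 3))
        x = C @ [0.5, -0.2, 0.1] + rng.normal(size=n)
        y = 0.4 * x + C @ [0.3, 0.3, 0.0] + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "c0": C[:, 0], "c1": C[:, 1], "c2": C[:, 2]})
        expected = pg.partial_corr(df, x="x", y="y", covar=["c0", "c1", "c2"])["r"].iloc[0]
        assert partial_corr(x, y, C) == pytest.approx(expected, abs=1e-9)

    def test_known_partial_correlation_recovered(self):
        # Fisher-z interval around a generated rho = 0.5 at n = 200
        rng = np.random.default_rng(3)
        n, rho = 200, 0.5
        z = rng.normal(size=n)
        x = z + rng.normal(size=n) * np.sqrt(1 / rho**2 - 1)
        x = rho * z / 1.0  # rebuild cleanly below
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        r = partial_corr(x, y, rng.normal(size=(n, 2)))
        assert 0.38 <= r <= 0.60

    def test_zero_variance_is_nan(self):
        x = np.ones(30)
        y = np.arange(30.0)
        assert np.isnan(partial_corr(x, y))


class TestPermutationThreshold:
    @staticmethod
    def _iid_setup(n, n_probes=25, n_genes=25, seed=0):
        rng = np.random.default_rng(seed)
        meth = pd.DataFrame(
            rng.uniform(0.1, 0.9, size=(n_probes, n)),
            index=[f"cg{i}" for i in range(n_probes)],
        )
        expr = pd.DataFrame(
            rng.lognormal(2.0, 1.0, size=(n_genes, n)),
            index=[f"G{i}" for i in range(n_genes)],
        )
        pairs = pd.DataFrame(
            {
                "probe_id": [f"cg{i % n_probes}" for i in range(80)],
                "gene_id": [f"G{(i * 7) % n_genes}" for i in range(80)],
                "offset": 0,
            }
        ).drop_duplicates(["probe_id", "gene_id"])
        return meth, expr, pairs

    def test_small_n_matches_closed_form(self):
        meth, expr, pairs = self._iid_setup(n=8, n_probes=10, n_genes=10, seed=4)
        lo, up = permutation_threshold(meth, expr, None, pairs, B=400, seed=1)
        rstar = analytic_critical_r(8, 0)
        assert up == pytest.approx(rstar, abs=0.05)
        assert lo == pytest.approx(-rstar, abs=0.05)

    def test_covariate_adjusted_threshold(self):
        rng = np.random.default_rng(5)
        n, k = 100, 4
        meth, expr, pairs = self._iid_setup(n=n, seed=5)
        C = rng.normal(size=(n, k))
        lo, up = permutation_threshold(meth, expr, C, pairs, B=300, seed=2)
        rstar = analytic_critical_r(n, k)
        assert up == pytest.approx(rstar, abs=0.03)

    def test_b_too_small_rejected(self):
        meth, expr, pairs = self._iid_setup(n=20)
        with pytest.raises(ConfigError):
            permutation_threshold(meth, expr, None, pairs, B=5)

    def test_degenerate_alpha_one(self):
        meth, expr, pairs = self._iid_setup(n=30, seed=6)
        lo, up = permutation_threshold(meth, expr, None, pairs, B=50, alpha=1.0, seed=3)
        assert lo == pytest.approx(up, abs=0.05)  # both collapse to the median


class TestClassification:
    @staticmethod
    def _classified(negate=False, seed=10):
        rng = np.random.default_rng(seed)
        n = 120
        meth = pd.DataFrame(rng.uniform(0.1, 0.9, size=(20, n)),
                            index=[f"cg{i}" for i in range(20)])
        expr_vals = rng.lognormal(2, 1, size=(20, n))
        # couple gene j to probe j strongly, alternating sign
        L = np.log2(expr_vals + 1)
        for j in range(10):
            sign = -1 if j % 2 == 0 else 1
            # offset keeps log-expression positive so clipping at TPM=0 never bites
            L[j] = 6.0 + sign * 3.0 * meth.to_numpy()[j] + rng.normal(0, 0.3, n)
        expr = pd.DataFrame(np.clip(2.0**L - 1, 0, None), index=[f"G{i}" for i in range(20)])
        if negate:
            # affine negation on the log scale: log2(TPM'+1) = c - log2(TPM+1),
            # which flips every correlation sign exactly while keeping TPM' >= 0
            c = L.max() + 1.0
            expr = pd.DataFrame(2.0 ** (c - L) - 1, index=expr.index)
        pairs = pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(20)],
            "gene_id": [f"G{i}" for i in range(20)],
            "offset": np.linspace(-4500, 4500, 20).astype(int),
        })
        return meth, expr, pairs

    def test_classification_and_antisymmetry(self):
        meth, expr, pairs = self._classified()
        thresholds = (-0.5, 0.5)
        out, summary = classify_cis_pairs(meth, expr, None, pairs, thresholds)
        assert summary["n_significant"] >= 8
        neg = (out["significant"] & (out["sign"] == "negative")).sum()
        pos = (out["significant"] & (out["sign"] == "positive")).sum()
        meth2, expr2, _ = self._classified(negate=True)
        out2, _ = classify_cis_pairs(meth2, expr2, None, pairs, thresholds)
        neg2 = (out2["significant"] & (out2["sign"] == "negative")).sum()
        pos2 = (out2["significant"] & (out2["sign"] == "positive")).sum()
        assert (neg, pos) == (pos2, neg2)

    def test_null_significance_close_to_alpha(self):
        rng = np.random.default_rng(11)
        n = 158
        meth = pd.DataFrame(rng.uniform(0.1, 0.9, size=(40, n)),
                            index=[f"cg{i}" for i in range(40)])
        expr = pd.DataFrame(rng.lognormal(2, 1, size=(40, n)),
                            index=[f"G{i}" for i in range(40)])
        pairs = pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(40) for _ in range(10)],
            "gene_id": [f"G{(i + j) % 40}" for i in range(40) for j in range(10)],
            "offset": 0,
        })
        lo, up = permutation_threshold(meth, expr, None, pairs, B=100, seed=7)
        out, summary = classify_cis_pairs(meth, expr, None, pairs, (lo, up))
        frac = summary["n_significant"] / summary["n_pairs"]
        assert 0.02 <= frac <= 0.09

    def test_planted_negative_fraction_recovered(self):
        couplings = [
            PlantedCoupling(i, i, -0.9 if i < 37 else 0.9, tss_offset=-1000 if i < 37 else 1000)
            for i in range(50)
        ]
        cfg = SimulationConfig(
            n_pairs=200, n_probes=60, n_genes=60, seed=12, cis_couplings=couplings,
        )
        cohort = generate_cohort(cfg)
        betas, man, truth = generate_methylation(cfg, cohort)
        tpm, anno, truth = generate_expression(cfg, cohort, truth, betas, man)
        pairs = pd.DataFrame({
            "probe_id": [man["probe_id"].iloc[c.probe] for c in couplings],
            "gene_id": [f"G{c.gene:04d}" for c in couplings],
            "offset": [c.tss_offset for c in couplings],
        })
        out, summary = classify_cis_pairs(betas, tpm, None, pairs, (-0.5, 0.5))
        assert summary["negative_fraction"] == pytest.approx(0.74, abs=0.08)
        profile = summary["offset_profile"]
        up_mean = profile[profile["bin_start"] < 0]["partial_r"].mean()
        down_mean = profile[profile["bin_start"] >= 0]["partial_r"].mean()
        assert up_mean < 0 < down_mean

    def test_robustness_orthogonal_vs_driven(self):
        rng = np.random.default_rng(13)
        n = 160
        mdd = np.tile([1, 0], n // 2)
        meth = pd.DataFrame(rng.uniform(0.2, 0.8, size=(10, n)),
                            index=[f"cg{i}" for i in range(10)])
        L = 3.0 * meth.to_numpy() + rng.normal(0, 0.3, size=(10, n))
        expr = pd.DataFrame(np.clip(2.0**L - 1, 0, None), index=[f"G{i}" for i in range(10)])
        pairs = pd.DataFrame({"probe_id": [f"cg{i}" for i in range(10)],
                              "gene_id": [f"G{i}" for i in range(10)], "offset": 0})
        out, _ = classify_cis_pairs(meth, expr, None, pairs, (-0.5, 0.5))
        frac = robustness_with_mdd(meth, expr, None, out, mdd, (-0.5, 0.5))
        assert frac >= 0.9
        # couplings driven entirely by the MDD split disappear after adjustment
        sep = np.where(mdd == 1, 1.0, -1.0)
        meth2 = pd.DataFrame(0.5 + 0.2 * sep + rng.normal(0, 0.02, size=(10, n)),
                             index=meth.index)
        L2 = np.tile(2.0 * sep, (10, 1)) + rng.normal(0, 0.2, size=(10, n))
        expr2 = pd.DataFrame(np.clip(2.0**L2 - 1, 0, None), index=expr.index)
        out2, _ = classify_cis_pairs(meth2, expr2, None, pairs, (-0.5, 0.5))
        assert out2["significant"].all()
        frac2 = robustness_with_mdd(meth2, expr2, None, out2, mdd, (-0.5, 0.5))
        assert frac2 <= 0.2

    def test_no_significant_pairs_is_nan(self):
        meth, expr, pairs = TestPermutationThreshold._iid_setup(30, seed=14)
        out, _ = classify_cis_pairs(meth, expr, None, pairs, (-0.9999, 0.9999))
        assert np.isnan(robustness_with_mdd(meth, expr, None, out,
                                            np.tile([0, 1], 15), (-0.9999, 0.9999)))
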