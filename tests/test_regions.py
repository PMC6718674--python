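"""Region clustering, scoring, DMR criteria, and feature enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cotwin.errors import ValidationError
from cotwin.pair_model import run_feature_scan
from cotwin.preprocess import within_pair_logratio
from cotwin.regions import (
    call_dmrs,
    feature_enrichment,
    form_candidate_regions,
    probe_correlation,
    score_region,
)
from cotwin.simulate import PlantedBlock, SimulationConfig, generate_cohort, generate_methylation

from tests.conftest import make_pair_sheet


def manifest_from_positions(positions, chrom="chr1"):
    rows = []
    for i, pos in enumerate(positions):
        rows.append(
            {
                "probe_id": f"cg{i}",
                "chrom": chrom if isinstance(chrom, str) else chrom[i],
                "pos": pos,
                "gene_symbol": ".",
                "feature_class": "Body",
                "cgi_context": "OpenSea",
                "sex_chrom": False,
                "multi_mapped": False,
                "snp_overlap": False,
                "detection_fail_fraction": 0.0,
                "intensity_z": 0.0,
            }
        )
    return pd.DataFrame(rows)


class TestClustering:
    def test_hand_clustering(self):
        # gaps 500 and 900 merge; the 9000 probe is a dropped singleton
        man = manifest_from_positions([100, 600, 1500, 9000])
        cands = form_candidate_regions(man, list(man["probe_id"]), max_gap_bp=1000)
        assert len(cands) == 1
        assert cands[0]["start"] == 100 and cands[0]["end"] == 1500
        assert cands[0]["probe_ids"] == ["cg0", "cg1", "cg2"]

    def test_chromosomes_never_merge(self):
        man = manifest_from_positions([100, 200, 100, 200], chrom=["chr1", "chr1", "chr2", "chr2"])
        cands = form_candidate_regions(man, list(man["probe_id"]), max_gap_bp=1000)
        assert len(cands) == 2
        assert {c["chrom"] for c in cands} == {"chr1", "chr2"}

    def test_all_gaps_too_large(self):
        man = manifest_from_positions([100, 5000, 10000])
        assert form_candidate_regions(man, list(man["probe_id"]), 1000) == []

    def test_gap_growth_is_monotone(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.integers(1, 200_000, size=120))
        pos = np.unique(pos)
        man = manifest_from_positions(pos)
        assigned = []
        for gap in (250, 500, 1000, 2000):
            cands = form_candidate_regions(man, list(man["probe_id"]), gap)
            assigned.append(sum(len(c["probe_ids"]) for c in cands))
        assert assigned == sorted(assigned)


class TestProbeCorrelation:
    def test_identical_probes(self):
        betas = pd.DataFrame(
            [np.linspace(0.2, 0.8, 10), np.linspace(0.2, 0.8, 10)],
            index=["cg0", "cg1"],
            columns=[f"s{i}" for i in range(10)],
        )
        cand = {"chrom": "chr1", "start": 1, "end": 2, "probe_ids": ["cg0", "cg1"]}
        assert probe_correlation(cand, betas) == pytest.approx(1.0)

    def test_matches_direct_corrcoef(self, small_cohort):
        cfg, cohort, betas, manifest, truth = small_cohort
        ids = list(betas.index[truth.probe_block == 0])
        cand = {"chrom": "chr1", "start": 1, "end": 2, "probe_ids": ids}
        corr = np.corrcoef(betas.loc[ids].to_numpy())
        expected = corr[np.triu_indices_from(corr, k=1)].mean()
        assert probe_correlation(cand, betas) == pytest.approx(expected, abs=1e-12)
        assert probe_correlation(cand, betas, method="min") == pytest.approx(
            corr[np.triu_indices_from(corr, k=1)].min(), abs=1e-12
        )

    def test_independent_probes_near_zero(self):
        rng = np.random.default_rng(1)
        betas = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(5, 158)),
            index=[f"cg{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(158)],
        )
        cand = {"chrom": "chr1", "start": 1, "end": 2, "probe_ids": list(betas.index)}
        assert abs(probe_correlation(cand, betas)) < 0.15


class TestScoring:
    def _toy_scored(self, diffs=0.04):
        """2-pair, 5-probe toy with constant beta differences."""
        sheet = make_pair_sheet(2, seed=0)
        base = np.array([[0.50, 0.46, 0.52, 0.48]])  # d, n, d, n
        betas = pd.DataFrame(
            np.repeat(base, 5, axis=0) + np.array([[diffs / 2, -diffs / 2, diffs / 2, -diffs / 2]]),
            index=[f"cg{i}" for i in range(5)],
            columns=sheet["sample_id"],
        )
        results = pd.DataFrame(
            {
                "feature_id": [f"cg{i}" for i in range(5)],
                "alpha": [0.1, 0.2, 0.1, 0.1, 0.1],
                "p": [0.02, 0.005, 0.02, 0.02, 0.02],
            }
        )
        cand = {"chrom": "chr1", "start": 100, "end": 900,
                "probe_ids": [f"cg{i}" for i in range(5)]}
        return cand, results, betas, sheet

    def test_stouffer_closed_form(self):
        cand, results, betas, sheet = self._toy_scored()
        results["p"] = 0.01
        results["alpha"] = 0.1
        region = score_region(cand, results, betas, sheet)
        z = stats.norm.isf(0.005)
        expected = 2 * stats.norm.sf(np.sqrt(5) * z)
        assert region["region_p"] == pytest.approx(expected, rel=1e-10)
        assert region["region_p"] < 0.01
        assert region["peak_p"] == pytest.approx(0.01)

    def test_hand_percent_differences(self):
        # beta_dep - beta_ctrl = 0.04 for every probe and pair
        cand, results, betas, sheet = self._toy_scored(diffs=0.0)
        dep_cols = [s for s in betas.columns if s.endswith("_d")]
        ctrl_cols = [s for s in betas.columns if s.endswith("_n")]
        betas[dep_cols] = 0.54
        betas[ctrl_cols] = 0.50
        region = score_region(cand, results, betas, sheet)
        assert region["mean_diff_pct"] == pytest.approx(4.0, abs=1e-12)
        assert region["peak_diff_pct"] == pytest.approx(4.0, abs=1e-12)
        assert region["direction"] == "hyper"
        assert region["peak_probe_id"] == "cg1"  # smallest p

    def test_mixed_signs_tie_flagged(self):
        cand, results, betas, sheet = self._toy_scored()
        results["alpha"] = [0.1, -0.1, 0.1, -0.1, 0.0]
        region = score_region(cand, results, betas, sheet)
        assert region["mean_fc"] == pytest.approx(1.0)
        assert region["direction"] == "hyper"
        assert region["direction_tie"]

    def test_identical_probes_region_p_not_larger_than_peak(self):
        cand, results, betas, sheet = self._toy_scored()
        results["p"] = 0.03
        results["alpha"] = 0.1
        region = score_region(cand, results, betas, sheet)
        assert region["region_p"] <= region["peak_p"]


class TestCallDmrs:
    @staticmethod
    def _planted_run(seed, block_sizes=(6, 4)):
        cfg = SimulationConfig(
            n_pairs=79, n_probes=600, n_genes=5, seed=seed,
            planted_dmrs=[PlantedBlock(s, 0.6, 1.15) for s in block_sizes],
        )
        cohort = generate_cohort(cfg)
        betas, manifest, truth = generate_methylation(cfg, cohort)
        rm = within_pair_logratio(betas, cohort.samples, offset=1e-6)
        results = run_feature_scan(rm)
        cands = form_candidate_regions(manifest, list(betas.index), 1000)
        scored = [score_region(c, results, betas, cohort.samples) for c in cands]
        dmrs = call_dmrs([s for s in scored if s])
        return dmrs, truth, manifest

    def test_planted_block_called_small_block_never(self):
        dmrs, truth, manifest = self._planted_run(seed=1)
        block_probes = set(manifest["probe_id"][truth.probe_block == 0])
        small_probes = set(manifest["probe_id"][truth.probe_block == 1])
        sig = dmrs[dmrs["significant"]]
        assert any(block_probes & set(ids) for ids in sig["probe_ids"])
        assert not any(small_probes <= set(ids) and len(ids) >= 5 for ids in sig["probe_ids"])

    def test_reported_dmrs_satisfy_all_criteria(self):
        dmrs, _, _ = self._planted_run(seed=2)
        sig = dmrs[dmrs["significant"]]
        assert (sig["n_probes"] >= 5).all()
        assert (sig["peak_p"] < 0.01).all()
        assert (sig["mean_probe_corr"] >= 0.30).all()
        assert (sig["region_q"] < 0.05).all()

    def test_boundary_peak_p_excluded(self):
        df = [
            {"chrom": "chr1", "start": 1, "end": 999, "probe_ids": [f"cg{i}" for i in range(5)],
             "n_probes": 5, "peak_probe_id": "cg0", "peak_p": 0.01, "mean_probe_corr": 0.9,
             "region_p": 1e-6, "mean_fc": 1.1, "mean_diff_pct": 1.0, "peak_diff_pct": 1.0,
             "direction": "hyper", "direction_tie": False}
        ]
        out = call_dmrs(df)
        assert not out["significant"].iloc[0]
        df[0]["peak_p"] = 0.0099
        assert call_dmrs(df)["significant"].iloc[0]

    def test_empty_candidates(self):
        out = call_dmrs([])
        assert len(out) == 0


class TestFeatureEnrichment:
    def _manifest(self, n=700):
        rng = np.random.default_rng(3)
        man = manifest_from_positions(np.arange(1, n + 1) * 1000)
        classes = ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "Intergenic"]
        man["feature_class"] = [classes[i % 7] for i in range(n)]  # uniform background
        man["cgi_context"] = rng.choice(["Island", "Shore", "Shelf", "OpenSea"], size=n)
        return man

    def test_single_class_enrichment(self):
        man = self._manifest()
        dmr = list(man[man["feature_class"] == "1stExon"]["probe_id"][:40])
        out = feature_enrichment(dmr, man)
        row = out[(out["category_type"] == "feature_class") & (out["category"] == "1stExon")].iloc[0]
        assert row["fold_enrichment"] == pytest.approx(7.0, rel=0.05)
        other = out[(out["category_type"] == "feature_class") & (out["category"] != "1stExon")]
        assert (other["fold_enrichment"] == 0).all()

    def test_background_proportions_give_no_signal(self):
        man = self._manifest()
        # stratified draw: exactly the background class proportions
        dmr = list(man.groupby("feature_class")["probe_id"].head(15))
        out = feature_enrichment(dmr, man)
        fc_rows = out[out["category_type"] == "feature_class"]
        assert np.allclose(fc_rows["fold_enrichment"], 1.0, atol=0.01)
        assert (fc_rows["q"] > 0.05).all()

    def test_independence_table_oracle(self):
        # 2x2 table (10, 90, 100, 900): odds ratio 1, Fisher p = 1
        odds, p = stats.fisher_exact([[10, 90], [100, 900]])
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_empty_dmr_set(self):
        out = feature_enrichment([], self._manifest(70))
        assert len(out) == 0
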