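"""End-to-end orchestration: simulate/load inputs, run all stages, report.

Stages: preprocess -> within-pair scans (EWAS + differential expression)
-> DMR calling -> cis integration -> differential networks -> overlap
enrichment [-> replication when case-control inputs are supplied]. Each
stage writes fixed-name TSV/JSON outputs under the run directory and
records an input-content hash in ``cache.json``; on rerun, stages whose
hash matches and whose outputs exist are skipped. Wall-clock timings go to
the log only, so a rerun with an identical config is byte-identical on
disk.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from cotwin import enrichment as enr
from cotwin import integration as integ
from cotwin import io as cio
from cotwin import networks as nets
from cotwin import preprocess as prep
from cotwin import regions as reg
from cotwin import replication as repl
from cotwin.errors import ConfigError
from cotwin.io import log
from cotwin.pair_model import run_feature_scan
from cotwin.simulate import (
    PlantedBlock,
    PlantedCoupling,
    SimulationConfig,
    annotate_manifest_genes,
    generate_cohort,
    generate_expression,
    generate_methylation,
)

STAGES = ("simulate", "preprocess", "ewas", "dge", "dmr", "integrate", "network", "overlap", "replicate")


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class Run:
    """A pipeline run bound to a config and an output directory."""

    def __init__(self, config: dict, out_dir: str | Path, seed: int | None = None):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed if seed is not None else config.get("seed", 0))
        cache_path = self.out / "cache.json"
        self.cache = json.loads(cache_path.read_text()) if cache_path.exists() else {}
        self.report: dict = {"seed": self.seed, "stages": {}, "config": _jsonable(config)}

    def _save_cache(self) -> None:
        (self.out / "cache.json").write_text(json.dumps(self.cache, indent=1, sort_keys=True))

    def stage(self, name: str, inputs_hash: str, outputs: list[str]):
        """True when the stage must run (cache miss or missing outputs)."""
        paths = [self.out / o for o in outputs]
        entry = self.cache.get(name)
        if entry and entry.get("hash") == inputs_hash and all(p.exists() for p in paths):
            log.info("stage %s: cached, skipping", name)
            self.report["stages"][name] = entry.get("counts", {})
            return False
        return True

    def done(self, name: str, inputs_hash: str, counts: dict) -> None:
        self.cache[name] = {"hash": inputs_hash, "counts": _jsonable(counts)}
        self._save_cache()
        self.report["stages"][name] = counts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def simulate_inputs(sim_cfg: dict, seed: int, out_dir: Path) -> dict[str, Path]:
    """Generate a synthetic cohort and write the fixture files."""
    blocks = [PlantedBlock(*b) if not isinstance(b, PlantedBlock) else b
              for b in sim_cfg.get("planted_dmrs", [])]
    couplings = [PlantedCoupling(*c) if not isinstance(c, PlantedCoupling) else c
                 for c in sim_cfg.get("cis_couplings", [])]
    config = SimulationConfig(
        n_pairs=int(sim_cfg.get("n_pairs", 40)),
        n_probes=int(sim_cfg.get("n_probes", 2000)),
        n_genes=int(sim_cfg.get("n_genes", 500)),
        n_batches=int(sim_cfg.get("n_batches", 10)),
        batch_sd=float(sim_cfg.get("batch_sd", 0.1)),
        noise_sd=float(sim_cfg.get("noise_sd", 0.2)),
        planted_dmrs=blocks,
        planted_degs=[tuple(d) for d in sim_cfg.get("planted_degs", [])],
        cis_couplings=couplings,
        covariate_effects=dict(sim_cfg.get("covariate_effects", {})),
        flagged_fraction=float(sim_cfg.get("flagged_fraction", 0.01)),
        seed=seed,
    )
    cohort = generate_cohort(config)
    betas, manifest, truth = generate_methylation(config, cohort)
    tpm, gene_anno, truth = generate_expression(config, cohort, truth, betas, manifest)
    manifest = annotate_manifest_genes(manifest, gene_anno)

    paths = {
        "beta": out_dir / "betas.tsv",
        "tpm": out_dir / "tpm.tsv",
        "manifest": out_dir / "manifest.tsv",
        "genes": out_dir / "genes.tsv",
        "samples": out_dir / "samples.tsv",
        "truth": out_dir / "truth.json",
    }
    cio.write_matrix(betas, paths["beta"])
    cio.write_matrix(tpm, paths["tpm"])
    cio.write_manifest(manifest, paths["manifest"])
    gene_anno.to_csv(paths["genes"], sep="\t", index=False)
    cio.write_sample_sheet(cohort.samples, paths["samples"])
    paths["truth"].write_text(
        json.dumps(
            {
                "probe_alpha": truth.probe_alpha.tolist(),
                "probe_block": truth.probe_block.tolist(),
                "gene_log2fc": truth.gene_log2fc.tolist(),
                "couplings": [
                    {"probe": c.probe, "gene": c.gene, "r": c.r, "tss_offset": c.tss_offset}
                    for c in truth.couplings
                ],
            },
            indent=1,
        )
    )
    return paths


def run_all(
    config: dict,
    out_dir: str | Path,
    seed: int | None = None,
    simulate: bool = False,
    stages: list[str] | None = None,
) -> dict:
    """Execute the pipeline; returns the run report (also written as JSON)."""
    t_start = time.time()
    run = Run(config, out_dir, seed=seed)
    out = run.out
    want = set(stages) if stages else set(STAGES)

    paths_cfg = dict(config.get("paths", {}))
    if simulate:
        sim_hash = _hash(config.get("simulate", {}), run.seed)
        fixture_names = ["betas.tsv", "tpm.tsv", "manifest.tsv", "genes.tsv", "samples.tsv"]
        if run.stage("simulate", sim_hash, fixture_names):
            t0 = time.time()
            simulate_inputs(config.get("simulate", {}), run.seed, out)
            log.info("stage simulate: %.1fs", time.time() - t0)
            run.done("simulate", sim_hash, {"fixtures": fixture_names})
        paths_cfg = {
            "beta": out / "betas.tsv",
            "tpm": out / "tpm.tsv",
            "manifest": out / "manifest.tsv",
            "genes": out / "genes.tsv",
            "samples": out / "samples.tsv",
        }
    required = ["beta", "manifest", "samples"]
    missing = [k for k in required if k not in paths_cfg]
    if missing:
        raise ConfigError(f"missing input paths: {missing}")
    has_expr = "tpm" in paths_cfg and "genes" in paths_cfg
    if not has_expr and ({"dge", "integrate"} & want) and not simulate:
        raise ConfigError("expression inputs (tpm, genes) required for dge/integrate stages")

    # ---- load inputs
    betas = cio.read_matrix(paths_cfg["beta"], kind="beta")
    manifest = cio.read_manifest(paths_cfg["manifest"])
    sheet = cio.read_sample_sheet(paths_cfg["samples"])
    tpm = cio.read_matrix(paths_cfg["tpm"], kind="tpm") if has_expr else None
    gene_anno = cio.read_gene_annotation(paths_cfg["genes"]) if has_expr else None
    input_hash = _hash({k: _file_hash(Path(v)) for k, v in paths_cfg.items()})

    pc = config["preprocess"]
    retained, qc_report = prep.filter_probes(
        manifest, betas, pc["detect_fail_max"], pc["intensity_z_max"]
    )
    betas_f = betas.loc[retained]
    qc_report.to_csv(out / "probe_qc.tsv", sep="\t", index=False)
    genes_kept = prep.filter_genes(tpm, pc["gene_floor"], pc["gene_max_low_fraction"]) if has_expr else []
    tpm_f = tpm.loc[genes_kept] if has_expr else None
    run.report["stages"]["preprocess"] = {
        "probes_retained": len(retained),
        "genes_retained": len(genes_kept),
    }

    meth_rm = prep.within_pair_logratio(betas_f, sheet, offset=pc["meth_offset"])

    # ---- EWAS
    ewas_hash = _hash(input_hash, config["preprocess"], config["model"])
    if "ewas" in want and run.stage("ewas", ewas_hash, ["ewas.tsv"]):
        t0 = time.time()
        ewas = run_feature_scan(meth_rm)
        ewas.to_csv(out / "ewas.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
        log.info("stage ewas: %.1fs", time.time() - t0)
        run.done("ewas", ewas_hash, {"n_probes": len(ewas)})
    ewas = pd.read_csv(out / "ewas.tsv", sep="\t") if (out / "ewas.tsv").exists() else None

    # ---- differential expression
    dge = None
    if has_expr and "dge" in want:
        expr_rm = prep.within_pair_logratio(tpm_f, sheet, offset=pc["expr_offset"])
        if run.stage("dge", ewas_hash, ["degs.tsv"]):
            t0 = time.time()
            dge = run_feature_scan(expr_rm)
            dge.to_csv(out / "degs.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
            log.info("stage dge: %.1fs", time.time() - t0)
            run.done("dge", ewas_hash, {"n_genes": len(dge),
                                        "n_significant": int((dge["q"] < config["model"]["q_max"]).sum())})
        dge = pd.read_csv(out / "degs.tsv", sep="\t")

    # ---- DMR calling
    dmrs = None
    candidates = []
    if ewas is not None and "dmr" in want:
        rc = config["regions"]
        candidates = reg.form_candidate_regions(manifest, retained, rc["max_gap_bp"])
        scored = [
            s for c in candidates
            if (s := reg.score_region(c, ewas, betas_f, sheet, corr_method=rc["corr_method"]))
        ]
        dmrs = reg.call_dmrs(
            scored, rc["min_probes"], rc["peak_p"], rc["min_corr"], rc["q_max"]
        )
        dmr_table = dmrs.copy()
        man_idx = manifest.set_index("probe_id")
        dmr_table["gene"] = [
            next((g for p in ids if (g := man_idx.loc[p, "gene_symbol"]) != "."), ".")
            for ids in dmr_table["probe_ids"]
        ]
        dmr_table["probe_ids"] = dmr_table["probe_ids"].apply(",".join)
        dmr_table.to_csv(out / "dmrs.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
        sig = dmr_table[dmr_table["significant"]]
        if len(sig):
            cio.write_dmr_bed(sig, out / "dmrs.bed")
        else:
            (out / "dmrs.bed").write_text("")
        enrich = reg.feature_enrichment(
            [p for _, row in sig.iterrows() for p in row["probe_ids"].split(",")],
            manifest,
            background_probe_ids=retained,
        )
        enrich.to_csv(out / "dmr_enrichment.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
        run.report["stages"]["dmr"] = {
            "n_candidates": len(candidates),
            "n_meeting_criteria": int(dmrs["meets_criteria"].sum()) if len(dmrs) else 0,
            "n_significant": int(dmrs["significant"].sum()) if len(dmrs) else 0,
        }

    # ---- cis integration
    if has_expr and "integrate" in want and tpm_f is not None and len(tpm_f):
        ic = config["integration"]
        cis = integ.map_cis_pairs(
            manifest[manifest["probe_id"].isin(retained)], gene_anno, ic["cis_window"]
        )
        cis = cis[cis["gene_id"].isin(genes_kept)].reset_index(drop=True)
        cov = _sample_covariates(sheet, betas_f.columns)
        if len(cis):
            thresholds = integ.permutation_threshold(
                betas_f, tpm_f, cov, cis, B=ic["permutations"], alpha=ic["alpha"],
                seed=run.seed + 1000, tail=ic["tail"],
            )
            classified, summary = integ.classify_cis_pairs(
                betas_f, tpm_f, cov, cis, thresholds,
                offset_bin_bp=ic["offset_bin_bp"], window=ic["cis_window"],
            )
            mdd = (sheet.set_index("sample_id").loc[betas_f.columns, "role"] == "depressed").to_numpy(int)
            robust = integ.robustness_with_mdd(betas_f, tpm_f, cov, classified, mdd, thresholds)
            classified.to_csv(out / "cis_pairs.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
            profile = summary.pop("offset_profile")
            profile.to_csv(out / "cis_offset_profile.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
            summary.update(
                threshold_lower=thresholds[0], threshold_upper=thresholds[1],
                permutations=ic["permutations"], robust_to_mdd_fraction=robust,
            )
            (out / "cis_summary.json").write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True))
            run.report["stages"]["integrate"] = {
                k: v for k, v in summary.items() if not isinstance(v, pd.DataFrame)
            }

    # ---- differential networks
    if ewas is not None and "network" in want and dmrs is not None:
        nc = config["networks"]
        dep_ids = list(sheet[sheet["role"] == "depressed"]["sample_id"])
        ctrl_pairs = sheet.set_index(["pair_id", "role"])["sample_id"]
        pair_ids = list(dict.fromkeys(sheet["pair_id"]))
        ctrl_ids = [ctrl_pairs[p, "nondepressed"] for p in pair_ids]
        dep_ids = [ctrl_pairs[p, "depressed"] for p in pair_ids]
        report_net = {}
        nominal = dmrs[dmrs["region_p"] < nc["nominal_p"]] if len(dmrs) else dmrs
        if nominal is not None and len(nominal) >= 10:
            regions_df = nominal.copy()
            regions_df["probe_ids"] = regions_df["probe_ids"].apply(
                lambda v: v if isinstance(v, list) else v.split(",")
            )
            node_dep = nets.region_node_matrix(regions_df, betas_f, dep_ids)
            node_ctrl = nets.region_node_matrix(regions_df, betas_f, ctrl_ids)
            net_dep = nets.build_group_network(node_dep, "depressed", edge_cutoff=nc["edge_cutoff"])
            modules = nets.detect_modules(net_dep, nc["min_module_size"], nc["tree_cut_height"])
            if len(modules):
                sets = {m["module_id"]: m["members"] for _, m in modules.iterrows()}
                conn = nets.differential_connectivity(
                    sets, node_dep, node_ctrl, B_perm=nc["permutations"],
                    edge_cutoff=nc["edge_cutoff"], seed=run.seed + 2000,
                )
                conn.to_csv(out / "connectivity.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
                modules_out = modules.copy()
                modules_out["members"] = modules_out["members"].apply(",".join)
                modules_out.to_csv(out / "modules.tsv", sep="\t", index=False)
                report_net = {"n_nodes": len(node_dep), "n_modules": len(modules)}
            else:
                report_net = {"n_nodes": len(node_dep), "n_modules": 0}
        else:
            log.warning("too few nominal regions for a co-methylation network")
            report_net = {"n_nodes": 0, "n_modules": 0}
        run.report["stages"]["network"] = report_net

    # ---- overlap enrichment
    if ewas is not None and dge is not None and dmrs is not None and "overlap" in want:
        man_idx = manifest.set_index("probe_id")
        sig_dmrs = dmrs[dmrs["significant"]] if len(dmrs) else dmrs
        dm_genes = set()
        for ids in sig_dmrs["probe_ids"]:
            ids = ids if isinstance(ids, list) else ids.split(",")
            dm_genes |= {man_idx.loc[p, "gene_symbol"] for p in ids} - {"."}
        de_genes = set(dge[dge["q"] < config["model"]["q_max"]]["feature_id"])
        background = (set(manifest["gene_symbol"]) - {"."}) & set(genes_kept)
        dm_genes &= background
        de_genes &= background
        if background and (dm_genes or de_genes):
            result = enr.fisher_overlap(dm_genes, de_genes, background)
            overlap = {
                "n_both": result.n_both, "n_dm_only": result.n_a_only,
                "n_de_only": result.n_b_only, "background": result.background_size,
                "odds_ratio": result.odds_ratio, "fold_enrichment": result.fold_enrichment,
                "p": result.p,
            }
        else:
            overlap = {"n_both": 0, "background": len(background)}
        (out / "overlap.json").write_text(json.dumps(_jsonable(overlap), indent=1, sort_keys=True))
        run.report["stages"]["overlap"] = overlap

    # ---- replication
    if "replicate" in want and "replication_beta" in paths_cfg:
        rbeta = cio.read_matrix(paths_cfg["replication_beta"], kind="beta")
        rsheet = pd.read_csv(paths_cfg["replication_samples"], sep="\t")
        cases = rsheet["case"].to_numpy(int)
        cov = rsheet[["age", "sex"]].to_numpy(float)
        feats = [f for f in rbeta.index if f in set(ewas["feature_id"])]
        scan = repl.casecontrol_scan(rbeta, cases, cov, feats)
        scan.to_csv(out / "replication.tsv", sep="\t", index=False, float_format=cio.FLOAT_FORMAT)
        run.report["stages"]["replicate"] = {"n_features": len(scan)}

    log.info("total wall clock: %.1fs", time.time() - t_start)
    (out / "report.json").write_text(json.dumps(_jsonable(run.report), indent=1, sort_keys=True))
    return run.report


def _sample_covariates(sheet: pd.DataFrame, sample_ids) -> np.ndarray:
    """Per-sample covariate matrix for the partial-correlation analysis."""
    from cotwin.simulate import STANDARD_COVARIATES

    sub = sheet.set_index("sample_id").loc[list(sample_ids)]
    return sub[list(STANDARD_COVARIATES)].to_numpy(float)
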