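"""End-to-end pipeline driver for the synthetic-cohort reproduction run.

``run_pipeline`` executes generate -> mask -> QC/AMF -> permutation PCA ->
bootstrap DMR screen -> random-forest marker selection -> healthy-cohort
validation, writes intermediate artifacts, and emits a deterministic JSON
report with per-stage counts.

One global seed derives independent per-stage seeds through
``numpy.random.SeedSequence`` spawning, so each stage is reproducible in
isolation and the whole run is byte-identical given the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cfamf import amf as amf_mod
from cfamf import dmr as dmr_mod
from cfamf import forest as forest_mod
from cfamf import io as io_mod
from cfamf import simulate as sim_mod
from cfamf import unsupervised as unsup_mod
from cfamf import validation as val_mod


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every knob of the synthetic end-to-end run, serializable to YAML."""

    simulation: sim_mod.SimulationConfig = field(
        default_factory=sim_mod.SimulationConfig)
    rf: forest_mod.RFConfig = field(default_factory=forest_mod.RFConfig)
    min_cpgs: int = 5
    max_null_fraction: float = 0.10
    mask_fraction: float = 0.01
    variance_z: float = 2.0
    pca_k: int = 30
    pca_n_perm: int = 1000
    pca_scale: bool = False
    train_fraction: float = 0.85
    n_subsets: int = 3
    coverage_threshold: float = 0.90
    z_threshold: float = 2.0
    q_threshold: float = 0.05
    q_method: str = "bh"
    top_k: int = 500
    n_healthy: int = 12
    healthy_depth_mean: float = 30.0
    healthy_spread: float = 0.02
    median_tolerance: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["cpgs_per_bin"] = list(self.simulation.cpgs_per_bin)
        d["simulation"]["baseline_beta"] = list(self.simulation.baseline_beta)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in data:
            data["simulation"] = _nested(
                sim_mod.SimulationConfig, data["simulation"])
        if "rf" in data:
            data["rf"] = _nested(forest_mod.RFConfig, data["rf"])
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _nested(cls, data):
    if isinstance(data, cls):
        return data
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    data = dict(data)
    for key in ("cpgs_per_bin", "baseline_beta"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: PipelineConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def derive_seeds(seed: int, n: int = 8) -> list:
    """Per-stage integer seeds spawned from one global seed (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage on a freshly simulated cohort; return the report.

    When ``outdir`` is given, intermediate artifacts (AMF table, QC report,
    scree/score tables, per-subset statistics, candidate and marker BEDs,
    gene list, validation summary) and ``report.json`` are written there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    (sim_seed, mask_seed, split_seed, subset_seed, pca_seed, rf_seed,
     healthy_seed, gene_seed) = derive_seeds(config.seed, 8)

    report: dict = {"config_hash": config.config_hash(),
                    "seed": config.seed,
                    "stage_seeds": {
                        "simulate": sim_seed, "mask": mask_seed,
                        "split": split_seed, "subsets": subset_seed,
                        "pca": pca_seed, "rf": rf_seed,
                        "healthy": healthy_seed, "gene_model": gene_seed,
                    }}

    # --- stage 1: simulate -------------------------------------------------
    sim_config = dataclasses.replace(config.simulation, seed=sim_seed)
    cohort = sim_mod.simulate_cohort(sim_config)
    report["simulate"] = {
        "n_samples": len(cohort.calls),
        "n_bins": int(len(cohort.bins)),
        "n_dmr_planted": len(cohort.truth.dmr_bin_ids),
    }

    # --- stage 2: mask -----------------------------------------------------
    blacklist = sim_mod.simulate_blacklist(
        cohort, fraction=config.mask_fraction, seed=mask_seed)
    mask = io_mod.RegionMask.from_tuples(
        blacklist[["chrom", "start", "end"]].itertuples(index=False))
    masked = {sid: io_mod.apply_mask(cs, mask)
              for sid, cs in cohort.calls.items()}
    report["mask"] = {"n_intervals": int(len(blacklist))}

    # --- stage 3: QC + AMF matrix -----------------------------------------
    scheme = amf_mod.BinScheme(chrom_sizes=cohort.chrom_sizes,
                               bin_width=sim_config.bin_width,
                               min_cpgs=config.min_cpgs)
    bins = amf_mod.eligible_bins(cohort.cpg_positions, scheme)
    qc = {}
    vectors = {}
    for sid in cohort.calls:
        qc[sid] = amf_mod.sample_qc(masked[sid], cohort.chh_calls[sid],
                                    scheme, bins)
        vectors[sid] = amf_mod.compute_amf(masked[sid], scheme, bins)
    matrix, amf_report = amf_mod.assemble_matrix(
        vectors, bins, qc, max_null_fraction=config.max_null_fraction)
    report["amf"] = amf_report
    if out is not None:
        io_mod.write_amf_table(matrix, out / "amf_table.tsv")
        pd.DataFrame([{
            "sample_id": r.sample_id,
            "conversion_rate": r.conversion_rate,
            "depth_summary": r.depth_summary, "pass": r.pass_qc,
        } for r in qc.values()]).to_csv(out / "qc.tsv", sep="\t",
                                        index=False, float_format="%.6g")

    # --- stage 4: unsupervised --------------------------------------------
    screened = unsup_mod.variance_screen(matrix, z_threshold=config.variance_z)
    imputed = unsup_mod.impute_group_means(screened, cohort.cohort)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        pca = unsup_mod.pca_with_permutation_cutoff(
            imputed, k=config.pca_k, n_perm=config.pca_n_perm,
            seed=pca_seed, scale=config.pca_scale)
    correlations = unsup_mod.correlate_pcs(pca, cohort.cohort)
    report["unsupervised"] = {
        "n_bins_variance_screened": int(screened.shape[0]),
        "n_significant_pcs": len(pca.significant_pcs),
        "cutoff": float(pca.cutoff),
    }
    if out is not None:
        pd.DataFrame({
            "pc": np.arange(1, pca.n_components + 1),
            "variance_proportion": pca.variance_proportions,
            "cutoff": pca.cutoff,
        }).to_csv(out / "scree.tsv", sep="\t", index=False,
                  float_format="%.10g")
        pca.scores.to_csv(out / "pc_scores.tsv", sep="\t",
                          float_format="%.10g")
        correlations.to_csv(out / "pc_correlations.tsv", sep="\t",
                            index=False, float_format="%.6g")

    # --- stage 5: DMR screen ----------------------------------------------
    split_spec = dmr_mod.SplitSpec(train_fraction=config.train_fraction,
                                   seed=split_seed)
    train_ids, test_ids = dmr_mod.stratified_split(cohort.cohort, split_spec)
    subsets = dmr_mod.draw_subsets(train_ids, cohort.cohort,
                                   n_subsets=config.n_subsets,
                                   seed=subset_seed)
    results = []
    for i, subset in enumerate(subsets, start=1):
        res = dmr_mod.screen_subset(
            matrix, subset, cohort.cohort,
            coverage_threshold=config.coverage_threshold,
            z_threshold=config.z_threshold,
            q_threshold=config.q_threshold, q_method=config.q_method)
        results.append(res)
        if out is not None:
            res.table.to_csv(out / f"subset{i}_stats.tsv", sep="\t",
                             index=False, float_format="%.6g")
    candidate_set = dmr_mod.intersect_and_rank(results, top_k=config.top_k)
    groups = cohort.cohort.set_index("sample_id")["group"]
    report["dmr"] = {
        "n_train": len(train_ids), "n_test": len(test_ids),
        "n_train_good": int((groups.loc[train_ids] == "good").sum()),
        "n_train_poor": int((groups.loc[train_ids] == "poor").sum()),
        "n_test_good": int((groups.loc[test_ids] == "good").sum()),
        "n_test_poor": int((groups.loc[test_ids] == "poor").sum()),
        "n_tested_per_subset": [r.n_tested for r in results],
        "n_dmr_per_subset": [len(r.dmr_ids) for r in results],
        "n_intersection": len(candidate_set.intersection_dmrs),
        "n_candidates": len(candidate_set.candidates),
    }
    truth_ids = set(cohort.truth.dmr_bin_ids)
    selected = set(candidate_set.candidates)
    if selected:
        recall = len(selected & truth_ids) / max(len(truth_ids), 1)
        precision = len(selected & truth_ids) / len(selected)
    else:
        recall, precision = 0.0, 0.0
    n_hypo = sum(
        int((r.table.set_index("bin_id").loc[list(selected), "direction"]
             == "hypo").sum()) for r in results) if selected else 0
    n_dir = 3 * len(selected) if selected else 0
    report["truth_recovery"] = {
        "candidate_recall": recall,
        "candidate_precision": precision,
        "hypo_fraction_among_candidates":
            (n_hypo / n_dir) if n_dir else None,
    }
    if out is not None:
        cand_bed = io_mod.parse_bin_ids(candidate_set.candidates)
        cand_bed["name"] = candidate_set.candidates
        io_mod.write_bed_regions(cand_bed, out / "candidates.bed")

    # --- stage 6: random forest -------------------------------------------
    rf_config = dataclasses.replace(config.rf, seed=rf_seed)
    model = forest_mod.train_forest(
        matrix, candidate_set.candidates, cohort.cohort, train_ids,
        test_ids, rf_config)
    markers = forest_mod.rank_markers(model, matrix, cohort.cohort)
    gene_model = sim_mod.simulate_gene_model(cohort.chrom_sizes,
                                             seed=gene_seed)
    annotated = forest_mod.annotate_markers(markers, gene_model)
    report["rf"] = {
        "best_mtry": model.best_mtry,
        "cv_auc": float(model.cv_metric_table.set_index("mtry")
                        .loc[model.best_mtry, "cv_auc"]),
        "train_auc": float(model.roc_train["auc"]),
        "test_auc": float(model.roc_test["auc"]) if model.roc_test else None,
        "n_markers": int(len(markers)),
        "marker_regions": {
            r: int((annotated["region"] == r).sum())
            for r in ("exon", "intron", "intergenic")
        },
    }
    if out is not None:
        io_mod.write_bed_regions(
            annotated.rename(columns={"bin_id": "name"}),
            out / "markers.bed")
        annotated.to_csv(out / "markers.tsv", sep="\t", index=False,
                         float_format="%.6g")
        model.importance.sort_values(ascending=False).to_csv(
            out / "importance.tsv", sep="\t", float_format="%.6g")
        forest_mod.export_gene_list(annotated, out / "marker_genes.txt")

    # --- stage 7: external validation -------------------------------------
    marker_regions = annotated[["chrom", "start", "end"]].copy()
    marker_regions["name"] = annotated["bin_id"]
    healthy_cfg = dataclasses.replace(
        sim_config, depth_mean=config.healthy_depth_mean)
    poor_means = (cohort.truth.per_bin_group_means.set_index("bin_id")
                  .loc[list(annotated["bin_id"]), "mean_poor"].to_numpy())
    healthy = sim_mod.simulate_healthy_bedset(
        healthy_cfg, marker_regions, n_samples=config.n_healthy,
        region_means=poor_means, spread=config.healthy_spread,
        seed=healthy_seed)
    retained, cov_report = val_mod.exclude_low_coverage_samples(
        healthy, marker_regions)
    ext_amf = pd.DataFrame(
        {cs.sample_id: val_mod.amf_over_regions(cs, marker_regions)
         for cs in retained})
    row = {b: i for i, b in enumerate(matrix.bin_ids())}
    study_amf = pd.DataFrame(
        matrix.values[[row[b] for b in annotated["bin_id"]]],
        index=list(annotated["bin_id"]), columns=matrix.samples)
    comparison = val_mod.compare_distributions(
        study_amf, groups, ext_amf, tolerance=config.median_tolerance)
    n_covered = int(comparison["covered"].sum())
    report["validation"] = {
        "n_external_samples": len(healthy),
        "n_external_retained": len(retained),
        "n_marker_regions": int(len(marker_regions)),
        "n_regions_covered": n_covered,
        "n_regions_stringent": int(
            comparison.loc[comparison["covered"], "stringent"]
            .fillna(False).astype(bool).sum()),
    }
    if out is not None:
        comparison.to_csv(out / "validation.tsv", sep="\t", index=False,
                          float_format="%.6g")

    # containment chain sanity
    chain = (
        report["rf"]["n_markers"], report["dmr"]["n_candidates"],
        report["dmr"]["n_intersection"],
        min(report["dmr"]["n_dmr_per_subset"]),
        min(report["dmr"]["n_tested_per_subset"]),
        report["amf"]["n_bins_retained"],
    )
    report["containment_chain_ok"] = all(
        a <= b for a, b in zip(chain, chain[1:]))

    if out is not None:
        write_report(report, out / "report.json")
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
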