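"""End-to-end pipeline driver.

Runs simulate/ingest → preprocess → network → cross-cohort validation →
association → enrichment → survival → matching and writes every stage's
outputs plus a machine-readable summary with provenance (config, seed,
output checksums) into a run directory.  A single global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence(seed).spawn``, in the
fixed stage order below, so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .community import association_table, eigengene_set, group_difference
from .enrichment import GeneSetCollection, enrichment_table
from .matching import nn_match, propensity_scores
from .network import (
    NetworkConfig,
    build_network,
    detect_communities,
    merge_similar,
    scan_soft_threshold,
)
from .preprocessing import (
    CountMatrix,
    ExpressionMatrix,
    FilterConfig,
    batch_adjust,
    filter_expressed,
    iqr_filter,
    tmm_normalize,
)
from .survival import deathclass_anova, km_curve, prognosis_scan, tercile_split
from .synthetic import SimulationConfig, default_config, generate_multi_cohort
from .validation import preservation_z, retain_modules, revalidate_edges

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "preprocess", "network", "validate",
    "associate", "enrich", "survival", "match",
]

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    out_dir: str = "coexpipe_run"
    seed: int = 0
    # data source: bundled synthetic generator by default, or file paths
    simulation: Optional[SimulationConfig] = None
    discovery_counts: Optional[str] = None
    annotations: Optional[str] = None
    validation_cohorts: list = field(default_factory=list)  # [{name, path, unit}]
    geneset_gmt: Optional[str] = None
    # stage knobs
    filter: FilterConfig = field(default_factory=FilterConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    edge_alpha: float = 0.05
    require_all_cohorts: bool = False
    n_permutations: int = 200
    z_threshold: float = 3.0
    enrichment_sided: str = "greater"
    traits: list = field(default_factory=lambda: ["nt_probnp", "lvef", "vo2peak", "activity"])
    caliper: Optional[float] = None
    edge_export_min_tom: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            from .synthetic import CohortSpec, SurvivalLink, TraitLink

            sim["cohorts"] = [CohortSpec(**c) for c in sim.get("cohorts", [])]
            sim["trait_links"] = [TraitLink(**t) for t in sim.get("trait_links", [])]
            if sim.get("survival_link"):
                sim["survival_link"] = SurvivalLink(**sim["survival_link"])
            raw["simulation"] = SimulationConfig(**sim)
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "network" in raw:
            raw["network"] = NetworkConfig(**raw["network"])
        return cls(**raw)


@dataclass
class PipelineResult:
    run_dir: Path
    summary: dict


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed: SeedSequence(global).spawn by stage index."""
    children = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return children[STAGES.index(stage)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance(stage: str, cfg: PipelineConfig, stage_dir: Path, extra=None) -> dict:
    files = sorted(p for p in stage_dir.iterdir() if p.is_file() and p.name != "provenance.json")
    prov = {
        "stage": stage,
        "seed": cfg.seed,
        "outputs": {p.name: _sha256(p) for p in files},
    }
    if extra:
        prov.update(extra)
    cio.write_json(prov, stage_dir / "provenance.json")
    return prov


def _default_genesets(truth, rng) -> GeneSetCollection:
    """Planted-module gene sets (with decoy background genes) for testing ORA."""
    labels = truth.labels
    background = list(labels.index[labels == 0])
    sets = {}
    for m in sorted(set(labels) - {0}):
        members = set(labels.index[labels == m])
        n_decoy = max(5, len(members) // 4)
        decoys = rng.choice(background, size=min(n_decoy, len(background)), replace=False)
        sets[f"planted_module_{m}"] = members | set(decoys)
    all_genes = list(labels.index)
    sets["random_mixed"] = set(
        rng.choice(all_genes, size=min(40, len(all_genes)), replace=False)
    )
    return GeneSetCollection(sets=sets, source="synthetic")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; outputs land under ``config.out_dir``.

    A stage failure raises with the stage name; earlier outputs remain on
    disk.  Identical configs (including seed) reproduce outputs bit-exactly.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def _stage_dir(name: str) -> Path:
        d = run_dir / name
        d.mkdir(exist_ok=True)
        return d

    try:
        # ---- simulate / ingest -------------------------------------------
        stage = "simulate"
        d = _stage_dir(stage)
        truth = None
        if config.discovery_counts:
            discovery = cio.read_counts_tsv(config.discovery_counts, cohort="discovery")
            annotations = cio.read_annotations_csv(config.annotations)
            cohorts_raw: dict = {"discovery": discovery}
            for vc in config.validation_cohorts:
                if vc.get("unit", "counts") == "counts":
                    cohorts_raw[vc["name"]] = cio.read_counts_tsv(vc["path"], cohort=vc["name"])
                else:
                    cohorts_raw[vc["name"]] = cio.read_expression_tsv(
                        vc["path"], unit=vc["unit"], cohort=vc["name"]
                    )
        else:
            sim = config.simulation or default_config(seed=config.seed)
            matrices, annotations, truth = generate_multi_cohort(sim)
            cohorts_raw = matrices
            for name, m in matrices.items():
                if isinstance(m, CountMatrix):
                    cio.write_counts_tsv(m, d / f"{name}.counts.tsv")
                else:
                    cio.write_expression_tsv(m, d / f"{name}.expr.tsv")
            cio.write_annotations_csv(annotations, d / "annotations.csv")
            truth.labels.to_csv(d / "truth_labels.tsv", sep="\t")
        discovery = cohorts_raw["discovery"]
        summary["stages"][stage] = _provenance(stage, config, d, {
            "cohorts": {k: list(getattr(v, "counts", getattr(v, "values", None)).shape)
                        for k, v in cohorts_raw.items()}})

        # ---- preprocess ---------------------------------------------------
        stage = "preprocess"
        d = _stage_dir(stage)
        expr_cohorts: dict[str, ExpressionMatrix] = {}
        retained_per_cohort: dict[str, set] = {}
        factors = {}
        for name, mat in cohorts_raw.items():
            if isinstance(mat, CountMatrix):
                kept = filter_expressed(mat, config.filter)
                expr, fac = tmm_normalize(mat)
                expr_cohorts[name] = ExpressionMatrix(
                    values=expr.values.loc[kept], unit=expr.unit, cohort=name,
                    provenance=expr.provenance)
                retained_per_cohort[name] = set(kept)
                factors[name] = fac
            else:
                kept = iqr_filter(mat, config.filter)
                expr_cohorts[name] = ExpressionMatrix(
                    values=mat.values.loc[kept], unit=mat.unit, cohort=name,
                    provenance={"method": "iqr_filter",
                                "iqr_cutoff": config.filter.iqr_cutoff,
                                "scale": mat.unit})
                retained_per_cohort[name] = set(kept)
        # reproducible transcriptome: expressed in discovery AND in >= 1
        # validation cohort
        val_names = [n for n in expr_cohorts if n != "discovery"]
        confirmed = set()
        for n in val_names:
            confirmed |= retained_per_cohort[n]
        core = retained_per_cohort["discovery"] & confirmed if val_names else retained_per_cohort["discovery"]
        core_idx = expr_cohorts["discovery"].genes.intersection(sorted(core))
        disc_expr = ExpressionMatrix(
            values=expr_cohorts["discovery"].values.loc[core_idx],
            unit=expr_cohorts["discovery"].unit, cohort="discovery",
            provenance=expr_cohorts["discovery"].provenance)
        for name, expr in expr_cohorts.items():
            cio.write_expression_tsv(expr, d / f"{name}.expr.tsv")
        for name, fac in factors.items():
            fac.to_csv(d / f"{name}.tmm_factors.csv")
        summary["stages"][stage] = _provenance(stage, config, d, {
            "retained_per_cohort": {k: len(v) for k, v in retained_per_cohort.items()},
            "core_transcriptome": len(core_idx)})

        # ---- network ------------------------------------------------------
        stage = "network"
        d = _stage_dir(stage)
        scan = scan_soft_threshold(
            np.corrcoef(disc_expr.values.to_numpy()), config=config.network)
        if scan.recommended != config.network.power:
            logger.warning("configured power %d differs from scan recommendation %d",
                           config.network.power, scan.recommended)
        network = build_network(disc_expr, config.network)
        partition = detect_communities(network, config.network)
        eg0 = eigengene_set(disc_expr, partition)
        partition = merge_similar(partition, eg0.eigengenes,
                                  config.network.merge_cut_height, expr=disc_expr)
        scan.table.to_csv(d / "soft_threshold_scan.csv", index=False)
        cio.write_partition(partition, d / "partition.tsv")
        cio.write_edge_list(network, d / "edges.tsv", min_tom=config.edge_export_min_tom)
        cio.write_graphml(network, d / "network.graphml",
                          min_tom=config.edge_export_min_tom)
        summary["stages"][stage] = _provenance(stage, config, d, {
            "power": config.network.power,
            "recommended_power": scan.recommended,
            "n_genes": int(len(network.genes)),
            "communities_detected": len(partition.communities),
            "community_sizes": {int(c): int((partition.labels == c).sum())
                                for c in partition.communities}})

        # ---- validate -----------------------------------------------------
        stage = "validate"
        d = _stage_dir(stage)
        val_exprs = {n: expr_cohorts[n] for n in val_names}
        reports = []
        if val_exprs:
            edge_report, network = revalidate_edges(
                network, partition, val_exprs, alpha=config.edge_alpha,
                require_all_cohorts=config.require_all_cohorts)
            edge_report.to_frame(network, min_tom=config.edge_export_min_tom).to_csv(
                d / "edge_validation.tsv", sep="\t", index=False)
            ss = stage_seed(config.seed, stage)
            for i, (name, expr) in enumerate(val_exprs.items()):
                rep = preservation_z(
                    partition, disc_expr, expr,
                    n_permutations=config.n_permutations,
                    seed=int(ss.generate_state(1)[0]) + i,
                    config=config.network, cohort_name=name)
                rep.table.to_csv(d / f"preservation_{name}.csv")
                reports.append(rep)
            partition, retain_summary = retain_modules(partition, reports,
                                                       config.z_threshold)
            retain_summary.to_csv(d / "retention.csv")
            edge_stats = {"overall_confirmation_rate": edge_report.overall_rate}
        else:
            retain_summary = pd.DataFrame()
            edge_stats = {}
        cio.write_partition(partition, d / "partition_retained.tsv")
        cio.write_edge_list(network, d / "edges_pruned.tsv",
                            min_tom=config.edge_export_min_tom)
        summary["stages"][stage] = _provenance(stage, config, d, {
            **edge_stats,
            "communities_retained": len(partition.communities)})

        # ---- associate ----------------------------------------------------
        stage = "associate"
        d = _stage_dir(stage)
        eigs = eigengene_set(disc_expr, partition)
        disc_ann = annotations.loc[eigs.eigengenes.columns] if len(eigs.communities) else annotations.iloc[:0]
        if len(eigs.communities):
            scope = (disc_ann["group"] == "patient").to_numpy() if "group" in disc_ann else None
            assoc = association_table(eigs, disc_ann, config.traits,
                                      trait_scope=scope)
            eigs.eigengenes.to_csv(d / "eigengenes.tsv", sep="\t")
            assoc.to_csv(d / "associations.csv")
        else:
            assoc = pd.DataFrame()
            (d / "eigengenes.tsv").write_text("")
            (d / "associations.csv").write_text("")
        summary["stages"][stage] = _provenance(stage, config, d, {
            "communities": len(eigs.communities),
            "variance_explained": {int(k): float(v)
                                   for k, v in eigs.variance_explained.items()}})

        # ---- enrich -------------------------------------------------------
        stage = "enrich"
        d = _stage_dir(stage)
        if config.geneset_gmt:
            collection = cio.read_gmt(config.geneset_gmt)
        elif truth is not None:
            rng = np.random.default_rng(stage_seed(config.seed, stage))
            collection = _default_genesets(truth, rng)
            cio.write_gmt(collection, d / "genesets.gmt")
        else:
            collection = None
        if collection is not None and len(partition.communities):
            universe = set(partition.labels.index[partition.labels != 0])
            enr = enrichment_table(partition, collection, universe,
                                   sided=config.enrichment_sided)
            enr.to_csv(d / "enrichment.csv", index=False)
        else:
            enr = pd.DataFrame()
            (d / "enrichment.csv").write_text("")
        summary["stages"][stage] = _provenance(stage, config, d, {
            "n_sets": len(collection.sets) if collection else 0})

        # ---- survival -----------------------------------------------------
        stage = "survival"
        d = _stage_dir(stage)
        surv_cols = {"time", "event"} <= set(annotations.columns)
        if surv_cols and len(eigs.communities):
            surv = annotations.loc[eigs.eigengenes.columns, ["time", "event"]].dropna()
            eig_surv = eigengene_set(
                ExpressionMatrix(values=disc_expr.values[surv.index],
                                 unit=disc_expr.unit, cohort="discovery"),
                partition)
            prog = prognosis_scan(eig_surv, surv)
            prog.to_csv(d / "prognosis.csv", index=False)
            for c in eig_surv.communities:
                coding = tercile_split(eig_surv.get(c).to_numpy())
                km_rows = []
                for terc in (0, 1, 2):
                    mask = coding.labels == terc
                    if mask.sum() == 0 or surv["event"].to_numpy()[mask].sum() == 0:
                        continue
                    km = km_curve(surv["time"].to_numpy()[mask],
                                  surv["event"].to_numpy()[mask])
                    km["tercile"] = terc
                    km["community"] = c
                    km_rows.append(km)
                if km_rows:
                    pd.concat(km_rows).to_csv(d / f"km_community_{c}.tsv",
                                              sep="\t", index=False)
            if "death_class" in annotations.columns:
                dc = annotations.loc[eig_surv.eigengenes.columns, "death_class"]
                deathclass_anova(eig_surv, dc.to_numpy()).to_csv(d / "deathclass_anova.csv")
        else:
            prog = pd.DataFrame()
            (d / "prognosis.csv").write_text("")
        summary["stages"][stage] = _provenance(stage, config, d, {
            "n_fits": int(len(prog))})

        # ---- match --------------------------------------------------------
        stage = "match"
        d = _stage_dir(stage)
        covar_cols = ["age", "sex", "bmi", "diabetes"]
        have_cov = set(covar_cols) <= set(annotations.columns)
        pool_names = [n for n in val_names
                      if isinstance(cohorts_raw[n], CountMatrix)] or val_names
        if have_cov and pool_names and "group" in annotations.columns:
            pool = pool_names[0]
            disc_samples = expr_cohorts["discovery"].samples
            case_ids = [s for s in disc_samples
                        if annotations.loc[s, "group"] == "patient"]
            ctrl_ids = list(expr_cohorts[pool].samples)
            ids = case_ids + ctrl_ids
            cov = annotations.loc[ids, covar_cols].astype(float)
            lab = pd.Series([1] * len(case_ids) + [0] * len(ctrl_ids), index=ids)
            scores = propensity_scores(cov, lab)
            match = nn_match(scores, lab, caliper=config.caliper, covariates=cov)
            match.pairs.to_csv(d / "matched_pairs.csv", index=False)
            cio.write_json({
                "caliper": match.caliper,
                "n_matched": int(len(match.pairs)),
                "unmatched_cases": [str(s) for s in match.unmatched_cases],
                "smd_before": match.smd_before.to_dict(),
                "smd_after": match.smd_after.to_dict(),
            }, d / "match_diagnostics.json")
            # batch-adjusted group contrast on matched samples
            matched_ctrl = list(match.pairs["control"])
            shared = disc_expr.genes.intersection(expr_cohorts[pool].genes)
            if len(match.pairs) >= 3 and len(shared) >= 10 and len(eigs.communities):
                combined = pd.concat(
                    [disc_expr.values.loc[shared, case_ids],
                     expr_cohorts[pool].values.loc[shared, matched_ctrl]], axis=1)
                batches = ["discovery"] * len(case_ids) + [pool] * len(matched_ctrl)
                adj = batch_adjust(
                    ExpressionMatrix(values=combined, unit="log2CPM"), batches)
                sub_part_labels = partition.labels.reindex(shared).fillna(0).astype(int)
                from .network import ModulePartition
                sub_part = ModulePartition(labels=sub_part_labels)
                eg_m = eigengene_set(adj, sub_part)
                rows = []
                glab = np.array(["patient"] * len(case_ids) + ["control"] * len(matched_ctrl))
                for c in eg_m.communities:
                    w = group_difference(eg_m.get(c).to_numpy(), glab)
                    rows.append({"community": c, "welch_t": w.t, "welch_p": w.p,
                                 "smd": w.smd})
                pd.DataFrame(rows).to_csv(d / "matched_group_contrast.csv", index=False)
            n_matched = int(len(match.pairs))
        else:
            n_matched = 0
        summary["stages"][stage] = _provenance(stage, config, d, {
            "n_matched": n_matched})

    except Exception as err:  # noqa: BLE001 - annotate with failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    cio.write_json(summary, run_dir / "summary.json")
    return PipelineResult(run_dir=run_dir, summary=summary)
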