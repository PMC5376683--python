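"""End-to-end pipeline: simulate/read -> QC -> transforms -> clustering ->
summaries -> bimodal stratification -> differentiation model -> classifier.

A single YAML config drives every stage; each run writes its artifacts plus a
manifest (config echo, seeds, per-file SHA-256 digests) so that a rerun with
the same config and seed is bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import diffmodel as dm
from . import preprocess as pp
from . import stats as st
from . import structure as sd
from .panel import load_default_panel, read_cq_plate, read_panel, write_cq_plate, write_matrix
from .simulate import (
    GeneratorConfig,
    generate_patient_cohort,
    generate_reference,
    truth_metrics,
)

logger = logging.getLogger("scfib")


@dataclass
class PipelineConfig:
    """Run-level settings; see docs/methods.md for parameter rationale."""

    out_dir: str = "scfib_run"
    seed: int = 0
    reference_plate: str | None = None  # path; None -> simulate
    patient_plate: str | None = None  # path; None -> simulate
    panel_path: str | None = None  # None -> packaged default panel
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    n_subgroups: int = 5
    linkage: str = "average"
    som_grid: tuple = (3, 2)
    som_iterations: int = 5000
    bimodal_gene: str = "ACTA2"
    classifier_n_pcs: int = 3
    marker_rules: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        pre = pp.PreprocessConfig(**raw.pop("preprocess", {}))
        if "som_grid" in raw:
            raw["som_grid"] = tuple(raw["som_grid"])
        return cls(preprocess=pre, **raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_echo(config), "stages": [], "outputs": {}}
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise PipelineError(name, exc) from exc
            manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 3)})
            return result

        return wrap

    panel = stage("panel")(
        lambda: read_panel(config.panel_path) if config.panel_path else load_default_panel()
    )

    def _load_reference():
        if config.reference_plate:
            return read_cq_plate(config.reference_plate, panel), None
        plate, truth = generate_reference(GeneratorConfig(panel=panel), seed=config.seed)
        write_cq_plate(plate, out / "reference_plate.tsv")
        truth.cells.to_csv(out / "reference_truth.tsv", sep="\t")
        return plate, truth

    plate, truth = stage("read_reference")(_load_reference)

    def _preprocess():
        rq = pp.cq_to_rq(plate, config.preprocess)
        gated, qc = pp.qc_gapdh_gate(rq, config.preprocess)
        (out / "qc_report.json").write_text(json.dumps(qc, indent=1), encoding="utf-8")
        log2u = pp.to_log2(gated, impute=False, config=config.preprocess)
        log2i = pp.to_log2(gated, impute=True, config=config.preprocess)
        write_matrix(log2i, out / "reference_log2_imputed.tsv")
        return qc, log2u, log2i

    qc, log2u, log2i = stage("preprocess")(_preprocess)

    def _structure():
        cell_corr = sd.spearman_matrix(log2i, axis="cell")
        gene_corr = sd.spearman_matrix(log2i, axis="gene")
        _write(cell_corr.rho, out / "cell_correlation.tsv")
        _write(gene_corr.rho, out / "gene_correlation.tsv")
        subgroups = sd.hier_cluster(cell_corr, k=config.n_subgroups, linkage_method=config.linkage)
        mixed = _find_mixed_subgroup(subgroups, log2i.cells)
        if mixed is not None:
            subgroups = sd.split_mixed_cluster(subgroups, log2i.cells, mixed)
        subgroups.labels.to_frame().to_csv(out / "subgroups.tsv", sep="\t")
        bygene = pp.autoscale_by_gene(log2i)
        pca_model, scores = sd.fit_pca(bygene, n_components=2)
        _write(scores, out / "pca_scores.tsv")
        _write(pca_model.loadings, out / "pca_loadings.tsv")
        bycell = pp.autoscale_by_cell(log2i)
        som = sd.fit_som(bycell, grid=config.som_grid, seed=config.seed,
                         n_iter=config.som_iterations)
        som.labels.to_frame().to_csv(out / "som_units.tsv", sep="\t")
        return subgroups, bycell

    subgroups, bycell = stage("structure")(_structure)

    def _stats():
        summary = st.summarize_groups(log2u, subgroups)
        _write(summary.reset_index(), out / "subgroup_summary.tsv", index=False)
        by_class = st.summarize_groups(log2u, "cell_class")
        _write(by_class.reset_index(), out / "class_summary.tsv", index=False)
        activated = log2u.subset_cells(
            log2u.cells.index[log2u.cells["cell_class"].isin(["expCAF", "CAF"])]
        )
        fit = st.fit_bimodal(
            activated.values[config.bimodal_gene][
                activated.detected[config.bimodal_gene]
            ].to_numpy(),
            seed=config.seed,
        )
        strat = st.stratify_by_gene(activated, config.bimodal_gene, fit) if fit.k == 2 else None
        return summary, fit, strat

    summary, bimodal_fit, strat = stage("stats")(_stats)

    def _diffmodel():
        conditions = _subgroup_conditions(subgroups, log2i.cells)
        states = list(subgroups.labels.unique())
        profile = dm.pseudotemporal_profile(summary, states)
        model = dm.order_states(
            dm.label_states(profile, panel, conditions, rules=config.marker_rules)
        )
        _write(model.profile.score, out / "pseudotemporal_scores.tsv")
        gene_clusters = dm.cluster_profiles(model.profile)
        _write(gene_clusters, out / "gene_clusters.tsv")
        doc = {"states": [str(s) for s in model.states],
               "labels": {str(k): v for k, v in model.labels.items()},
               "order": model.label_order()}
        (out / "state_model.json").write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return model

    model = stage("differentiation_model")(_diffmodel)

    def _classifier():
        space = cls.fit_reference(bycell, subgroups, model, n_pcs=config.classifier_n_pcs)
        cls.save_reference(space, out / "reference_space.json")
        resub = cls.classify_cells(space, bycell)
        _write(resub.assignments, out / "reference_classification.tsv")
        manifest["resubstitution_accuracy"] = _resubstitution_accuracy(resub, subgroups, model)
        if config.patient_plate or truth is not None:
            if config.patient_plate:
                pplate = read_cq_plate(config.patient_plate, panel)
            else:
                pplate, ptruth = generate_patient_cohort(seed=config.seed + 1)
                write_cq_plate(pplate, out / "patient_plate.tsv")
                ptruth.cells.to_csv(out / "patient_truth.tsv", sep="\t")
            prq = pp.cq_to_rq(pplate, config.preprocess)
            pgated, pqc = pp.qc_gapdh_gate(prq, config.preprocess)
            plog2 = pp.to_log2(pgated, impute=True, config=config.preprocess)
            pcells = pp.autoscale_by_cell(plog2)
            result = cls.classify_cells(space, pcells)
            _write(result.assignments, out / "patient_classification.tsv")
            _write(cls.cohort_report(result), out / "patient_cohort_report.tsv", index=False)
        return space

    stage("classifier")(_classifier)

    if truth is not None:
        gated_truth = truth.cells.loc[subgroups.labels.index]
        metrics = truth_metrics(gated_truth["cluster"],
                                _premerge_labels(subgroups))
        manifest["subgroup_ari"] = metrics["ari"]

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _digest(p)
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo = dict(vars(config))
    echo["preprocess"] = vars(config.preprocess)
    echo["som_grid"] = list(config.som_grid)
    return echo


def _find_mixed_subgroup(subgroups, cells: pd.DataFrame):
    """The mixed cluster is the subgroup containing both conditions (if any)."""
    from .panel import CLASS_CONDITION

    for sg in subgroups.labels.unique():
        members = subgroups.members(sg)
        conds = {CLASS_CONDITION.get(c, c) for c in cells.loc[members, "cell_class"]}
        if len(conds) > 1:
            return sg
    return None


def _premerge_labels(subgroups) -> pd.Series:
    """Undo the manual mixed-cluster split for comparison with cluster truth."""
    return subgroups.labels.astype(str).str.replace(r"/.*$", "", regex=True)


def _subgroup_conditions(subgroups, cells: pd.DataFrame) -> dict:
    from .panel import CLASS_CONDITION

    conditions = {}
    for sg in subgroups.labels.unique():
        members = subgroups.members(sg)
        conds = cells.loc[members, "cell_class"].map(lambda c: CLASS_CONDITION.get(c, c))
        conditions[sg] = conds.mode().iloc[0]
    return conditions


def _resubstitution_accuracy(result, subgroups, model) -> float:
    state_of_cell = subgroups.labels.map(model.labels)
    assigned = result.assignments["assigned_state"]
    return float((state_of_cell.reindex(assigned.index) == assigned).mean())
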