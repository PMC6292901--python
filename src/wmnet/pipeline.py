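"""End-to-end orchestration: simulate -> behaviour -> GLM -> networks ->
connectivity -> metrics, under one seeded configuration.

Every stage draws its randomness from a sub-stream derived from the
master seed, the stage name and the subject index, so partial re-runs
and full runs agree.  Stage outputs are written with JSON sidecars and
the final report collects the quantities the analysis is about: demand
collinearity (VIF), network recovery, within/between connectivity by
level, segregation and reconfiguration statistics, difficulty trends
and the reconfiguration-Criterion correlations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as behavior_stats
from . import connectivity as conn
from . import glm as glm_mod
from . import metrics as metrics_mod
from . import networks as networks_mod
from .simulate import Cohort, CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = logging.getLogger("wmnet")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Master configuration for a full pipeline run."""

    master_seed: int = 0
    outdir: str = "wmnet_out"
    fraction: float = 0.05
    hrf_peak_delay: float = 6.0
    fit_behavior_models: bool = True
    write_cohort: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = {k: v for k, v in d["cohort"].items()
                      if not isinstance(v, dict)}
        return d


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s ...", name)
            try:
                return fn(*a, **kw)
            except Exception as err:  # noqa: BLE001 - re-tagged
                raise PipelineError(name, err) from err
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig) -> Cohort:
    return generate_cohort(config.cohort, master_seed=config.master_seed)


@_stage("behavior")
def _behavior(cohort: Cohort) -> dict:
    table = cohort.trial_table
    acc = behavior_stats.fit_accuracy_model(table)
    rt = behavior_stats.fit_rt_model(table)
    diag = behavior_stats.rt_residual_diagnostics(table)
    return {"accuracy": acc.to_dict(), "rt": rt.to_dict(),
            "rt_diagnostics": diag}


@_stage("glm")
def _glm(config: PipelineConfig, cohort: Cohort) -> dict:
    hrf = glm_mod.HRFModel(peak_delay=config.hrf_peak_delay)
    betas = {"set_size": [], "steps": []}
    vifs = []
    for sub in cohort.subjects:
        fits, designs = [], []
        for run, entry in sub.bundle.items():
            t_run = sub.trials[sub.trials["run"] == run]
            design = glm_mod.build_design(t_run, hrf,
                                          confounds=entry["confounds"])
            designs.append(design)
            fits.append(glm_mod.fit_glm(entry["signal"], design))
        combined = glm_mod.combine_runs(fits)
        for effect, col in (("set_size", "delay_x_set_size"),
                            ("steps", "delay_x_steps")):
            sel = combined[combined["column"] == col].sort_values("roi")
            betas[effect].append(sel["beta"].to_numpy())
        vifs.append(glm_mod.average_vif(designs))
    maps = {e: glm_mod.group_parametric_map(np.array(b))
            for e, b in betas.items()}
    pmap = pd.DataFrame({
        "roi": maps["set_size"]["roi"],
        "z_set_size": maps["set_size"]["z"],
        "z_steps": maps["steps"]["z"]})
    vif = pd.concat(vifs, axis=1).mean(axis=1)
    return {"parametric_map": pmap, "vif": vif.to_dict()}


@_stage("networks")
def _networks(config: PipelineConfig, cohort: Cohort, pmap: pd.DataFrame) -> dict:
    partition = networks_mod.select_top_nodes(pmap, config.fraction)
    truth = cohort.truth
    jac_m = _jaccard(partition.maintenance_nodes, truth.maintenance_nodes)
    jac_n = _jaccard(partition.manipulation_nodes, truth.manipulation_nodes)
    out = {"partition": partition,
           "jaccard_maintenance": jac_m, "jaccard_manipulation": jac_n}
    fa_mats = [s.fa for s in cohort.subjects if s.fa is not None]
    if fa_mats:
        # FA matrices are indexed in ground-truth node order; validate
        # the truth communities' structural footprint
        truth_part = networks_mod.NetworkPartition(
            tuple(truth.maintenance_nodes), tuple(truth.manipulation_nodes),
            config.fraction)
        out["structural"] = networks_mod.validate_structure(fa_mats, truth_part)
    return out


def _jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


@_stage("connectivity")
def _connectivity(config: PipelineConfig, cohort: Cohort,
                  partition: networks_mod.NetworkPartition) -> dict:
    hrf = glm_mod.HRFModel(peak_delay=config.hrf_peak_delay)
    tensors = {}
    for sub in cohort.subjects:
        tensors[sub.spec.subject_id] = conn.condition_tensor(
            sub.bundle, partition, sub.trials, hrf)
    return {"tensors": tensors}


@_stage("metrics")
def _metrics(cohort: Cohort, tensors: dict,
             partition: networks_mod.NetworkPartition) -> dict:
    table = metrics_mod.metrics_table(tensors, partition)
    trends = {}
    for demand in ("set_size", "steps"):
        sub = table[table["demand"] == demand]
        for col in ("segregation_maintenance", "segregation_manipulation",
                    "z_between"):
            t = sub[["subject", "level", col]].rename(columns={col: "value"})
            trends[f"{demand}:{col}"] = metrics_mod.difficulty_trend(t)
    criterion = {s.spec.subject_id: s.spec.criterion_set_size
                 for s in cohort.subjects}
    recon_rows, correlations = [], {}
    for demand in ("set_size", "steps"):
        per_subset = {}
        for subset in metrics_mod.SUBSETS:
            vals = {}
            for sid, tensor in tensors.items():
                mats = [tensor["matrices"][(demand, lv)] for lv in (1, 2, 3, 4)]
                rec = metrics_mod.reconfiguration(mats, partition, subset)
                vals[sid] = rec.reconfiguration
                recon_rows.append({"subject": sid, "demand": demand,
                                   "subset": subset,
                                   "reconfiguration": rec.reconfiguration})
            per_subset[subset] = vals
            ordered = sorted(vals)
            correlations[f"{demand}:{subset}"] = metrics_mod.behavior_correlation(
                [vals[s] for s in ordered], [criterion[s] for s in ordered])
    r_set = correlations["set_size:between"]["r"]
    r_steps = correlations["steps:between"]["r"]
    fisher = metrics_mod.compare_correlations(
        r_set, r_steps, len(cohort.subjects))
    return {"table": table, "reconfiguration": pd.DataFrame(recon_rows),
            "trends": trends, "criterion_correlations": correlations,
            "fisher_between_set_vs_steps": fisher}


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write a JSON report plus stage TSVs."""
    outdir = Path(config.outdir)
    if not outdir.exists():
        log.info("creating output directory %s", outdir)
        outdir.mkdir(parents=True)
    report: dict = {"config": config.to_dict()}
    cohort = _simulate(config)
    report["cohort"] = {
        "n_subjects": len(cohort.subjects),
        "n_trials": int(len(cohort.trial_table)),
        "set_size_steps_r": float(np.corrcoef(
            cohort.trial_table["abs_set_size"],
            cohort.trial_table["steps"])[0, 1]),
    }
    cohort.trial_table.to_csv(outdir / "trials.tsv", sep="\t", index=False)
    if config.write_cohort:
        cohort.write(outdir / "cohort")
    if config.fit_behavior_models:
        report["behavior"] = _behavior(cohort)
    if cohort.subjects[0].bundle is not None:
        glm_out = _glm(config, cohort)
        glm_out["parametric_map"].to_csv(outdir / "parametric_map.tsv",
                                         sep="\t", index=False)
        report["vif"] = glm_out["vif"]
        net = _networks(config, cohort, glm_out["parametric_map"])
        partition = net["partition"]
        (outdir / "partition.json").write_text(
            json.dumps(partition.to_dict(), indent=1))
        report["networks"] = {
            "n_nodes": partition.size,
            "jaccard_maintenance": net["jaccard_maintenance"],
            "jaccard_manipulation": net["jaccard_manipulation"]}
        if "structural" in net:
            report["networks"]["structural"] = {
                k: v for k, v in net["structural"].items()
                if np.isscalar(v) or isinstance(v, (bool, float, int))}
        tensors = _connectivity(config, cohort, partition)["tensors"]
        met = _metrics(cohort, tensors, partition)
        met["table"].to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        met["reconfiguration"].to_csv(outdir / "reconfiguration.tsv",
                                      sep="\t", index=False)
        level_means = (met["table"][met["table"]["demand"] == "set_size"]
                       .groupby("level")[["z_within_maintenance",
                                          "z_within_manipulation",
                                          "z_between"]].mean())
        report["connectivity"] = {
            "level_means": {str(k): {c: float(v) for c, v in row.items()}
                            for k, row in level_means.iterrows()}}
        report["metrics"] = {
            "trends": met["trends"],
            "criterion_correlations": met["criterion_correlations"],
            "fisher_between_set_vs_steps": met["fisher_between_set_vs_steps"]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, default=_jsonify))
    log.info("report written to %s", outdir / "report.json")
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
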