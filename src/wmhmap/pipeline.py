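"""End-to-end pipeline orchestration with config, seeding and a manifest.

A run configuration (YAML/JSON-compatible dict) names the inputs, model
term lists, estimator/link, incidence threshold, FDR level and mediation
spec. ``run_pipeline`` executes derive -> filter -> load models ->
voxel-wise (joint and marginal) -> summaries -> mediation and writes
versioned CSV/NIfTI/JSON artifacts plus a machine-readable manifest
(seed, config hash, row counts at each exclusion step).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import load_models, mediation, risk_factors, synthetic, voxelwise
from ._design import Term

__all__ = ["default_config", "validate_config", "config_hash", "run_pipeline"]

CONFOUND_TERMS = ["age", "female", "head_size"]
CONFOUND_INTERACTIONS = [("age", "female")]
RISK_TERMS = [
    Term("hypertension"), Term("hypercholesterolemia"), Term("diabetes"),
    Term("smoking_score", "factor"), Term("whr_indicator"),
    Term("apoe_status", "factor"),
]


def default_config() -> dict:
    """A complete synthetic-run configuration with published defaults."""
    return {
        "seed": 0,
        "n_subjects": 800,
        "grid_dims": [12, 12, 6],
        "effect_blobs": [
            {"covariate": "hypertension", "center": [6, 6, 3],
             "radius": 3.0, "amplitude": 0.8},
        ],
        "min_count": 4,
        "alpha_fdr": 0.05,
        "estimator": "BR",
        "link": "probit",
        "marginal_risks": ["hypertension", "whr_indicator"],
        "mediation": {
            "treatment": "log_wmh_load",
            "mediator": "mediator",
            "outcome": "reaction_time",
            "n_boot": 500,
        },
        "copula_corr": {},
    }


def validate_config(config: dict) -> dict:
    """Explicit schema/range validation of a run configuration."""
    cfg = dict(default_config())
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    if not (0.0 < cfg["alpha_fdr"] < 1.0):
        raise ValueError("alpha_fdr must lie in (0, 1)")
    if cfg["min_count"] < 1:
        raise ValueError("min_count must be >= 1")
    if cfg["estimator"] not in ("BR", "ML"):
        raise ValueError("estimator must be BR or ML")
    if cfg["link"] not in ("probit", "logit"):
        raise ValueError("link must be probit or logit")
    if int(cfg["n_subjects"]) < 10:
        raise ValueError("n_subjects too small")
    known_risks = {t.name for t in RISK_TERMS} | {"cvr_score"}
    bad = set(cfg["marginal_risks"]) - known_risks
    if bad:
        raise ValueError(f"unknown marginal risk variables: {sorted(bad)}")
    med = cfg["mediation"]
    for key in ("treatment", "mediator", "outcome"):
        if key not in med:
            raise ValueError(f"mediation config missing {key!r}")
    return cfg


def config_hash(config: dict) -> str:
    """Stable content hash of a configuration."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"),
                       default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _log(records: list, stage: str, **fields):
    rec = {"stage": stage, **fields}
    records.append(rec)
    return rec


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full synthetic-cohort analysis chain; return the manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    manifest = {"seed": cfg["seed"], "config_hash": config_hash(cfg),
                "config": cfg, "stages": log, "outputs": []}

    def emit(name: str, writer):
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    try:
        gen_cfg = synthetic.GeneratorConfig(
            n_subjects=int(cfg["n_subjects"]), seed=int(cfg["seed"]),
            grid_dims=tuple(cfg["grid_dims"]),
            effect_blobs=[synthetic.EffectBlob(
                covariate=b["covariate"], center=tuple(b["center"]),
                radius=float(b["radius"]), amplitude=float(b["amplitude"]))
                for b in cfg["effect_blobs"]],
            copula_corr={tuple(k.split("~")): v
                         for k, v in cfg["copula_corr"].items()},
        )
        table, stack, truth = synthetic.generate_cohort(gen_cfg, with_stack=True)
        _log(log, "simulate", n_subjects=len(table),
             grid_dims=list(stack.grid_dims))

        # re-derive risk variables from the raw fields and filter
        derived = risk_factors.derive_risk_table(table)
        for col in ("wmh_load", "log_wmh_load", "mediator", "reaction_time"):
            derived[col] = table[col].to_numpy()
        required = ["age", "female", "head_size", "cvr_score", "log_wmh_load"]
        filtered, report = risk_factors.complete_case_filter(derived, required)
        _log(log, "derive_filter", **{k: v for k, v in report.items()
                                      if k != "per_column"})
        emit("exclusions.json", lambda p: p.write_text(json.dumps(report, indent=2)))
        emit("covariates.csv", lambda p: filtered.to_csv(p, index=False))

        # subject-level log-load model (confounds + CVR score)
        spec = load_models.ModelSpec(
            response="log_wmh_load",
            terms=CONFOUND_TERMS + ["cvr_score"],
            interactions=CONFOUND_INTERACTIONS,
        )
        fit = load_models.fit_linear_load_model(filtered, spec)
        tab, pr2 = fit.summary_table()
        tab["r2_adj"] = fit.r2_adj
        tab = tab.merge(pr2.rename_axis("term").reset_index(), on="term",
                        how="left")
        emit("load_model.csv", lambda p: tab.to_csv(p, index=False))
        _log(log, "load_model", r2_adj=fit.r2_adj, n=fit.n)

        # voxel-wise maps: joint model (all risks) and marginal models
        keep = filtered.index.to_numpy()
        sub_stack = voxelwise.LesionStack(
            data=stack.data[keep], brain_mask=stack.brain_mask,
            affine=stack.affine,
            subject_ids=[stack.subject_ids[i] for i in keep])
        joint = voxelwise.fit_voxelwise_model(
            sub_stack, filtered, CONFOUND_TERMS + RISK_TERMS,
            CONFOUND_INTERACTIONS, estimator=cfg["estimator"],
            link=cfg["link"], min_count=int(cfg["min_count"]),
            alpha_fdr=float(cfg["alpha_fdr"]))
        summaries = [voxelwise.summarize_significant_voxels(joint)
                     .assign(model="joint")]
        for risk in cfg["marginal_risks"]:
            term = next((t for t in RISK_TERMS if t.name == risk), Term(risk))
            marg = voxelwise.fit_voxelwise_model(
                sub_stack, filtered, CONFOUND_TERMS + [term],
                CONFOUND_INTERACTIONS, estimator=cfg["estimator"],
                link=cfg["link"], min_count=int(cfg["min_count"]),
                alpha_fdr=float(cfg["alpha_fdr"]))
            summaries.append(voxelwise.summarize_significant_voxels(marg)
                             .assign(model=f"marginal:{risk}"))
        summary = pd.concat(summaries, ignore_index=True)
        emit("significant_voxels.csv", lambda p: summary.to_csv(p, index=False))
        _log(log, "voxelwise", n_analysis_voxels=joint.n_analysis_voxels,
             n_nonconverged=joint.n_nonconverged)
        for label in ("z", "q"):
            for term in ("hypertension",):
                if term in joint.maps:
                    emit(f"joint_{term}_{label}.nii.gz",
                         lambda p, t=term, l=label: voxelwise.write_stat_map(
                             joint.maps[t][l], joint.analysis_mask, p,
                             affine=joint.affine))
        prob = voxelwise.empirical_probability_map(sub_stack, sqrt_transform=True)
        emit("sqrt_probability.nii.gz",
             lambda p: voxelwise.write_stat_map(
                 prob, sub_stack.brain_mask, p, affine=sub_stack.affine))

        # mediation: log load -> mediator -> reaction time
        med_cfg = cfg["mediation"]
        med_table, med_report = risk_factors.complete_case_filter(
            filtered, [med_cfg["treatment"], med_cfg["mediator"],
                       med_cfg["outcome"], "education_years"])
        spec_m = mediation.MediationSpec(
            treatment=med_cfg["treatment"], mediator=med_cfg["mediator"],
            outcome=med_cfg["outcome"],
            covariates=CONFOUND_TERMS + ["education_years"],
            interactions=CONFOUND_INTERACTIONS,
            n_boot=int(med_cfg.get("n_boot", 10_000)), seed=int(cfg["seed"]))
        est = mediation.fit_mediation(med_table, spec_m)
        med_tab = mediation.mediation_summary_table(est)
        emit("mediation.csv", lambda p: med_tab.to_csv(p, index=False))
        _log(log, "mediation", acme=est.acme, ade=est.ade, total=est.total,
             n=len(med_table))
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        failed = log[-1]["stage"] if log else "simulate"
        manifest["failed_after_stage"] = failed
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(f"pipeline failed after stage {failed!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
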