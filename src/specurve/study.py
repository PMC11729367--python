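"""End-to-end study runner: simulate -> spectra -> fit -> tests -> multiverse.

Three research-question entry points:

* ``Q1``     - full-cohort group comparison and pain correlation, each with
               the preregistered test and the multiverse inference;
* ``Q2_CBP`` / ``Q2_CWP`` - the diagnosis subgroup against a matched healthy
               subsample (size, age, gender and dataset matched), same pair
               of analyses;
* ``Q3``     - whole-brain region-wise tests with resampling-based FDR.

Every stage logs (stage, n subjects, n excluded, wall time) at INFO and all
outputs are written with a manifest of the config hash and seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from .config import StudyConfig
from .multiverse import (
    PREREGISTERED,
    StudyData,
    build_curve,
    compute_exponent_table,
    enumerate_specifications,
    exponent_matrix_from_study,
    infer_curve,
    run_specification,
    whole_brain_analysis,
)
from .stats import match_controls
from .synthetic import (
    MPFC_REGIONS,
    EffectConfig,
    assign_ground_truth,
    generate_cohort,
    whole_brain_regions,
)

__all__ = ["StudyResult", "simulate_study", "run_study"]

log = logging.getLogger(__name__)

QUESTIONS = ("Q1", "Q2_CBP", "Q2_CWP", "Q3")


@dataclass
class StudyResult:
    question: str
    config: StudyConfig
    cohort: pd.DataFrame
    preregistered: dict = field(default_factory=dict)  # analysis -> SpecResult
    curves: dict = field(default_factory=dict)  # analysis -> SpecificationCurve
    inference: dict = field(default_factory=dict)  # analysis -> CurveInference
    whole_brain: dict = field(default_factory=dict)  # analysis -> DataFrame
    matched_ids: list[str] | None = None


def _stage(name: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s wall=%.2fs %s", name, time.time() - t0, extras)


def simulate_study(config: StudyConfig, whole_brain: bool = False):
    """Generate cohort, ground truth and study data from one config."""
    t0 = time.time()
    n_other = config.n_pain - config.n_cbp - config.n_cwp
    diag = (
        {"CBP": config.n_cbp, "CWP": config.n_cwp, "other": n_other}
        if n_other >= 0 and config.n_pain >= config.n_cbp + config.n_cwp
        else None
    )
    cohort = generate_cohort(
        n_pain=config.n_pain,
        n_healthy=config.n_healthy,
        diagnosis_counts=diag,
        age_range=(config.age_min, config.age_max),
        seed=config.cohort_seed,
    )
    effects = EffectConfig(
        group_d=config.group_d,
        pain_rho=config.pain_rho,
        age_slope=config.age_slope,
        exponent_mean=config.exponent_mean,
        exponent_noise_sd=config.exponent_noise_sd,
    )
    truth = assign_ground_truth(cohort, effects, seed=config.truth_seed)
    regions = (
        whole_brain_regions(config.n_regions_whole_brain)
        if whole_brain
        else MPFC_REGIONS[: config.n_regions]
    )
    if config.data_mode == "timeseries":
        data = StudyData.from_truth_timeseries(
            truth, cohort, regions=regions,
            duration=config.duration_s, sampling_rate=config.sampling_rate_hz,
            seed=config.data_seed,
        )
    else:
        data = StudyData.from_truth_spectra(
            truth, cohort, regions=regions,
            noise_sd=config.spectrum_noise_sd, seed=config.data_seed,
        )
    _stage("simulate", t0, n_subjects=len(cohort), n_regions=len(regions))
    return cohort, truth, data


def _mpfc_analyses(config: StudyConfig, cohort: pd.DataFrame, data: StudyData, result: StudyResult) -> None:
    t0 = time.time()
    specs = enumerate_specifications()
    table = compute_exponent_table(data, cohort, specs)
    _stage("exponents", t0, n_specs=len(specs))
    kw = dict(t_prior_scale=config.t_prior_scale, r_prior_width=config.r_prior_width)
    for analysis in ("group", "correlation"):
        t0 = time.time()
        prereg_j = specs.index(PREREGISTERED)
        result.preregistered[analysis] = run_specification(
            data, cohort, PREREGISTERED, analysis,
            exponents=table[prereg_j],
            residualization=config.residualization, **kw,
        )
        curve = build_curve(
            data, cohort, analysis, exponent_table=table, specs=specs,
            residualization=config.residualization, **kw,
        )
        result.curves[analysis] = curve
        result.inference[analysis] = infer_curve(
            data, cohort, analysis,
            B=config.b_permutations, seed=config.inference_seed,
            exponent_table=table, **kw,
        )
        _stage(f"multiverse[{analysis}]", t0,
               n_used=result.preregistered[analysis].n_used,
               n_excluded=result.preregistered[analysis].n_excluded)


def run_study(config: StudyConfig, question: str, out_dir: str | Path | None = None) -> StudyResult:
    """Run one research question end to end; optionally write a result bundle."""
    if question not in QUESTIONS:
        raise ValueError(f"question must be one of {QUESTIONS}")
    whole_brain = question == "Q3"
    cohort, truth, data = simulate_study(config, whole_brain=whole_brain)
    result = StudyResult(question=question, config=config, cohort=cohort)

    if question in ("Q2_CBP", "Q2_CWP"):
        t0 = time.time()
        diagnosis = "CBP" if question == "Q2_CBP" else "CWP"
        sub_ids = cohort.loc[cohort["diagnosis"] == diagnosis, "subject_id"].tolist()
        matched = match_controls(
            cohort, sub_ids, seed=config.match_seed,
            bf_threshold=config.match_bf_threshold, max_iter=config.match_max_iter,
            prior_scale=config.t_prior_scale,
        )
        result.matched_ids = matched
        cohort = cohort[cohort["subject_id"].isin(set(sub_ids) | set(matched))].reset_index(
            drop=True
        )
        _stage("match_controls", t0, n_subgroup=len(sub_ids), n_matched=len(matched))

    if question == "Q3":
        t0 = time.time()
        exponents = exponent_matrix_from_study(data, cohort)
        for analysis in ("group", "correlation"):
            result.whole_brain[analysis] = whole_brain_analysis(
                exponents, cohort, analysis, B_fdr=config.b_fdr, seed=config.fdr_seed
            )
        _stage("whole_brain", t0, n_regions=exponents.shape[1])
    else:
        _mpfc_analyses(config, cohort, data, result)

    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: StudyResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_cohort(result.cohort, out / "cohort.csv")
    for analysis, curve in result.curves.items():
        sio.write_curve(curve.to_frame(), out / f"curve_{analysis}.csv")
    inference = {a: inf.to_dict() for a, inf in result.inference.items()}
    for analysis, res in result.preregistered.items():
        inference.setdefault("preregistered", {})[analysis] = {
            "effect": res.effect.value,
            "bf10": res.bayes.bf10,
            "p": res.freq_p,
            "z": res.z,
            "n_used": res.n_used,
            "n_excluded": res.n_excluded,
        }
    if inference:
        sio.write_inference(inference, out / "inference.json")
    for analysis, frame in result.whole_brain.items():
        frame.to_csv(out / f"whole_brain_{analysis}.csv", index=False, float_format="%.12g")
    cfg = result.config.to_dict()
    seeds = {k: v for k, v in cfg.items() if k.endswith("seed")}
    sio.write_manifest(out / "manifest.json", cfg, seeds)
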