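"""Specification enumeration, per-specification analysis, the specification
curve, permutation-based curve inference, and whole-brain testing.

A specification is one combination of five analytic choices (epoch length,
taper, PSD-vs-parameter averaging, fit range, knee); the full grid has
2*2*2*3*2 = 48 members, among them the preregistered one (2 s, dpss,
average PSD, 2-40 Hz, no knee).  For each specification the pipeline
computes one aperiodic exponent per subject, drops non-converged subjects,
age-residualizes, and runs the group (Cohen's d + Bayesian t-test) or
correlation (Pearson r + Bayesian correlation) analysis.  Curve inference
compares the observed curve to B null curves obtained by shuffling group
labels or pain ratings; because the spectral stage is label-independent,
exponents are computed once per (subject, specification) and reused across
permutations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import specparam
from . import stats as ss
from .spectral import compute_psd, segment_epochs
from .synthetic import MPFC_REGIONS, GroundTruth, synthesize_spectrum, synthesize_timeseries

__all__ = [
    "Specification",
    "PREREGISTERED",
    "SpecResult",
    "SpecificationCurve",
    "CurveInference",
    "StudyData",
    "enumerate_specifications",
    "compute_exponent_table",
    "run_specification",
    "build_curve",
    "permuted_cohort",
    "infer_curve",
    "whole_brain_analysis",
]

log = logging.getLogger(__name__)

FIT_RANGES: tuple[tuple[float, float], ...] = ((2.0, 40.0), (40.0, 60.0), (1.0, 100.0))


@dataclass(frozen=True)
class Specification:
    """One combination of the five analytic choices."""

    epoch_length: float  # s, in {2, 5}
    taper: str  # 'dpss' | 'hanning'
    avg_psd: bool  # True: average spectra then fit once; False: average exponents
    fit_range: tuple[float, float]  # Hz
    knee: bool

    @property
    def mode(self) -> str:
        return "knee" if self.knee else "fixed"

    def label(self) -> str:
        lo, hi = self.fit_range
        return (
            f"{self.epoch_length:g}s/{self.taper}/"
            f"avg={'yes' if self.avg_psd else 'no'}/{lo:g}-{hi:g}Hz/"
            f"knee={'yes' if self.knee else 'no'}"
        )


PREREGISTERED = Specification(
    epoch_length=2.0, taper="dpss", avg_psd=True, fit_range=(2.0, 40.0), knee=False
)


def enumerate_specifications() -> list[Specification]:
    """All 48 specifications, ordered by the nested loop
    (epoch length, taper, averaging, fit range, knee) with the tabulated
    option order (2 s before 5 s, dpss before hanning, average-PSD before
    average-parameters, 2-40 / 40-60 / 1-100 Hz, no knee before knee)."""
    return [
        Specification(L, taper, avg, rng, knee)
        for L, taper, avg, rng, knee in itertools.product(
            (2.0, 5.0), ("dpss", "hanning"), (True, False), FIT_RANGES, (False, True)
        )
    ]


@dataclass(frozen=True)
class SpecResult:
    specification: Specification
    effect: ss.EffectSize
    bayes: ss.BayesResult
    freq_p: float
    z: float
    n_used: int
    n_excluded: int


@dataclass
class SpecificationCurve:
    results: list[SpecResult]  # ordered by ascending effect size
    analysis: str  # 'group' | 'correlation'

    @property
    def effects(self) -> np.ndarray:
        return np.array([r.effect.value for r in self.results])

    @property
    def dominant_sign(self) -> int:
        m = float(np.median(self.effects))
        return 1 if m >= 0 else -1  # a median of exactly 0 counts as +1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            s = r.specification
            rows.append(
                {
                    "epoch_length": s.epoch_length,
                    "taper": s.taper,
                    "avg_psd": "yes" if s.avg_psd else "no",
                    "fit_range_lo": s.fit_range[0],
                    "fit_range_hi": s.fit_range[1],
                    "knee": "yes" if s.knee else "no",
                    "effect": r.effect.value,
                    "bf10": r.bayes.bf10,
                    "p": r.freq_p,
                    "z": r.z,
                    "n_used": r.n_used,
                    "n_excluded": r.n_excluded,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CurveInference:
    p_median: float
    p_share: float
    p_aggregate: float
    B: int
    observed_median: float
    observed_share: float
    observed_z: float
    dominant_sign: int

    def to_dict(self) -> dict:
        return {
            "p_median": self.p_median,
            "p_share": self.p_share,
            "p_aggregate": self.p_aggregate,
            "B": self.B,
            "observed_median": self.observed_median,
            "observed_share": self.observed_share,
            "observed_z": self.observed_z,
            "dominant_sign": self.dominant_sign,
        }


# --------------------------------------------------------------- study data


class StudyData:
    """Per-subject, per-region source data for the pipeline.

    Two storage modes: precomputed spectra on the per-epoch-length grids
    (the fast synthesis path) or continuous time series that are epoched
    and taper-transformed on demand (with caching keyed by subject, epoch
    length and taper).
    """

    def __init__(self) -> None:
        self.mode: str = "spectra"
        self.regions: tuple[str, ...] = MPFC_REGIONS
        self.subjects: list[str] = []
        self._grids: dict[float, np.ndarray] = {}
        self._spectra: dict[tuple[str, str, float], np.ndarray] = {}
        self._signals: dict[tuple[str, str], np.ndarray] = {}
        self._fs: float = 250.0
        self._psd_cache: dict[tuple[str, str, float, str], tuple[np.ndarray, np.ndarray]] = {}

    # -- constructors

    @classmethod
    def from_truth_spectra(
        cls,
        truth: GroundTruth,
        cohort: pd.DataFrame,
        regions: tuple[str, ...] = MPFC_REGIONS,
        epoch_lengths: tuple[float, ...] = (2.0, 5.0),
        fmax: float = 100.0,
        noise_sd: float = 0.05,
        seed: int = 0,
        grid_resolution: dict[float, float] | None = None,
    ) -> "StudyData":
        """Direct-spectrum synthesis on per-epoch-length grids.

        By default each epoch length L gets its native 1/L Hz grid;
        ``grid_resolution`` overrides the spacing per epoch length (used by
        scaled-down simulation studies to trade resolution for speed while
        keeping the epoch-length dimension's data streams distinct).
        """
        sd = cls()
        sd.mode = "spectra"
        sd.regions = tuple(regions)
        sd.subjects = list(cohort["subject_id"])
        for L in epoch_lengths:
            df = 1.0 / L if grid_resolution is None else grid_resolution[L]
            grid = np.arange(1.0, fmax + df / 2.0, df)
            sd._grids[L] = grid
            for sid in sd.subjects:
                for reg in sd.regions:
                    sd._spectra[(sid, reg, L)] = synthesize_spectrum(
                        truth, sid, f"{reg}@{L:g}s", grid, noise_sd=noise_sd, seed=seed
                    )
        return sd

    @classmethod
    def from_truth_timeseries(
        cls,
        truth: GroundTruth,
        cohort: pd.DataFrame,
        regions: tuple[str, ...] = MPFC_REGIONS,
        duration: float = 300.0,
        sampling_rate: float = 250.0,
        seed: int = 0,
    ) -> "StudyData":
        sd = cls()
        sd.mode = "timeseries"
        sd.regions = tuple(regions)
        sd.subjects = list(cohort["subject_id"])
        sd._fs = sampling_rate
        for sid in sd.subjects:
            for reg in sd.regions:
                sd._signals[(sid, reg)] = synthesize_timeseries(
                    truth, sid, reg, duration=duration, sampling_rate=sampling_rate, seed=seed
                )
        return sd

    @classmethod
    def from_spectra_frame(cls, frame: pd.DataFrame, epoch_length: float) -> "StudyData":
        """Build from a long-format table (subject_id, region_label, frequency_hz, power)."""
        sd = cls()
        sd.mode = "spectra"
        sd.subjects = list(dict.fromkeys(frame["subject_id"]))
        sd.regions = tuple(dict.fromkeys(frame["region_label"]))
        grid = None
        for (sid, reg), g in frame.groupby(["subject_id", "region_label"], sort=False):
            f = g["frequency_hz"].to_numpy(dtype=float)
            if grid is None:
                grid = f
            elif not np.array_equal(f, grid):
                raise ValueError("all spectra must share one frequency grid")
            sd._spectra[(sid, reg, epoch_length)] = g["power"].to_numpy(dtype=float)
        sd._grids[epoch_length] = grid
        return sd

    # -- access

    def epoch_lengths(self) -> tuple[float, ...]:
        if self.mode == "spectra":
            return tuple(sorted(self._grids))
        return (2.0, 5.0)

    def get_region_spectra(
        self, subject_id: str, spec: Specification
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        if self.mode == "spectra":
            if spec.epoch_length not in self._grids:
                available = self.epoch_lengths()
                L = available[0] if len(available) == 1 else spec.epoch_length
                if L not in self._grids:
                    raise KeyError(f"no spectra for epoch length {spec.epoch_length}")
            else:
                L = spec.epoch_length
            grid = self._grids[L]
            return [(grid, self._spectra[(subject_id, reg, L)]) for reg in self.regions]
        out = []
        for reg in self.regions:
            key = (subject_id, reg, spec.epoch_length, spec.taper)
            if key not in self._psd_cache:
                epochs = segment_epochs(
                    self._signals[(subject_id, reg)], self._fs, spec.epoch_length, 0.5
                )
                self._psd_cache[key] = compute_psd(epochs, taper=spec.taper)
            out.append(self._psd_cache[key])
        return out

    def exponent_cache_key(self, spec: Specification) -> tuple:
        """Specs that cannot differ on this data share one cache entry.

        On stored spectra the taper choice has no effect (the spectra were
        never taper-estimated), so it is dropped from the key.
        """
        if self.mode == "spectra":
            return (spec.epoch_length, spec.avg_psd, spec.fit_range, spec.knee)
        return (spec.epoch_length, spec.taper, spec.avg_psd, spec.fit_range, spec.knee)


# --------------------------------------------------- exponent table pipeline


def compute_exponent_table(
    study: StudyData,
    cohort: pd.DataFrame,
    specs: list[Specification] | None = None,
    **fit_settings,
) -> pd.DataFrame:
    """One aperiodic exponent per (subject, specification); NaN = non-converged.

    Exponents are computed once per distinct data-level configuration and
    reused (the spectral stage does not depend on group labels or pain
    ratings, so permutation inference can share this table).
    """
    specs = specs if specs is not None else enumerate_specifications()
    subjects = [s for s in cohort["subject_id"] if s in set(study.subjects)]
    cache: dict[tuple, np.ndarray] = {}
    cols = {}
    for j, spec in enumerate(specs):
        key = study.exponent_cache_key(spec)
        if key not in cache:
            vals = np.empty(len(subjects))
            for i, sid in enumerate(subjects):
                spectra = study.get_region_spectra(sid, spec)
                chi, ok = specparam.exponent_for_subject(
                    spectra,
                    avg_psd=spec.avg_psd,
                    fit_range=spec.fit_range,
                    mode=spec.mode,
                    **fit_settings,
                )
                vals[i] = chi if ok else np.nan
            cache[key] = vals
        cols[j] = cache[key]
    table = pd.DataFrame(cols, index=pd.Index(subjects, name="subject_id"))
    n_nan = int(table.isna().to_numpy().sum())
    log.info(
        "exponent table: %d subjects x %d specs, %d non-converged fits",
        len(subjects), len(specs), n_nan,
    )
    return table


class InsufficientDataError(ValueError):
    pass


def _analyze(
    chi: pd.Series,
    cohort: pd.DataFrame,
    analysis: str,
    t_prior_scale: float = ss.DEFAULT_T_PRIOR_SCALE,
    r_prior_width: float = ss.DEFAULT_R_PRIOR_WIDTH,
    residualization: str = "pooled",
) -> tuple[ss.EffectSize, ss.BayesResult, float, float, int, int]:
    """Age-residualized group or correlation analysis of one exponent vector."""
    info = cohort.set_index("subject_id").loc[chi.index]
    if analysis == "group":
        used = chi.notna()
    elif analysis == "correlation":
        used = chi.notna() & (info["group"] == "pain").to_numpy()
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    n_total = len(chi) if analysis == "group" else int((info["group"] == "pain").sum())
    n_used = int(used.sum())
    n_excluded = n_total - n_used
    if n_used < 4:
        raise InsufficientDataError(f"only {n_used} usable subjects")
    vals = chi[used].to_numpy(dtype=float)
    age = info.loc[used.to_numpy(), "age"].to_numpy(dtype=float)
    if analysis == "group":
        is_pain = (info.loc[used.to_numpy(), "group"] == "pain").to_numpy()
        if residualization == "pooled":
            resid = ss.residualize(vals, age)
        else:
            resid = np.empty_like(vals)
            resid[is_pain] = ss.residualize(vals[is_pain], age[is_pain])
            resid[~is_pain] = ss.residualize(vals[~is_pain], age[~is_pain])
        x, y = resid[is_pain], resid[~is_pain]
        if x.size < 2 or y.size < 2:
            raise InsufficientDataError("a group has fewer than 2 usable subjects")
        effect = ss.cohens_d(x, y)
        t, p = ss.two_sample_test(x, y)
        bayes = ss.BayesResult(
            statistic=t,
            bf10=ss.bf_ttest_from_t(t, x.size, y.size, t_prior_scale),
            n=x.size, n2=y.size, prior_scale=t_prior_scale,
        )
        z = ss.signed_z_from_p(p, effect.value) if p < 1.0 else 0.0
        return effect, bayes, p, z, n_used, n_excluded
    pain_vals = info.loc[used.to_numpy(), "pain_intensity"].to_numpy(dtype=float)
    chi_res = ss.residualize(vals, age)
    pain_res = ss.residualize(pain_vals, age)
    r, p = ss.pearson_test(chi_res, pain_res)
    effect = ss.EffectSize(kind="pearson_r", value=r, n=n_used)
    bayes = ss.BayesResult(
        statistic=r,
        bf10=ss.bf_correlation_from_r(r, n_used, r_prior_width),
        n=n_used, prior_scale=r_prior_width,
    )
    z = ss.signed_z_from_p(p, r) if p < 1.0 else 0.0
    return effect, bayes, p, z, n_used, n_excluded


def run_specification(
    study: StudyData,
    cohort: pd.DataFrame,
    spec: Specification,
    analysis: str,
    exponents: pd.Series | None = None,
    **analyze_kw,
) -> SpecResult:
    """Full pipeline for one specification: spectra -> exponents -> test."""
    if exponents is None:
        exponents = compute_exponent_table(study, cohort, [spec])[0]
    effect, bayes, p, z, n_used, n_excl = _analyze(exponents, cohort, analysis, **analyze_kw)
    return SpecResult(
        specification=spec, effect=effect, bayes=bayes,
        freq_p=p, z=z, n_used=n_used, n_excluded=n_excl,
    )


def build_curve(
    study: StudyData,
    cohort: pd.DataFrame,
    analysis: str,
    exponent_table: pd.DataFrame | None = None,
    specs: list[Specification] | None = None,
    **analyze_kw,
) -> SpecificationCurve:
    """All specifications, ordered by ascending effect size."""
    specs = specs if specs is not None else enumerate_specifications()
    if exponent_table is None:
        exponent_table = compute_exponent_table(study, cohort, specs)
    results = [
        run_specification(study, cohort, spec, analysis, exponents=exponent_table[j], **analyze_kw)
        for j, spec in enumerate(specs)
    ]
    results.sort(key=lambda r: r.effect.value)
    return SpecificationCurve(results=results, analysis=analysis)


# ----------------------------------------------------------- permutation null


def permuted_cohort(
    cohort: pd.DataFrame, analysis: str, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Shuffle group labels (group analysis) or pain ratings among pain
    subjects (correlation analysis); everything else unchanged."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    if analysis == "group":
        out["group"] = rng.permutation(out["group"].to_numpy())
    elif analysis == "correlation":
        pain = (out["group"] == "pain").to_numpy()
        perm = rng.permutation(int(pain.sum()))
        ratings = out.loc[pain, "pain_intensity"].to_numpy()
        out.loc[pain, "pain_intensity"] = ratings[perm]
        if "_pain_latent" in out.columns:
            latent = out.loc[pain, "_pain_latent"].to_numpy()
            out.loc[pain, "_pain_latent"] = latent[perm]
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    return out


class _NullCurveEngine:
    """Fast recomputation of curve statistics under label/rating permutations.

    Exploits that the exponent table is permutation-invariant: per
    specification the age-residualized exponents (group analysis) or the
    exponent/age vectors (correlation) are precomputed, and the Bayesian
    evidence criterion BF10 > 3 is translated once into an equivalent
    threshold on |t| or |r| (BF10 is strictly increasing in the statistic's
    magnitude at fixed n).
    """

    def __init__(
        self,
        exponent_table: pd.DataFrame,
        cohort: pd.DataFrame,
        analysis: str,
        t_prior_scale: float = ss.DEFAULT_T_PRIOR_SCALE,
        r_prior_width: float = ss.DEFAULT_R_PRIOR_WIDTH,
    ) -> None:
        self.analysis = analysis
        info = cohort.set_index("subject_id").loc[exponent_table.index]
        self.is_pain = (info["group"] == "pain").to_numpy()
        age = info["age"].to_numpy(dtype=float)
        self.pain_ratings = info["pain_intensity"].to_numpy(dtype=float)
        self.t_prior_scale = t_prior_scale
        self.r_prior_width = r_prior_width
        self._t_thresholds: dict[tuple[int, int], float] = {}
        self._r_thresholds: dict[int, float] = {}
        self.specs_data = []
        for j in exponent_table.columns:
            chi = exponent_table[j].to_numpy(dtype=float)
            used = np.isfinite(chi)
            if self.analysis == "correlation":
                used = used & self.is_pain
            idx = np.where(used)[0]
            if self.analysis == "group":
                resid = ss.residualize(chi[idx], age[idx])
                self.specs_data.append({"idx": idx, "resid": resid})
            else:
                chi_res = ss.residualize(chi[idx], age[idx])
                a = age[idx]
                ac = a - a.mean()
                self.specs_data.append(
                    {"idx": idx, "chi_res": chi_res, "age_c": ac,
                     "age_ss": float(ac @ ac), "chi_norm": float(np.sqrt(chi_res @ chi_res))}
                )

    # -- evidence thresholds

    def _t_star(self, n1: int, n2: int) -> float:
        key = (n1, n2)
        if key not in self._t_thresholds:
            from scipy.optimize import brentq

            f = lambda t: ss.bf_ttest_from_t(t, n1, n2, self.t_prior_scale) - 3.0
            self._t_thresholds[key] = (
                brentq(f, 0.0, 50.0) if f(50.0) > 0 else math.inf
            )
        return self._t_thresholds[key]

    def _r_star(self, n: int) -> float:
        if n not in self._r_thresholds:
            from scipy.optimize import brentq

            f = lambda r: ss.bf_correlation_from_r(r, n, self.r_prior_width) - 3.0
            self._r_thresholds[n] = brentq(f, 1e-9, 1.0 - 1e-9) if f(1.0 - 1e-9) > 0 else math.inf
        return self._r_thresholds[n]

    # -- one curve's statistics

    def curve_stats(
        self, labels_pain: np.ndarray | None = None, ratings: np.ndarray | None = None
    ) -> tuple[float, float, float]:
        """(median effect, evidential share, Stouffer Z) for one labeling.

        ``labels_pain``/``ratings`` are full-length vectors aligned with the
        exponent-table subjects; None means the observed labels/ratings.
        """
        K = len(self.specs_data)
        effects = np.empty(K)
        tstats = np.empty(K)
        dfs = np.empty(K)
        evid = np.zeros(K, dtype=bool)
        if self.analysis == "group":
            lab = self.is_pain if labels_pain is None else labels_pain
            for k, d in enumerate(self.specs_data):
                g = lab[d["idx"]]
                x = d["resid"][g]
                y = d["resid"][~g]
                n1, n2 = x.size, y.size
                sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
                diff = x.mean() - y.mean()
                effects[k] = diff / math.sqrt(sp2)
                t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
                tstats[k] = t
                dfs[k] = n1 + n2 - 2
                evid[k] = abs(t) > self._t_star(n1, n2)
        else:
            rat = self.pain_ratings if ratings is None else ratings
            for k, d in enumerate(self.specs_data):
                y = rat[d["idx"]]
                yc = y - y.mean()
                beta = (d["age_c"] @ yc) / d["age_ss"]
                y_res = yc - beta * d["age_c"]
                denom = d["chi_norm"] * math.sqrt(y_res @ y_res)
                r = float(d["chi_res"] @ y_res) / denom
                n = d["idx"].size
                effects[k] = r
                tstats[k] = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
                dfs[k] = n - 2
                evid[k] = abs(r) > self._r_star(n)
        p = 2.0 * sps.t.sf(np.abs(tstats), dfs)
        p = np.clip(p, 1e-300, 1.0)
        z = np.sign(effects) * sps.norm.isf(p / 2.0)
        median = float(np.median(effects))
        dominant = 1.0 if median >= 0 else -1.0
        share = float(np.mean(evid & (np.sign(effects) == dominant)))
        agg_z = float(np.sum(z) / math.sqrt(K))
        return median, share, agg_z


def infer_curve(
    study: StudyData,
    cohort: pd.DataFrame,
    analysis: str,
    B: int = 500,
    seed: int = 0,
    exponent_table: pd.DataFrame | None = None,
    observed_direction: bool = False,
    **prior_kw,
) -> CurveInference:
    """Permutation inference on the specification curve.

    Builds the observed curve plus B null curves (group labels or pain
    ratings shuffled) and returns add-one permutation p-values for the
    median effect, the share of evidential specifications (BF10 > 3 with
    the curve's dominant sign), and the Stouffer-aggregated Z.

    Each curve's statistics are taken in that curve's own dominant
    direction (so the median and aggregate comparisons are effectively on
    magnitudes), which keeps the permutation test calibrated; with
    ``observed_direction=True`` null curves are instead evaluated in the
    observed curve's direction (a strictly one-sided variant).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if exponent_table is None:
        exponent_table = compute_exponent_table(study, cohort, enumerate_specifications())
    engine = _NullCurveEngine(exponent_table, cohort, analysis, **prior_kw)
    obs_median, obs_share, obs_z = engine.curve_stats()
    s = 1.0 if obs_median >= 0 else -1.0
    rng = np.random.default_rng(seed)
    null_median = np.empty(B)
    null_share = np.empty(B)
    null_z = np.empty(B)
    n_subj = len(exponent_table)
    n_pain_subj = int(engine.is_pain.sum())
    for b in range(B):
        if analysis == "group":
            labels = engine.is_pain[rng.permutation(n_subj)]
            null_median[b], null_share[b], null_z[b] = engine.curve_stats(labels_pain=labels)
        else:
            ratings = engine.pain_ratings.copy()
            pain_idx = np.where(engine.is_pain)[0]
            ratings[pain_idx] = ratings[pain_idx[rng.permutation(n_pain_subj)]]
            null_median[b], null_share[b], null_z[b] = engine.curve_stats(ratings=ratings)
    if observed_direction:
        p_median = (1 + int(np.sum(s * null_median >= s * obs_median))) / (B + 1)
        p_aggr = (1 + int(np.sum(s * null_z >= s * obs_z))) / (B + 1)
    else:
        p_median = (1 + int(np.sum(np.abs(null_median) >= abs(obs_median)))) / (B + 1)
        p_aggr = (1 + int(np.sum(np.abs(null_z) >= abs(obs_z)))) / (B + 1)
    p_share = (1 + int(np.sum(null_share >= obs_share))) / (B + 1)
    return CurveInference(
        p_median=float(p_median),
        p_share=float(p_share),
        p_aggregate=float(p_aggr),
        B=B,
        observed_median=obs_median,
        observed_share=obs_share,
        observed_z=obs_z,
        dominant_sign=int(s),
    )


# ------------------------------------------------------------- whole brain


def _residualize_matrix(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Column-wise simple-OLS residuals of a (n, R) matrix on one covariate."""
    x = covariate - covariate.mean()
    yc = values - values.mean(axis=0, keepdims=True)
    beta = (x @ yc) / (x @ x)
    return yc - np.outer(x, beta)


def _group_p_matrix(resid: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled t-tests of each column between labels True/False."""
    n1 = int(labels.sum())
    n2 = resid.shape[0] - n1
    x = resid[labels]
    y = resid[~labels]
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1)
    vy = y.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2)
    t = (mx - my) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(np.abs(t), n1 + n2 - 2)
    d = (mx - my) / np.sqrt(sp2)
    return d, p


def _corr_p_matrix(resid: np.ndarray, y_res: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson tests of each column against one residualized vector."""
    n = resid.shape[0]
    num = y_res @ resid
    den = np.sqrt((y_res @ y_res) * np.sum(resid**2, axis=0))
    r = num / den
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    return r, p


def whole_brain_analysis(
    exponents: pd.DataFrame,
    cohort: pd.DataFrame,
    analysis: str,
    B_fdr: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Region-wise frequentist tests with resampling-based FDR adjustment.

    ``exponents`` is a (subjects x regions) table of aperiodic exponents
    obtained with the preregistered spectral settings (use
    :func:`exponent_matrix_from_study` to compute one from raw study data).
    Per region the age-residualized two-sided t-test (group) or Pearson test
    (correlation) is computed; the null p-value distribution for the FDR
    adjustment comes from ``B_fdr`` label (or rating) permutations.
    """
    info = cohort.set_index("subject_id").loc[exponents.index]
    age = info["age"].to_numpy(dtype=float)
    is_pain = (info["group"] == "pain").to_numpy()
    rng = np.random.default_rng(seed)
    if analysis == "group":
        resid = _residualize_matrix(exponents.to_numpy(dtype=float), age)
        effect, p_obs = _group_p_matrix(resid, is_pain)
        p_null = np.empty((B_fdr, resid.shape[1]))
        for b in range(B_fdr):
            labels = is_pain[rng.permutation(is_pain.size)]
            _, p_null[b] = _group_p_matrix(resid, labels)
    elif analysis == "correlation":
        vals = exponents.to_numpy(dtype=float)[is_pain]
        a = age[is_pain]
        pain_ratings = info.loc[is_pain, "pain_intensity"].to_numpy(dtype=float)
        resid = _residualize_matrix(vals, a)
        ac = a - a.mean()

        def resid_y(y: np.ndarray) -> np.ndarray:
            yc = y - y.mean()
            return yc - ((ac @ yc) / (ac @ ac)) * ac

        effect, p_obs = _corr_p_matrix(resid, resid_y(pain_ratings))
        p_null = np.empty((B_fdr, resid.shape[1]))
        for b in range(B_fdr):
            y = pain_ratings[rng.permutation(pain_ratings.size)]
            _, p_null[b] = _corr_p_matrix(resid, resid_y(y))
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    p_adj = ss.resampling_fdr(p_obs, p_null)
    return pd.DataFrame(
        {"region_label": list(exponents.columns), "effect": effect, "p": p_obs, "p_adj": p_adj}
    )


def exponent_matrix_from_study(
    study: StudyData,
    cohort: pd.DataFrame,
    spec: Specification = PREREGISTERED,
    **fit_settings,
) -> pd.DataFrame:
    """Subjects x regions exponent matrix under one (default preregistered) spec."""
    subjects = [s for s in cohort["subject_id"] if s in set(study.subjects)]
    mat = np.empty((len(subjects), len(study.regions)))
    for i, sid in enumerate(subjects):
        spectra = study.get_region_spectra(sid, spec)
        for j, (freqs, power) in enumerate(spectra):
            model = specparam.fit_spectrum(
                freqs, power, fit_range=spec.fit_range, mode=spec.mode, **fit_settings
            )
            mat[i, j] = model.aperiodic.exponent if model.converged else np.nan
    return pd.DataFrame(mat, index=pd.Index(subjects, name="subject_id"), columns=study.regions)
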