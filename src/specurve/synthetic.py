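"""Synthetic cohorts and source-level spectra with known ground truth.

This module emulates the structure of a two-group resting-state EEG study of
chronic pain: a cohort of people with chronic pain (with diagnosis subgroups
and 0-10 numeric pain ratings) and healthy controls drawn from three source
datasets, and per-subject, per-region power spectra whose expected shape is
an aperiodic Lorentzian 10**(b - log10(k + F**chi)) plus Gaussian alpha
peaks in log10-power space.

Ground-truth aperiodic exponents carry configurable effects: a standardized
group difference ``group_d``, a partial (age-removed) correlation
``pain_rho`` between exponent and pain intensity, and a linear age trend
``age_slope``.  Every generator is a pure function of its arguments and a
seed, so downstream recovery and calibration can be tested without any
recorded data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike

__all__ = [
    "EffectConfig",
    "GroundTruth",
    "generate_cohort",
    "assign_ground_truth",
    "synthesize_spectrum",
    "synthesize_timeseries",
    "MPFC_REGIONS",
    "whole_brain_regions",
]

# Four opaque labels standing in for the parcels that make up the mPFC.
MPFC_REGIONS: tuple[str, ...] = ("mpfc-1", "mpfc-2", "mpfc-3", "mpfc-4")

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "dataset",
    "diagnosis",
    "pain_intensity",
]

# Per-dataset composition of the emulated study (pain, healthy).
_DATASET_WEIGHTS = {
    "pain": {1: 101, 2: 48, 3: 0},
    "healthy": {1: 88, 2: 0, 3: 27},
}
_FEMALE_FRACTION = {"pain": 98 / 151, "healthy": 74 / 115}


def whole_brain_regions(n_regions: int = 100) -> tuple[str, ...]:
    """Opaque labels for whole-brain mode (no atlas geometry is modeled)."""
    return tuple(f"region-{i:03d}" for i in range(n_regions))


def _child_rng(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-entity generator: seed combined with stable string hashes."""
    keys = [zlib.crc32(t.encode("utf8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def _split_counts(total: int, weights: dict[int, float], rng: np.random.Generator) -> dict[int, int]:
    """Largest-remainder apportionment of `total` across integer-keyed weights."""
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() == 0:
        w = np.ones_like(w)
    exact = total * w / w.sum()
    counts = np.floor(exact).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    return dict(zip(keys, counts.tolist()))


def generate_cohort(
    n_pain: int = 149,
    n_healthy: int = 115,
    diagnosis_counts: dict[str, int] | None = None,
    age_range: tuple[int, int] = (18, 86),
    seed: int = 0,
    pain_mean: float = 5.0,
    pain_sd: float = 1.8,
) -> pd.DataFrame:
    """Generate a cohort table of pain and healthy subjects.

    ``diagnosis_counts`` maps diagnosis labels (CBP, CWP, other) to counts and
    must sum to ``n_pain``; the default mirrors the emulated study
    (80 CBP / 33 CWP / remainder other).  Pain intensity is drawn on a
    continuous 0-10 scale and rounded to integers; the pre-rounding value is
    kept in a private ``_pain_latent`` column (not serialized) so correlation
    targets are defined pre-rounding.
    """
    if n_pain < 0 or n_healthy < 0:
        raise ValueError("counts must be non-negative")
    if diagnosis_counts is None:
        diagnosis_counts = (
            {"CBP": 80, "CWP": 33, "other": n_pain - 113} if n_pain >= 113 else {"other": n_pain}
        )
    if sum(diagnosis_counts.values()) != n_pain or any(
        v < 0 for v in diagnosis_counts.values()
    ):
        raise ValueError(
            f"diagnosis_counts {diagnosis_counts} must be non-negative and sum to n_pain={n_pain}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group, n in (("pain", n_pain), ("healthy", n_healthy)):
        ds_counts = _split_counts(n, _DATASET_WEIGHTS[group], rng)
        datasets = np.repeat(
            [k for k in sorted(ds_counts)], [ds_counts[k] for k in sorted(ds_counts)]
        )
        if group == "pain":
            diagnoses = np.repeat(
                [k for k in sorted(diagnosis_counts)],
                [diagnosis_counts[k] for k in sorted(diagnosis_counts)],
            )
            rng.shuffle(diagnoses)
        else:
            diagnoses = np.array(["none"] * n)
        ages = rng.integers(age_range[0], age_range[1] + 1, size=n)
        genders = np.where(rng.random(n) < _FEMALE_FRACTION[group], "f", "m")
        if group == "pain":
            latent = np.clip(rng.normal(pain_mean, pain_sd, size=n), 0.0, 10.0)
            ratings = np.round(latent).astype(float)
        else:
            latent = np.full(n, np.nan)
            ratings = np.full(n, np.nan)
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "subject_id": f"sub-{idx:03d}",
                    "group": group,
                    "age": int(ages[i]),
                    "gender": genders[i],
                    "dataset": int(datasets[i]),
                    "diagnosis": diagnoses[i],
                    "pain_intensity": ratings[i],
                    "_pain_latent": latent[i],
                }
            )
    cohort = pd.DataFrame(
        rows, columns=COHORT_COLUMNS + ["_pain_latent"]
    )
    validate_cohort(cohort)
    return cohort


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Enforce the cohort invariants; raise ValueError naming the first violation."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    if cohort["subject_id"].duplicated().any():
        raise ValueError("subject_ids must be unique")
    bad_group = ~cohort["group"].isin(["pain", "healthy"])
    if bad_group.any():
        raise ValueError(f"unknown group labels: {cohort.loc[bad_group, 'group'].unique()}")
    pain = cohort["group"] == "pain"
    if cohort.loc[pain, "pain_intensity"].isna().any():
        raise ValueError("pain subjects must have a pain_intensity")
    if cohort.loc[~pain, "pain_intensity"].notna().any():
        raise ValueError("healthy subjects must not have a pain_intensity")
    if (cohort.loc[~pain, "diagnosis"] != "none").any():
        raise ValueError("healthy subjects must have diagnosis 'none'")
    if (cohort.loc[pain, "diagnosis"] == "none").any():
        raise ValueError("pain subjects must have a diagnosis other than 'none'")


@dataclass(frozen=True)
class EffectConfig:
    """Ground-truth effect and distribution configuration.

    ``exponent_noise_sd`` is the SD of the age-independent exponent
    component; ``group_d`` and ``pain_rho`` are defined on that scale
    (standardized shift of the pain group; partial correlation with pain
    once age is removed).  Defaults emulate a population with exponents
    around 1.10 and total SD near 0.17 including a mild age-flattening
    trend, and a single individual alpha peak per subject.
    """

    group_d: float = 0.0
    pain_rho: float = 0.0
    age_slope: float = -0.003  # exponent units per year
    exponent_mean: float = 1.10
    exponent_noise_sd: float = 0.16
    offset_mean: float = 1.0
    offset_sd: float = 0.2
    knee: float = 0.0
    alpha_center: tuple[float, float] = (10.0, 1.0)  # mean, sd (Hz)
    alpha_height: tuple[float, float] = (0.6, 0.15)  # log10 power
    alpha_width: tuple[float, float] = (1.5, 0.25)  # Hz (Gaussian SD)
    n_peaks: int = 1

    def __post_init__(self) -> None:
        if abs(self.pain_rho) >= 1.0:
            raise ValueError("pain_rho must lie strictly inside (-1, 1)")
        if self.exponent_noise_sd < 0 or self.knee < 0:
            raise ValueError("exponent_noise_sd and knee must be non-negative")


@dataclass
class GroundTruth:
    """Per-subject true aperiodic parameters and peak lists."""

    params: pd.DataFrame  # columns subject_id, offset, knee, exponent
    peaks: pd.DataFrame  # columns subject_id, center, height, width
    config: EffectConfig

    def for_subject(self, subject_id: str) -> tuple[float, float, float, pd.DataFrame]:
        row = self.params.loc[self.params["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(f"no ground truth for subject {subject_id!r}")
        r = row.iloc[0]
        pk = self.peaks.loc[self.peaks["subject_id"] == subject_id]
        return float(r["offset"]), float(r["knee"]), float(r["exponent"]), pk


def assign_ground_truth(
    cohort: pd.DataFrame, config: EffectConfig | None = None, seed: int = 0
) -> GroundTruth:
    """Draw per-subject aperiodic parameters carrying the configured effects.

    The exponent of subject i is

        chi_i = mean + age_slope*(age_i - mean_age) + shift_i + e_i

    where ``shift_i = group_d * sd`` for pain subjects, and ``e_i`` has SD
    ``sd = exponent_noise_sd`` and, for pain subjects, correlation
    ``pain_rho`` with the standardized (pre-rounding) pain rating.  At large
    n the realized Cohen's d of the age-removed exponents approaches
    ``group_d`` and the partial correlation with pain approaches
    ``pain_rho``.
    """
    config = config or EffectConfig()
    validate_cohort(cohort)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    sd = config.exponent_noise_sd
    mean_age = float(cohort["age"].mean())
    pain = (cohort["group"] == "pain").to_numpy()

    latent = cohort["_pain_latent"] if "_pain_latent" in cohort else cohort["pain_intensity"]
    latent = latent.to_numpy(dtype=float)
    z_pain = np.zeros(n)
    if pain.any():
        lp = latent[pain]
        lp_sd = lp.std(ddof=0)
        z_pain[pain] = (lp - lp.mean()) / lp_sd if lp_sd > 0 else 0.0

    eps = rng.standard_normal(n)
    noise = np.where(
        pain,
        sd * (config.pain_rho * z_pain + np.sqrt(1.0 - config.pain_rho**2) * eps),
        sd * eps,
    )
    chi = (
        config.exponent_mean
        + config.age_slope * (cohort["age"].to_numpy(dtype=float) - mean_age)
        + np.where(pain, config.group_d * sd, 0.0)
        + noise
    )
    offsets = rng.normal(config.offset_mean, config.offset_sd, size=n)
    params = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "offset": offsets,
            "knee": np.full(n, config.knee),
            "exponent": chi,
        }
    )

    peak_rows = []
    for sid in cohort["subject_id"]:
        for _ in range(config.n_peaks):
            center = np.clip(rng.normal(*config.alpha_center), 8.0, 13.0)
            height = max(float(rng.normal(*config.alpha_height)), 0.2)
            width = float(np.clip(rng.normal(*config.alpha_width), 1.0, 2.5))
            peak_rows.append(
                {"subject_id": sid, "center": float(center), "height": height, "width": width}
            )
    peaks = pd.DataFrame(peak_rows, columns=["subject_id", "center", "height", "width"])
    return GroundTruth(params=params, peaks=peaks, config=config)


def _model_log10(
    freqs: np.ndarray, offset: float, knee: float, exponent: float, peaks: pd.DataFrame
) -> np.ndarray:
    out = offset - np.log10(knee + freqs**exponent)
    for _, p in peaks.iterrows():
        out += p["height"] * np.exp(-((freqs - p["center"]) ** 2) / (2.0 * p["width"] ** 2))
    return out


def synthesize_spectrum(
    truth: GroundTruth,
    subject_id: str,
    region_label: str,
    freqs: ArrayLike,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Linear-power spectrum on ``freqs``: model log10 power plus N(0, noise_sd) per bin.

    Fast path that bypasses time-domain synthesis; the per-(subject, region)
    noise stream is a pure function of (seed, subject_id, region_label).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or np.any(freqs <= 0) or np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be a positive, strictly ascending 1-D grid")
    offset, knee, exponent, peaks = truth.for_subject(subject_id)
    rng = _child_rng(seed, subject_id, region_label)
    log10p = _model_log10(freqs, offset, knee, exponent, peaks)
    if noise_sd > 0:
        log10p = log10p + rng.normal(0.0, noise_sd, size=freqs.size)
    return 10.0**log10p


def synthesize_timeseries(
    truth: GroundTruth,
    subject_id: str,
    region_label: str,
    duration: float = 300.0,
    sampling_rate: float = 250.0,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to the subject's model spectrum.

    White noise is transformed to the frequency domain, its amplitudes are
    scaled by the square root of the target linear power, and the result is
    transformed back; the expected PSD is then proportional to
    10**(b - log10(k + F**chi) + peaks).  The DC component is zeroed, so the
    output has (near-)zero mean.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    offset, knee, exponent, peaks = truth.for_subject(subject_id)
    n = int(round(duration * sampling_rate))
    rng = _child_rng(seed, subject_id, region_label, "ts")
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    amp[pos] = np.sqrt(10.0 ** _model_log10(freqs[pos], offset, knee, exponent, peaks))
    x = np.fft.irfft(spec * amp, n=n)
    return x - x.mean()
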