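"""Study configuration: one flat-keyed YAML document covering every
generator, fitting, statistics and multiverse parameter, with every seed
explicit.  Unknown keys are rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .stats import DEFAULT_R_PRIOR_WIDTH, DEFAULT_T_PRIOR_SCALE

__all__ = ["StudyConfig", "load_config", "save_config"]


@dataclass
class StudyConfig:
    # cohort
    n_pain: int = 149
    n_healthy: int = 115
    n_cbp: int = 80
    n_cwp: int = 33
    age_min: int = 18
    age_max: int = 86
    cohort_seed: int = 1
    # ground truth / effects
    group_d: float = 0.0
    pain_rho: float = 0.0
    age_slope: float = -0.003
    exponent_mean: float = 1.10
    exponent_noise_sd: float = 0.16
    truth_seed: int = 2
    # spectra
    data_mode: str = "spectra"  # 'spectra' (direct synthesis) or 'timeseries'
    n_regions: int = 4  # mPFC; whole-brain mode uses its own count
    n_regions_whole_brain: int = 100
    spectrum_noise_sd: float = 0.05
    duration_s: float = 300.0
    sampling_rate_hz: float = 250.0
    data_seed: int = 3
    # stats
    t_prior_scale: float = DEFAULT_T_PRIOR_SCALE
    r_prior_width: float = DEFAULT_R_PRIOR_WIDTH
    residualization: str = "pooled"  # or 'per_group'
    match_bf_threshold: float = 1.0 / 3.0
    match_max_iter: int = 1000
    match_seed: int = 4
    # multiverse / inference
    b_permutations: int = 500
    inference_seed: int = 5
    b_fdr: int = 500
    fdr_seed: int = 6

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> StudyConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return StudyConfig(**raw)


def save_config(config: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf8")
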