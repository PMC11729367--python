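"""File round-tripping: cohort CSV, spectra CSV, fit JSON, curve CSV,
inference JSON, and run manifests.  All formats are plain text; floats are
serialized with 12 significant digits so round-trips are lossless in
practice.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import COHORT_COLUMNS, validate_cohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_spectra",
    "read_spectra",
    "write_curve",
    "read_curve",
    "write_inference",
    "read_inference",
    "write_manifest",
]

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _fmt(x: float) -> str:
    return "" if pd.isna(x) else (FLOAT_FMT % x)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Cohort CSV: header row, UTF-8, empty field for missing pain_intensity."""
    validate_cohort(cohort)
    out = cohort[COHORT_COLUMNS].copy()
    out["pain_intensity"] = out["pain_intensity"].map(_fmt)
    out.to_csv(path, index=False, encoding="utf8")


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header != COHORT_COLUMNS:
            raise ParseError(f"{path}:1: expected header {','.join(COHORT_COLUMNS)}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(COHORT_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(COHORT_COLUMNS)} fields, got {len(parts)}"
                )
            try:
                rows.append(
                    {
                        "subject_id": parts[0],
                        "group": parts[1],
                        "age": int(parts[2]),
                        "gender": parts[3],
                        "dataset": int(parts[4]),
                        "diagnosis": parts[5],
                        "pain_intensity": float(parts[6]) if parts[6] else np.nan,
                    }
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    try:
        validate_cohort(cohort)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return cohort


def write_spectra(frame: pd.DataFrame, path: str | Path) -> None:
    """Long-format spectra CSV: subject_id, region_label, frequency_hz, power."""
    cols = ["subject_id", "region_label", "frequency_hz", "power"]
    frame[cols].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_spectra(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    expected = ["subject_id", "region_label", "frequency_hz", "power"]
    if list(frame.columns) != expected:
        raise ParseError(f"{path}:1: expected header {','.join(expected)}")
    return frame


def write_curve(curve_frame: pd.DataFrame, path: str | Path) -> None:
    """Curve CSV: one row per specification with settings and results."""
    curve_frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_curve(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_inference(inference: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(inference, indent=2) + "\n", encoding="utf8")


def read_inference(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf8"))


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode("utf8")
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: str | Path, config: dict, seeds: dict) -> dict:
    """Manifest of config hash, seeds and library versions; two runs with
    equal manifests produce equal outputs."""
    import scipy

    manifest = {
        "config_sha256": config_hash(config),
        "seeds": seeds,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf8")
    return manifest
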