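"""Cohort and configuration I/O.

Cohorts travel as CSV with a fixed header; booleans as 0/1, grades as the
literal strings of the Clavien–Dindo and pathology scales.  Validation is
per-row and errors cite the offending row number (header = row 1).
Generator configs load from YAML with line-item error messages.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cohort import (
    CLAVIEN_GRADES,
    PATHOLOGY_GRADES,
    SURGERY_GROUPS,
    CohortConfig,
    ComplicationRateSet,
    PatientRecord,
)
from .errors import CohortValidationError, ConfigurationError
from .risk import LogisticModelSpec

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "read_cohort_config",
    "write_scored_cohort",
]

COHORT_COLUMNS = (
    "id",
    "age",
    "sex",
    "mpd_mm",
    "cyst_mm",
    "mural_nodule",
    "ca19_9",
    "cea",
    "surgery",
    "pathology",
    "clavien",
)


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "mpd_mm": r.mpd_mm,
            "cyst_mm": r.cyst_mm,
            "mural_nodule": int(r.mural_nodule),
            "ca19_9": r.ca19_9,
            "cea": r.cea,
            "surgery": r.surgery,
            "pathology": r.pathology,
            "clavien": r.clavien,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def _parse_row(row: dict, line: int) -> PatientRecord:
    def num(field: str) -> float:
        try:
            return float(row[field])
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"row {line}: column '{field}' is not numeric ({row[field]!r})") from exc

    def enum(field: str, allowed) -> str:
        v = row[field]
        if v not in allowed:
            raise CohortValidationError(f"row {line}: column '{field}' has unknown value {v!r} (allowed: {allowed})")
        return v

    mural_raw = row["mural_nodule"]
    if mural_raw not in ("0", "1", 0, 1):
        raise CohortValidationError(f"row {line}: column 'mural_nodule' must be 0 or 1, got {mural_raw!r}")
    mpd = num("mpd_mm")
    if mpd > 10.0:
        raise CohortValidationError(
            f"row {line}: mpd_mm {mpd} exceeds 10 mm; main-duct dilatation above "
            "10 mm falls outside this analysis (main-duct disease exclusion)"
        )
    rec = PatientRecord(
        id=str(row["id"]),
        age=num("age"),
        sex=enum("sex", ("male", "female")),
        mpd_mm=mpd,
        cyst_mm=num("cyst_mm"),
        mural_nodule=bool(int(mural_raw)),
        ca19_9=num("ca19_9"),
        cea=num("cea"),
        surgery=enum("surgery", SURGERY_GROUPS),
        pathology=enum("pathology", PATHOLOGY_GRADES),
        clavien=enum("clavien", CLAVIEN_GRADES),
    )
    try:
        rec.validate()
    except ConfigurationError as exc:
        raise CohortValidationError(f"row {line}: {exc}") from exc
    return rec


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; errors name the failing row."""
    text = Path(path).read_text()
    reader = csv.DictReader(_io.StringIO(text))
    if reader.fieldnames is None:
        raise CohortValidationError(f"{path}: file is empty")
    missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    records = [_parse_row(row, line) for line, row in enumerate(reader, start=2)]
    if not records:
        warnings.warn(f"{path}: header-only file, empty cohort", stacklevel=2)
    return records


def write_scored_cohort(records: Sequence[PatientRecord], mp, sc, path: str | Path) -> None:
    """The cohort CSV plus per-patient `mp` and `sc` probability columns."""
    frame = cohort_to_frame(records)
    frame["mp"] = list(mp)
    frame["sc"] = list(sc)
    frame.to_csv(path, index=False)


def _rate_set(group: str, raw: dict) -> ComplicationRateSet:
    if not isinstance(raw, dict):
        raise ConfigurationError(f"rate_sets['{group}']: expected a mapping of severity -> rate")
    return ComplicationRateSet(group, {str(k): float(v) for k, v in raw.items()})


def read_cohort_config(path: str | Path) -> CohortConfig:
    """Load a generator config from YAML, validating field by field."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    kwargs: dict = {}
    simple = ("n_pd", "n_dp", "hgd_frac", "lgd_frac", "sc_noise_sd", "seed")
    for key in simple:
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "feature_params" in raw:
        kwargs["feature_params"] = raw.pop("feature_params")
    if "rate_sets" in raw:
        rs = raw.pop("rate_sets")
        kwargs["rate_sets"] = {g: _rate_set(g, v) for g, v in rs.items()}
    if "malignancy_model" in raw:
        m = raw.pop("malignancy_model")
        try:
            kwargs["malignancy_model"] = LogisticModelSpec(
                intercept=float(m["intercept"]),
                coefficients={k: float(v) for k, v in m["coefficients"].items()},
                transforms={k: str(v) for k, v in m["transforms"].items()},
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malignancy_model: malformed spec ({exc})") from exc
    if raw:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(raw)}")
    try:
        config = CohortConfig(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    config.validate()
    return config
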