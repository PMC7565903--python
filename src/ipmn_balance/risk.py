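"""Per-patient probability models.

Two scores drive the decision analysis:

* ``mp`` — malignancy probability: a logistic model over the seven
  preoperative factors of the clinical nomogram (age, sex, main pancreatic
  duct diameter, cyst size, mural nodule, CA19-9, CEA).  The published
  nomogram's fitted coefficients are not freely printed, so the default
  spec shipped here is a surrogate — calibrate before clinical use.
* ``sc`` — surgical-risk probability: the predicted chance of a serious
  postoperative complication.  The real risk calculator is a proprietary
  web service; :func:`sc_surrogate` stands in with a per-surgery baseline
  logit plus optional covariate terms and Gaussian logit noise.

All probabilities are carried as fractions in [0, 1]; conversion to
percent happens only at the I/O boundary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigurationError, MissingDataError

__all__ = [
    "LogisticModelSpec",
    "SurgicalRiskSpec",
    "DEFAULT_MP_SPEC",
    "DEFAULT_SC_SPEC",
    "logistic_score",
    "score_records",
    "sc_surrogate",
    "sc_scores",
]

_TRANSFORMS = ("identity", "log1p", "indicator")

#: Features a model spec may reference, in canonical order.
MODEL_FEATURES = ("age", "sex", "mpd_mm", "cyst_mm", "mural_nodule", "ca19_9", "cea")


def _encode(name: str, value: Any) -> float:
    """Map a raw record value onto the numeric scale the model uses."""
    if value is None:
        raise MissingDataError(f"feature '{name}' is missing")
    if name == "sex":
        if value in ("male", "female"):
            return 1.0 if value == "male" else 0.0
        raise MissingDataError(f"feature 'sex' has unusable value {value!r}")
    if name == "mural_nodule":
        return 1.0 if bool(value) else 0.0
    x = float(value)
    if not math.isfinite(x):
        raise MissingDataError(f"feature '{name}' is not finite ({value!r})")
    return x


def _apply_transform(transform: str, x: np.ndarray | float):
    if transform == "identity" or transform == "indicator":
        return x
    if transform == "log1p":
        return np.log1p(x)
    raise ConfigurationError(f"transforms: unknown transform '{transform}'")


@dataclass(frozen=True)
class LogisticModelSpec:
    """A logistic model: probability = expit(intercept + sum coef*T(x)).

    ``transforms`` must name a transform for every coefficient; allowed
    transforms are ``identity``, ``log1p`` (for right-skewed labs) and
    ``indicator`` (0/1 encoded categories).
    """

    intercept: float
    coefficients: Mapping[str, float]
    transforms: Mapping[str, str]

    def __post_init__(self) -> None:
        for name in self.coefficients:
            if name not in MODEL_FEATURES:
                raise ConfigurationError(
                    f"coefficients: '{name}' is not a patient feature "
                    f"(expected one of {MODEL_FEATURES})"
                )
            if name not in self.transforms:
                raise ConfigurationError(f"transforms: no transform given for '{name}'")
        for name, t in self.transforms.items():
            if t not in _TRANSFORMS:
                raise ConfigurationError(
                    f"transforms['{name}']: unknown transform '{t}' "
                    f"(expected one of {_TRANSFORMS})"
                )

    def linear_predictor(self, features: Mapping[str, Any]) -> float:
        lp = float(self.intercept)
        for name, coef in self.coefficients.items():
            x = _encode(name, features[name] if name in features else getattr(features, name, None))
            lp += coef * float(_apply_transform(self.transforms[name], x))
        return lp

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": dict(self.coefficients),
                "transforms": dict(self.transforms),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModelSpec":
        raw = json.loads(text)
        try:
            return cls(
                intercept=float(raw["intercept"]),
                coefficients={k: float(v) for k, v in raw["coefficients"].items()},
                transforms={k: str(v) for k, v in raw["transforms"].items()},
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"model spec: missing key {exc}") from exc


def _features_frame(records) -> dict[str, np.ndarray]:
    """Column-wise encoded feature arrays for a sequence of records."""
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        getter = lambda name: records[name].tolist()  # noqa: E731
    else:
        getter = lambda name: [getattr(r, name) for r in records]  # noqa: E731
    out: dict[str, np.ndarray] = {}
    for name in MODEL_FEATURES:
        try:
            raw = getter(name)
        except (KeyError, AttributeError):
            continue
        out[name] = np.array([_encode(name, v) for v in raw], dtype=float)
    return out


def logistic_score(record, spec: LogisticModelSpec) -> float:
    """Malignancy probability for one record under ``spec``.

    Strictly increasing in any feature with a positive coefficient.
    Raises :class:`MissingDataError` when a required feature is absent —
    incomplete records are excluded, never imputed.
    """
    feats = {name: getattr(record, name, None) for name in spec.coefficients}
    return float(expit(spec.linear_predictor(feats)))


def score_records(records, spec: LogisticModelSpec) -> np.ndarray:
    """Vectorized :func:`logistic_score`; bit-identical to the scalar path."""
    cols = _features_frame(records)
    n = len(next(iter(cols.values()))) if cols else len(records)
    lp = np.full(n, float(spec.intercept))
    for name, coef in spec.coefficients.items():
        if name not in cols:
            raise MissingDataError(f"feature '{name}' is missing from the cohort")
        lp += coef * np.asarray(_apply_transform(spec.transforms[name], cols[name]))
    return expit(lp)


@dataclass(frozen=True)
class SurgicalRiskSpec:
    """Surrogate serious-complication model.

    ``baseline`` maps a surgery group to its minimal serious-complication
    probability; covariate terms are centred deviations so that a patient
    at the reference covariate values receives exactly the baseline risk.
    """

    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"PD": 0.122, "DP": 0.084}
    )
    coefficients: Mapping[str, float] = field(default_factory=dict)
    transforms: Mapping[str, str] = field(default_factory=dict)
    centers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, p in self.baseline.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"baseline['{g}']: {p} is not in (0, 1)")
        for name in self.coefficients:
            if name not in MODEL_FEATURES:
                raise ConfigurationError(f"coefficients: '{name}' is not a patient feature")
            if name not in self.transforms:
                raise ConfigurationError(f"transforms: no transform given for '{name}'")

    def linear_predictor(self, surgery: str, features: Mapping[str, Any]) -> float:
        if surgery not in self.baseline:
            raise ConfigurationError(
                f"surgery '{surgery}' has no baseline risk (known: {sorted(self.baseline)})"
            )
        lp = float(logit(self.baseline[surgery]))
        for name, coef in self.coefficients.items():
            x = _encode(name, features.get(name))
            lp += coef * (float(_apply_transform(self.transforms[name], x)) - self.centers.get(name, 0.0))
        return lp


def sc_surrogate(
    record,
    spec: SurgicalRiskSpec | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Surgical-risk probability for one record.

    With ``noise_sd == 0`` the score is deterministic; otherwise a
    Gaussian perturbation on the logit scale models between-patient
    comorbidity variation the surrogate's covariates do not carry.
    """
    spec = spec or DEFAULT_SC_SPEC
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd: {noise_sd} must be >= 0")
    feats = {name: getattr(record, name, None) for name in MODEL_FEATURES}
    lp = spec.linear_predictor(record.surgery, feats)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        lp += noise_sd * gen.standard_normal()
    return float(expit(lp))


def sc_scores(
    records,
    spec: SurgicalRiskSpec | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Vectorized surgical-risk scores for a cohort."""
    spec = spec or DEFAULT_SC_SPEC
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd: {noise_sd} must be >= 0")
    cols = _features_frame(records)
    surgeries = [getattr(r, "surgery") for r in records]
    lp = np.empty(len(surgeries))
    for i, s in enumerate(surgeries):
        if s not in spec.baseline:
            raise ConfigurationError(
                f"surgery '{s}' has no baseline risk (known: {sorted(spec.baseline)})"
            )
        lp[i] = logit(spec.baseline[s])
    for name, coef in spec.coefficients.items():
        if name not in cols:
            raise MissingDataError(f"feature '{name}' is missing from the cohort")
        lp += coef * (np.asarray(_apply_transform(spec.transforms[name], cols[name])) - spec.centers.get(name, 0.0))
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        lp = lp + noise_sd * gen.standard_normal(len(lp))
    return expit(lp)


#: Surrogate malignancy model: positive weight on duct dilatation, mural
#: nodule and log CA19-9 (the strongest multivariable predictors in this
#: setting), smaller weights elsewhere; labs enter via log1p to tame skew.
#: Surrogate — calibrate before clinical use.
DEFAULT_MP_SPEC = LogisticModelSpec(
    intercept=-5.8,
    coefficients={
        "age": 0.020,
        "sex": 0.10,
        "mpd_mm": 0.25,
        "cyst_mm": 0.010,
        "mural_nodule": 1.10,
        "ca19_9": 0.45,
        "cea": 0.10,
    },
    transforms={
        "age": "identity",
        "sex": "indicator",
        "mpd_mm": "identity",
        "cyst_mm": "identity",
        "mural_nodule": "indicator",
        "ca19_9": "log1p",
        "cea": "log1p",
    },
)

#: Surrogate serious-complication model: per-surgery baseline risks at the
#: minimal published values, with a mild age effect around age 63.
DEFAULT_SC_SPEC = SurgicalRiskSpec(
    baseline={"PD": 0.122, "DP": 0.084},
    coefficients={"age": 0.03},
    transforms={"age": "identity"},
    centers={"age": 63.0},
)
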