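"""Configuration of the synthetic hospitalized-cohort data-generating process.

The generator emulates the observed-data structure of a daily-resolution
EHR cohort: baseline covariates L0 (standardised age, sex, a comorbidity
flag), a latent illness-severity process S_t that drives everything
downstream, a severe-hypoxia indicator (S_t above a threshold), an
observational daily treatment propensity, a discrete-time death hazard,
an informative discharge (loss to follow-up) hazard that falls with
severity, and a severity-driven "labs measured today" indicator.

The treatment effect enters in two places, both scaled by
``treatment_effect`` (a log-odds shift, 0 = exact null):

* directly on the death hazard while the patient is within
  ``treat_memory_days`` days of a treated day, and
* on the next day's severity, via ``treat_lag_scale * treatment_effect``.

Tying the severity pathway to ``treatment_effect`` guarantees that a null
effect is a *sharp* null — no downstream node responds to treatment — while
any non-null effect produces treatment-confounder feedback (treatment
lowers severity, severity drives future treatment, death and discharge).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["DGPConfig", "default_config"]


def _d(**kw: float) -> Any:
    return field(default_factory=lambda: dict(kw))


@dataclass
class DGPConfig:
    """All coefficients, effect sizes and the seed of the synthetic cohort.

    Coefficient groups are plain ``{name: value}`` mappings so configs round-trip
    through YAML. Logistic groups may contain ``+-inf`` (degenerate but
    well-defined probabilities); NaN is rejected everywhere, and non-finite
    values are rejected in the structural (severity/baseline) groups where they
    would propagate non-finite states.
    """

    n_patients: int = 3000
    horizon: int = 28
    seed: int = 0

    #: log-odds shift on the death hazard while recently treated; 0 = sharp null
    treatment_effect: float = -0.3

    #: S_t above this value means a severe-hypoxia day
    hypoxia_threshold: float = 1.25

    #: days a treated day keeps shifting the death hazard (trial course length)
    treat_memory_days: int = 6

    baseline_coefs: dict = _d(
        p_male=0.5, p_comorbid=0.3,
        sev0_intercept=0.1, sev0_age=0.45, sev0_comorbid=0.5, sev0_sd=0.9,
    )
    severity_coefs: dict = _d(
        intercept=0.06, ar=0.85, age=0.08, comorbid=0.10,
        treat_lag_scale=0.6, sd=0.55,
    )
    #: prev_treat sustains a started course; course_done (cumulative treated
    #: days reaching treat_memory_days) winds it down, mimicking ~6-day
    #: courses while keeping every assignment probability well inside (0, 1)
    treat_propensity_coefs: dict = _d(
        intercept=-5.0, severity=0.2, hypoxia=2.6, age=0.1, prev_treat=7.0,
        course_done=-5.0,
    )
    death_hazard_coefs: dict = _d(
        intercept=-5.7, severity=1.15, age=0.3, comorbid=0.3,
    )
    discharge_hazard_coefs: dict = _d(
        intercept=-2.5, severity=-1.0,
    )
    measurement_coefs: dict = _d(
        intercept=-0.4, severity=0.8,
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.treat_memory_days < 1:
            raise ValueError("treat_memory_days must be >= 1")
        for grp in ("baseline_coefs", "severity_coefs"):
            for k, v in getattr(self, grp).items():
                if not math.isfinite(float(v)):
                    raise ValueError(f"non-finite coefficient {grp}.{k} = {v}")
        for grp in ("treat_propensity_coefs", "death_hazard_coefs",
                    "discharge_hazard_coefs", "measurement_coefs"):
            for k, v in getattr(self, grp).items():
                if math.isnan(float(v)):
                    raise ValueError(f"NaN coefficient {grp}.{k}")
        for name in ("treatment_effect", "hypoxia_threshold"):
            if not math.isfinite(float(getattr(self, name))):
                raise ValueError(f"non-finite {name}")
        if not (0.0 < self.baseline_coefs["sev0_sd"]) or not (0.0 < self.severity_coefs["sd"]):
            raise ValueError("severity noise scales must be positive")

    # ------------------------------------------------------------------ io
    def replace(self, **kw: Any) -> "DGPConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DGPConfig":
        base = cls()
        kw: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(getattr(base, f.name), dict):
                merged = dict(getattr(base, f.name))
                merged.update(v)
                v = merged
            kw[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown DGP config keys: {sorted(unknown)}")
        return cls(**kw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "DGPConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides: Any) -> DGPConfig:
    """The package's reference study conditions (see docs/methods.md)."""
    return DGPConfig(**overrides)
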