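"""Simulation configuration with planted effects.

The generator emulates the statistical structure the downstream analysis
assumes: July-June claim years, four medication-severity archetypes with the
characteristic seasonal trajectory shapes (near-zero, winter-peaking,
moderate-flat, high with a January peak), clinic-level quality-indicator
heterogeneity, and a marginal logistic exacerbation model with planted
grade and covariate log-odds and AR(1) within-patient dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np

LogOdds = Union[float, Sequence[float]]


class ConfigurationError(ValueError):
    pass


def _default_grade_log_odds() -> Dict[str, LogOdds]:
    # satisfactory-vs-tertiary mirrors the whole-group OR scale (~1.25);
    # unsatisfactory slightly smaller, as in the published whole-group model
    return {
        "Unsatisfactory": math.log(1.10),
        "Satisfactory": math.log(1.25),
    }


def _default_covariate_log_odds() -> Dict[str, object]:
    return {
        # adherence levels 0..3, reference level 3 (>80%)
        "mpr_level": (1.0, 0.25, 0.30, 0.0),
        # having a comorbidity raises the odds slightly
        "comorbidity": 0.08,
        # male vs female
        "sex_male": 0.05,
        # age bands 15-34 .. 65+ (reference)
        "age_band": (-0.55, -0.35, -0.15, -0.05, 0.0),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic claims world.

    ``grade_log_odds`` values may be scalars or length-4 sequences (one
    planted effect per severity archetype) to create effect heterogeneity
    across severity groups.
    """

    n_patients: int = 20000
    n_periods: int = 3
    n_primary_clinics: int = 200
    n_tertiary_hospitals: int = 30
    severity_archetype_weights: Tuple[float, ...] = (0.73, 0.098, 0.146, 0.026)
    grade_log_odds: Dict[str, LogOdds] = field(default_factory=_default_grade_log_odds)
    covariate_log_odds: Dict[str, object] = field(
        default_factory=_default_covariate_log_odds
    )
    severity_log_odds: Tuple[float, ...] = (0.0, 0.68, 1.11, 1.70)
    period_log_odds: Tuple[float, ...] = ()  # reference = last period (0)
    intercept: float = -2.05
    ar1_rho: float = 0.4
    seed: int = 0
    first_year: int = 2013
    # composition / behaviour knobs
    tertiary_prob: Tuple[float, ...] = (0.074, 0.482, 0.357, 0.738)
    good_clinic_fraction: float = 0.45
    stay_prob: float = 0.8
    two_clinic_fraction: float = 0.02
    uninsured_fraction: float = 0.02
    comorbidity_prob: float = 0.67
    male_prob: float = 0.53
    age_band_weights: Tuple[float, ...] = (0.219, 0.191, 0.209, 0.174, 0.207)
    decoy_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "n_patients",
            "n_periods",
            "n_primary_clinics",
            "n_tertiary_hospitals",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        w = np.asarray(self.severity_archetype_weights, dtype=float)
        if len(w) != 4 or abs(w.sum() - 1.0) > 1e-6 or (w < 0).any():
            raise ConfigurationError(
                "severity_archetype_weights must be 4 probabilities summing to 1"
            )
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigurationError("ar1_rho must lie in [0, 1)")
        for key in ("Unsatisfactory", "Satisfactory"):
            v = np.atleast_1d(np.asarray(self.grade_log_odds[key], dtype=float))
            if len(v) not in (1, 4):
                raise ConfigurationError(
                    f"grade_log_odds[{key!r}] must be scalar or length 4"
                )
        if self.period_log_odds and len(self.period_log_odds) != self.n_periods:
            raise ConfigurationError(
                "period_log_odds must have one entry per assessment period"
            )
        aw = np.asarray(self.age_band_weights, dtype=float)
        if len(aw) != 5 or abs(aw.sum() - 1.0) > 1e-3:
            raise ConfigurationError("age_band_weights must be 5 probabilities")

    # -- resolved planted effects ----------------------------------------

    def grade_effects(self) -> np.ndarray:
        """(2, 4) array of log-odds: rows Unsatisfactory/Satisfactory,
        columns archetype 0..3; Tertiary is the zero reference."""
        out = np.zeros((2, 4))
        for i, key in enumerate(("Unsatisfactory", "Satisfactory")):
            v = np.atleast_1d(np.asarray(self.grade_log_odds[key], dtype=float))
            out[i] = v if len(v) == 4 else v[0]
        return out

    def period_effects(self) -> np.ndarray:
        if self.period_log_odds:
            return np.asarray(self.period_log_odds, dtype=float)
        eff = np.zeros(self.n_periods)
        defaults = {0: 0.34, 1: 0.12}  # echo the published period ORs
        for i in range(self.n_periods - 1):
            eff[i] = defaults.get(i, 0.0)
        return eff

    def covariate_effects(self) -> Dict[str, np.ndarray]:
        merged = _default_covariate_log_odds()
        merged.update(self.covariate_log_odds)
        return {
            "mpr_level": np.asarray(merged["mpr_level"], dtype=float),
            "comorbidity": float(merged["comorbidity"]),
            "sex_male": float(merged["sex_male"]),
            "age_band": np.asarray(merged["age_band"], dtype=float),
        }

    @classmethod
    def null_effects(cls, **kwargs) -> "SimulationConfig":
        """All planted effects zero (grade, covariates, severity, period)."""
        kwargs.setdefault(
            "grade_log_odds", {"Unsatisfactory": 0.0, "Satisfactory": 0.0}
        )
        kwargs.setdefault(
            "covariate_log_odds",
            {
                "mpr_level": (0.0, 0.0, 0.0, 0.0),
                "comorbidity": 0.0,
                "sex_male": 0.0,
                "age_band": (0.0,) * 5,
            },
        )
        kwargs.setdefault("severity_log_odds", (0.0, 0.0, 0.0, 0.0))
        kwargs.setdefault("period_log_odds", tuple([0.0] * kwargs.get("n_periods", 3)))
        return cls(**kwargs)
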