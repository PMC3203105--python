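"""Synthetic Australian-like demography, epidemiology, BMI and cost inputs.

The real model inputs (national life tables, burden-of-disease incidence,
measured BMI distributions) are not published in full, so this module
generates an internally consistent stand-in world:

* adult all-cause mortality follows a Gompertz curve per sex, evaluated at
  5-year age-band midpoints;
* chronic-disease incidence and case fatality rise log-linearly with age
  from disease-specific onset ages, with magnitudes chosen to resemble
  national adult rates (per person-year);
* BMI per sex/age stratum is normal, with the mean fitted so that
  P(BMI >= 30) equals the target obesity prevalence (21% of men, 23% of
  women by default);
* cohort sizes approximate the 2003 adult age pyramid (persons).

A small lognormal jitter (seeded) perturbs cohort counts and incidence so
different seeds give different but structurally identical worlds; mortality
and the BMI fit are exact so the stated invariants hold for every seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import disease_models

SEXES = ("male", "female")
AGE_LO = tuple(range(20, 100, 5))  # 16 five-year bands, 20-24 .. 95-99
DISEASES = (
    "stroke",
    "ischemic_heart_disease",
    "hypertensive_heart_disease",
    "diabetes",
    "osteoarthritis",
    "breast_cancer",
    "colon_cancer",
    "endometrial_cancer",
    "kidney_cancer",
)
FEMALE_ONLY = ("breast_cancer", "endometrial_cancer")


@dataclass(frozen=True)
class DiseaseRateParams:
    """Log-linear synthetic rate curves for one disease.

    ``i50``/``f50`` are the annual incidence / case-fatality rates at age 50
    per sex; ``gi``/``gf`` are log slopes per year of age; no incidence below
    ``onset`` (completed years).
    """

    i50_male: float
    i50_female: float
    gi: float
    f50: float
    gf: float
    onset: int
    remission: float = 0.0


# Magnitudes loosely follow national adult rates: cardiovascular and diabetes
# incidence of a few per 1000 rising steeply with age, rarer cancers, common
# but non-fatal osteoarthritis.
DEFAULT_DISEASE_PARAMS: dict[str, DiseaseRateParams] = {
    "ischemic_heart_disease": DiseaseRateParams(0.004, 0.002, 0.07, 0.05, 0.03, 30),
    "stroke": DiseaseRateParams(0.0015, 0.0012, 0.085, 0.08, 0.03, 30),
    "hypertensive_heart_disease": DiseaseRateParams(0.0004, 0.0004, 0.08, 0.04, 0.03, 35),
    "diabetes": DiseaseRateParams(0.006, 0.005, 0.05, 0.015, 0.02, 25),
    "osteoarthritis": DiseaseRateParams(0.008, 0.011, 0.04, 0.0, 0.0, 25),
    "breast_cancer": DiseaseRateParams(0.0, 0.0025, 0.02, 0.06, 0.0, 45),
    "colon_cancer": DiseaseRateParams(0.0008, 0.0007, 0.07, 0.12, 0.0, 30),
    "endometrial_cancer": DiseaseRateParams(0.0, 0.0006, 0.03, 0.08, 0.0, 35),
    "kidney_cancer": DiseaseRateParams(0.00025, 0.00015, 0.06, 0.20, 0.0, 30),
}

# 2003-like adult cohort sizes, thousands of persons per 5-year band.
DEFAULT_COUNTS_THOUSANDS = {
    "male": (690, 700, 720, 740, 750, 730, 680, 620, 520, 420, 310, 210, 120, 60, 20, 5),
    "female": (670, 690, 710, 730, 750, 740, 700, 640, 550, 460, 360, 260, 170, 95, 40, 12),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic world; YAML round-trippable."""

    gompertz_intercept: dict = field(
        default_factory=lambda: {"male": 3.2e-5, "female": 1.6e-5}
    )
    gompertz_slope: dict = field(default_factory=lambda: {"male": 0.090, "female": 0.095})
    counts_thousands: dict = field(
        default_factory=lambda: {s: list(DEFAULT_COUNTS_THOUSANDS[s]) for s in SEXES}
    )
    obesity_target: dict = field(default_factory=lambda: {"male": 0.21, "female": 0.23})
    bmi_sd: dict = field(default_factory=lambda: {"male": 4.0, "female": 5.0})
    height_m: dict = field(default_factory=lambda: {"male": 1.78, "female": 1.64})
    #: additive drift of mean BMI per calendar year (secular-trend hook;
    #: 0 = stationary population, the default analysis condition)
    bmi_trend_per_year: float = 0.0
    count_jitter_sd: float = 0.02
    incidence_jitter_sd: float = 0.03
    # baseline years-lived-with-disability rate: intercept + slope*(age-20),
    # capped (dimensionless, all causes)
    baseline_yld_intercept: float = 0.04
    baseline_yld_slope: float = 0.0025
    baseline_yld_cap: float = 0.35
    disease_params: dict = field(
        default_factory=lambda: {k: asdict(v) for k, v in DEFAULT_DISEASE_PARAMS.items()}
    )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def rates(self, disease: str) -> DiseaseRateParams:
        return DiseaseRateParams(**self.disease_params[disease])


def _midpoints() -> np.ndarray:
    return np.asarray(AGE_LO, float) + 2.5


def generate_population(seed: int, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Population counts and all-cause mortality by sex and 5-year band.

    Mortality is Gompertz, ``a * exp(b * age)``, evaluated at band midpoints
    (deterministic); counts carry a small seeded jitter.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    mids = _midpoints()
    rows = []
    for sex in SEXES:
        counts = np.asarray(config.counts_thousands[sex], float) * 1000.0
        if (counts <= 0).any():
            raise ValueError(f"non-positive cohort size for sex={sex}")
        counts = counts * rng.lognormal(0.0, config.count_jitter_sd, len(counts))
        mort = config.gompertz_intercept[sex] * np.exp(config.gompertz_slope[sex] * mids)
        if ((mort <= 0) | (mort >= 1)).any():
            raise ValueError("mortality rates must lie strictly in (0, 1)")
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_lo": AGE_LO,
                    "count": counts,
                    "mortality_rate": mort,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_disease_epi(seed: int, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Incidence, case fatality, remission and derived baseline prevalence
    for the nine obesity-related diseases, by sex and 5-year band.

    Breast and endometrial cancer have zero incidence for males.  The
    ``prevalence0`` column is the steady-state prevalence implied by the
    rates (disease model run from age 20), evaluated at band midpoints.
    """
    config = config or GeneratorConfig()
    unknown = set(config.disease_params) - set(DISEASES)
    if unknown:
        raise ValueError(f"unknown disease name(s): {sorted(unknown)}")
    missing = set(DISEASES) - set(config.disease_params)
    if missing:
        raise ValueError(f"missing disease parameters for: {sorted(missing)}")
    rng = np.random.default_rng(seed + 1)
    mids = _midpoints()
    rows = []
    for sex in SEXES:
        for disease in DISEASES:
            p = config.rates(disease)
            i50 = p.i50_male if sex == "male" else p.i50_female
            if sex == "male" and disease in FEMALE_ONLY:
                i50 = 0.0
            inc = i50 * np.exp(p.gi * (mids - 50.0))
            inc = np.where(mids >= p.onset, inc, 0.0)
            inc = inc * rng.lognormal(0.0, config.incidence_jitter_sd, len(inc))
            inc = np.clip(inc, 0.0, 0.25)
            cf = np.clip(p.f50 * np.exp(p.gf * (mids - 50.0)), 0.0, 0.5)
            rem = np.full(len(mids), p.remission)
            # steady-state prevalence over single-year ages, read at midpoints
            ages = np.arange(20, 101)
            bidx = np.clip((ages - 20) // 5, 0, len(mids) - 1)
            prev = disease_models.prevalence_from_rates(inc[bidx], cf[bidx], rem[bidx])
            prev_mid = prev[np.searchsorted(ages, np.floor(mids).astype(int))]
            rows.append(
                pd.DataFrame(
                    {
                        "disease": disease,
                        "sex": sex,
                        "age_lo": AGE_LO,
                        "incidence": inc,
                        "case_fatality": cf,
                        "remission": rem,
                        "prevalence0": prev_mid,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def fit_normal_mean_for_obesity(target: float, sd: float) -> float:
    """Mean of a normal BMI distribution with SD ``sd`` whose mass above 30
    equals ``target``."""
    if not 0.0 < target < 1.0:
        raise ValueError("obesity target must lie strictly in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return 30.0 - sd * stats.norm.isf(target)


def generate_bmi_params(seed: int, config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Normal BMI parameters per sex and 5-year band.

    The mean is fitted exactly so the implied obesity prevalence matches the
    per-sex target; the same stratum parameters are used at every age (the
    synthetic world carries no age gradient in adiposity).
    """
    config = config or GeneratorConfig()
    rows = []
    for sex in SEXES:
        sd = config.bmi_sd[sex]
        mean = fit_normal_mean_for_obesity(config.obesity_target[sex], sd)
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_lo": AGE_LO,
                    "mean_bmi": mean,
                    "sd_bmi": sd,
                    "mean_height": config.height_m[sex],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    implied = stats.norm.sf(30.0, out["mean_bmi"], out["sd_bmi"])
    if ((implied <= 0.05) | (implied >= 0.45)).any():
        raise ValueError("implied obesity prevalence outside the (0.05, 0.45) band")
    return out


def baseline_yld_rate(ages, config: GeneratorConfig | None = None) -> np.ndarray:
    """Baseline all-cause YLD (disability) rate by single-year age."""
    config = config or GeneratorConfig()
    ages = np.asarray(ages, float)
    return np.minimum(
        config.baseline_yld_intercept + config.baseline_yld_slope * (ages - 20.0),
        config.baseline_yld_cap,
    )
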