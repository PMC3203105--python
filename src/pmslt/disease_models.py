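"""Incidence -> prevalence -> disease-mortality propagation in annual cycles.

Each disease is a three-state model (well, diseased, dead-from-disease) run
in one-year cycles with all flows evaluated at the start-of-cycle state:

    S' = S - S*i + C*r
    C' = C + S*i - C*r - C*f
    disease deaths this cycle = C*f

S and C are proportions of the *living* cohort; people who die of the
disease leave the cohort through the life table's total-mortality channel
(all-cause mortality already contains these deaths), so within the
sub-model the living split is renormalised by returning the disease deaths
to the susceptible pool.  Under constant rates the prevalence fixed point is
the classic steady-state relation i / (i + r + f).

Baseline prevalence among the obese is not observed; it is derived with the
model itself, assuming a steady state: the whole-population incidence is
scaled by the obese/population mean-RR ratio (a PIF calculation against the
truncated-at-30, renormalised BMI distribution) and the disease model is run
over the lifetime of the youngest cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import risk_engine


def step_disease(S, C, incidence, case_fatality, remission=0.0):
    """One annual cycle; returns (S', C', disease_deaths).

    ``S`` and ``C`` are proportions of the living cohort (S + C is
    conserved: deaths are routed through the life table, see module
    docstring).  Accepts scalars or arrays.
    """
    i = np.asarray(incidence, float)
    f = np.asarray(case_fatality, float)
    r = np.asarray(remission, float)
    if (i < 0).any() or (f < 0).any() or (r < 0).any():
        raise ValueError("rates must be >= 0")
    S = np.asarray(S, float)
    C = np.asarray(C, float)
    new_cases = S * i
    remitted = C * r
    deaths = C * f
    C_next = C + new_cases - remitted - deaths
    S_next = (S + C) - C_next
    return S_next, C_next, deaths


def apply_pif_to_incidence(incidence, pif):
    """Scale incidence by (1 - PIF); PIF may be negative (risk increase)."""
    pif = np.asarray(pif, float)
    if (pif > 1.0).any():
        raise ValueError("pif must be <= 1")
    out = np.asarray(incidence, float) * (1.0 - pif)
    if (out < 0).any():
        raise ValueError("effective incidence would be negative")
    return out


def prevalence_from_rates(incidence, case_fatality, remission=None, init=0.0):
    """Run the disease model forward over single-year ages.

    Parameters are arrays over ages a0..a1 (one value per age); returns the
    start-of-age prevalence array of the same length, beginning at ``init``.
    This is the "steady state" derivation: a cohort followed from the
    youngest age gives prevalence-by-age for the whole (stationary)
    population.
    """
    i = np.asarray(incidence, float)
    f = np.asarray(case_fatality, float)
    r = np.zeros_like(i) if remission is None else np.asarray(remission, float)
    prev = np.empty(len(i))
    p = float(init)
    for k in range(len(i)):
        prev[k] = p
        _, p, _ = step_disease(1.0 - p, p, i[k], f[k], r[k])
    return prev


def derive_obese_baseline(
    epi: pd.DataFrame,
    bmi_params: pd.DataFrame,
    rr_table: pd.DataFrame,
    ages: np.ndarray | None = None,
) -> pd.DataFrame:
    """Steady-state disease prevalence among the obese (BMI >= 30).

    For each disease/sex/age the whole-population incidence is multiplied by
    the incidence-rate ratio E_obese[RR] / E_pop[RR], where E_obese uses the
    truncated-at-30, renormalised BMI distribution ("all Australians obese"
    counterfactual inflated to the population size); the disease model is
    then run over the lifetime of the youngest cohort.

    Returns a frame with columns disease, sex, age, incidence_ratio,
    incidence_obese, prevalence_obese.
    """
    if ages is None:
        ages = np.arange(20, 101)
    frames = []
    for sex in epi["sex"].unique():
        bp = bmi_params[bmi_params["sex"] == sex].sort_values("age_lo")
        band_idx = np.clip((ages - 20) // 5, 0, len(bp) - 1)
        mu = bp["mean_bmi"].to_numpy()[band_idx]
        sd = bp["sd_bmi"].to_numpy()[band_idx]
        for disease in epi["disease"].unique():
            sub = epi[(epi["disease"] == disease) & (epi["sex"] == sex)]
            sub = sub.sort_values("age_lo")
            b_idx = np.clip((ages - 20) // 5, 0, len(sub) - 1)
            i_pop = sub["incidence"].to_numpy()[b_idx]
            f = sub["case_fatality"].to_numpy()[b_idx]
            r = sub["remission"].to_numpy()[b_idx]
            ln_rr = risk_engine.expand_rr_by_age(rr_table, disease, sex, ages)
            e_pop = risk_engine.mean_rr_normal(mu, sd, ln_rr)
            e_obese = risk_engine.mean_rr_truncated_obese(mu, sd, ln_rr)
            if np.any(~np.isfinite(e_obese)):
                raise ValueError("truncated obese distribution has zero mass")
            ratio = e_obese / e_pop
            i_obese = i_pop * ratio
            prev = prevalence_from_rates(i_obese, f, r)
            frames.append(
                pd.DataFrame(
                    {
                        "disease": disease,
                        "sex": sex,
                        "age": ages,
                        "incidence_ratio": ratio,
                        "incidence_obese": i_obese,
                        "prevalence_obese": prev,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
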