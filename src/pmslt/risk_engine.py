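"""Relative-risk functions of BMI and potential impact fractions (PIF).

Relative risks are log-linear in BMI: an entry of ``rr`` per +1 kg m^-2
compounds multiplicatively, so RR(x) = rr**(x - ref).  The PIF of a shift of
the exposure distribution from ``base`` to ``cf`` is

    PIF = (E_base[RR] - E_cf[RR]) / E_base[RR]

and is independent of the reference BMI (the factor rr**-ref cancels).

Two computational routes are provided and cross-checked in the test suite:

* adaptive quadrature over BMI in [10, 60] for arbitrary densities
  (:func:`mean_rr`, :func:`pif`), and
* closed forms for normal / treated-obese-mixture exposures built on the
  lognormal-mean identity E[r**X] = exp(b*mu + b^2 s^2 / 2), b = ln r,
  which the cohort engine uses (:func:`pif_obese_shift`,
  :func:`pif_to_ideal`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .exposure_model import OBESITY_THRESHOLD

REF_BMI = 21.0  # reference exposure for absolute RR reporting
QUAD_LO, QUAD_HI = 10.0, 60.0
_NORMALIZATION_TOL = 1e-4


def rr_at(bmi, rr_per_unit: float, ref_bmi: float = REF_BMI):
    """RR at ``bmi`` relative to ``ref_bmi`` under a log-linear dose-response.

    No floor is applied below the reference: values below ``ref_bmi`` return
    RR < 1.
    """
    if rr_per_unit < 0:
        raise ValueError("rr_per_unit must be >= 0")
    return rr_per_unit ** (np.asarray(bmi, dtype=float) - ref_bmi)


def quad_bounds(dist) -> tuple[float, float]:
    """Integration window for a BMI density: the default [10, 60], widened
    to cover mean +/- 9 sd when the density's normal parameters imply
    non-negligible mass outside it (e.g. sd >= 5 strata)."""
    base = getattr(dist, "base", dist)
    mean = getattr(base, "mean", None)
    sd = getattr(base, "sd", None)
    if mean is None or sd is None:
        return QUAD_LO, QUAD_HI
    shift = getattr(dist, "shift", 0.0)
    return min(QUAD_LO, mean - 9.0 * sd - shift), max(QUAD_HI, mean + 9.0 * sd)


def _quad(f, lo, hi, points=None):
    kw = {"limit": 200}
    if points:
        pts = [p for p in points if lo < p < hi]
        if pts:
            kw["points"] = sorted(pts)
    val, _ = integrate.quad(f, lo, hi, **kw)
    return val


def mean_rr(dist, rr_per_unit: float, ref_bmi: float = REF_BMI) -> float:
    """E[RR(X)] under density ``dist`` by adaptive quadrature on [10, 60].

    ``dist`` must expose ``pdf``; a ``quad_points`` attribute (kink
    locations) is honoured when present, and the window from
    :func:`quad_bounds` is used.  Raises if the density does not integrate
    to one over that window; residual tail mass (< 1e-4) is renormalised
    away.
    """
    points = getattr(dist, "quad_points", None)
    lo, hi = quad_bounds(dist)
    mass = _quad(dist.pdf, lo, hi, points)
    if abs(mass - 1.0) > _NORMALIZATION_TOL:
        raise ValueError(
            f"density integrates to {mass:.8f} over [{lo}, {hi}]; expected 1"
        )
    if rr_per_unit <= 0:
        raise ValueError("rr_per_unit must be > 0 for mean_rr")
    b = np.log(rr_per_unit)
    return _quad(lambda x: dist.pdf(x) * np.exp(b * (x - ref_bmi)), lo, hi, points) / mass


def pif(base, cf, rr_per_unit: float, ref_bmi: float = REF_BMI) -> float:
    """Potential impact fraction of moving exposure from ``base`` to ``cf``."""
    e_base = mean_rr(base, rr_per_unit, ref_bmi)
    if e_base == 0:
        raise ValueError("E_base[RR] is zero")
    e_cf = mean_rr(cf, rr_per_unit, ref_bmi)
    return (e_base - e_cf) / e_base


# ---------------------------------------------------------------------------
# Closed forms for normal exposures (vectorised; used by the cohort engine)


def mean_rr_normal(mu, sd, ln_rr, ref_bmi: float = REF_BMI):
    """E[RR(X)] for X ~ N(mu, sd^2): exp(b (mu - ref) + b^2 sd^2 / 2)."""
    mu, sd, b = np.asarray(mu, float), np.asarray(sd, float), np.asarray(ln_rr, float)
    return np.exp(b * (mu - ref_bmi) + 0.5 * b**2 * sd**2)


def obese_tail_factor(mu, sd, ln_rr, threshold: float = OBESITY_THRESHOLD):
    """RR-weighted share of a normal exposure above ``threshold``.

    Equals E[RR(X); X >= t] / E[RR(X)] = Phi-bar((t - mu - b sd^2) / sd),
    the obese fraction under the RR-tilted (exponentially shifted) density.
    """
    mu, sd, b = np.asarray(mu, float), np.asarray(sd, float), np.asarray(ln_rr, float)
    return stats.norm.sf((threshold - mu - b * sd**2) / sd)


def pif_obese_shift(mu, sd, ln_rr, shift, uptake):
    """PIF when a fraction ``uptake`` of the obese segment of N(mu, sd^2) is
    translated down by ``shift`` BMI units.

    Only the treated mass changes, so
    PIF = uptake * (1 - exp(-b * shift)) * obese_tail_factor.
    Independent of the reference BMI.
    """
    b = np.asarray(ln_rr, float)
    return (
        np.asarray(uptake, float)
        * (1.0 - np.exp(-b * np.asarray(shift, float)))
        * obese_tail_factor(mu, sd, b)
    )


def pif_to_ideal(mu, sd, ln_rr, ideal_mu: float = 21.0, ideal_sd: float = 1.0):
    """PIF of replacing N(mu, sd^2) by the theoretical-minimum N(21, 1)."""
    mu, sd, b = np.asarray(mu, float), np.asarray(sd, float), np.asarray(ln_rr, float)
    return 1.0 - np.exp(b * (ideal_mu - mu) + 0.5 * b**2 * (ideal_sd**2 - sd**2))


def mean_rr_truncated_obese(mu, sd, ln_rr, ref_bmi: float = REF_BMI):
    """E[RR(X)] for the BMI >= 30 segment of N(mu, sd^2), renormalised."""
    mu, sd, b = np.asarray(mu, float), np.asarray(sd, float), np.asarray(ln_rr, float)
    tail = stats.norm.sf((OBESITY_THRESHOLD - mu) / sd)
    return mean_rr_normal(mu, sd, b, ref_bmi) * obese_tail_factor(mu, sd, b) / tail


# ---------------------------------------------------------------------------
# RR schedule handling


def ln_rr_se_from_ci(lo95, hi95):
    """SE of ln RR from a printed 95% CI; zero-width CIs give SE 0."""
    lo = np.asarray(lo95, float)
    hi = np.asarray(hi95, float)
    return (np.log(hi) - np.log(lo)) / (2.0 * 1.959963984540054)


def validate_rr_table(rr: pd.DataFrame) -> None:
    required = {"disease", "sex", "age_lo", "age_hi", "rr", "lo95", "hi95"}
    missing = required - set(rr.columns)
    if missing:
        raise ValueError(f"rr table missing columns: {sorted(missing)}")
    bad = rr[rr["rr"] < 1.0]
    if not bad.empty:
        raise ValueError(f"rr table has entries < 1 at rows {list(bad.index)}")
    if (rr["lo95"] > rr["rr"]).any() or (rr["hi95"] < rr["rr"]).any():
        raise ValueError("rr table confidence bounds do not bracket rr")


def expand_rr_by_age(
    rr: pd.DataFrame, disease: str, sex: str, ages: np.ndarray, ln_rr_shift=None
) -> np.ndarray:
    """Per-single-year ln RR schedule for one disease/sex.

    ``ln_rr_shift``, if given, maps table row index -> additive shift on
    ln RR (used for probabilistic draws).
    """
    rows = rr[(rr["disease"] == disease) & (rr["sex"].isin([sex, "both"]))]
    out = np.zeros(len(ages))  # ln RR = 0 <=> RR = 1
    for idx, row in rows.iterrows():
        # terminal band [lo, 100) also covers the closing age 100
        hi = np.inf if row["age_hi"] >= 100 else row["age_hi"]
        mask = (ages >= row["age_lo"]) & (ages < hi)
        val = np.log(row["rr"])
        if ln_rr_shift is not None and row["rr"] > 1.0:
            val += ln_rr_shift.get(idx, 0.0)
        out[mask] = val
    return out
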