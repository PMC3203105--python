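"""Body-weight trajectories and BMI exposure distributions.

A one-year course of an anti-obesity drug lowers mean body weight in the
treated (obese) segment of the population.  After the intervention year the
lost weight is regained, by default at the empirical rate of 0.385 kg/month,
so that the exposure benefit is transient unless a fraction of the loss is
assumed permanent.  Baseline BMI in each sex/age stratum is modelled as a
normal distribution; the counterfactual (treated) distribution is a mixture
in which the recruited share of the BMI >= 30 mass is translated downwards
by the current weight loss expressed in BMI units (kg divided by height
squared).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

OBESITY_THRESHOLD = 30.0  # kg m^-2

#: Post-intervention regain observed in the STORM maintenance trial (kg/month).
REGAIN_RATE_EMPIRICAL = 0.385
#: Alternative meta-regression maintenance-phase estimate (kg/month).
REGAIN_RATE_META_REGRESSION = 0.0309

# The meta-regression preset carries SD 0.0084; for the empirical preset the
# relative uncertainty is kept, i.e. 0.385 * 0.0084 / 0.0309.
REGAIN_SE_EMPIRICAL = REGAIN_RATE_EMPIRICAL * 0.0084 / REGAIN_RATE_META_REGRESSION
REGAIN_SE_META_REGRESSION = 0.0084


@dataclass(frozen=True)
class WeightEffect:
    """Mean weight-loss trajectory of a one-year drug course.

    Parameters
    ----------
    loss_at_12m:
        Mean reduction in body weight (kg) at the end of the 12-month course.
    loss_se:
        Standard error of that mean, used as the SD of the population-mean
        weight change in probabilistic analyses.
    regain_rate:
        Post-intervention weight regain, kg per month.
    regain_se:
        SD of the regain rate for probabilistic analyses.
    permanent_fraction:
        Share of the 12-month loss that is never regained.
    regain_mode:
        ``"empirical_rate"`` regains at ``regain_rate`` kg/month;
        ``"linear_3yr"`` interpolates the non-permanent loss linearly to zero
        over the 36 months following the course.
    """

    loss_at_12m: float
    loss_se: float = 0.0
    regain_rate: float = REGAIN_RATE_EMPIRICAL
    regain_se: float = REGAIN_SE_EMPIRICAL
    permanent_fraction: float = 0.0
    regain_mode: str = "empirical_rate"

    def __post_init__(self) -> None:
        if self.loss_at_12m < 0:
            raise ValueError("loss_at_12m must be >= 0")
        if self.regain_rate < 0:
            raise ValueError("regain_rate must be >= 0")
        if not 0.0 <= self.permanent_fraction <= 1.0:
            raise ValueError("permanent_fraction must lie in [0, 1]")
        if self.regain_mode not in ("empirical_rate", "linear_3yr"):
            raise ValueError(f"unknown regain_mode {self.regain_mode!r}")


def sibutramine_effect(**overrides) -> WeightEffect:
    """Sibutramine 120 mg daily: 4.45 (SE 0.426) kg at 12 months."""
    return replace(WeightEffect(loss_at_12m=4.45, loss_se=0.426), **overrides)


def orlistat_effect(**overrides) -> WeightEffect:
    """Orlistat 3 x 120 mg daily: 2.89 (SE 0.316) kg at 12 months."""
    return replace(WeightEffect(loss_at_12m=2.89, loss_se=0.316), **overrides)


def loss_at_month(effect: WeightEffect, months) -> np.ndarray | float:
    """Mean kg of weight lost (relative to no intervention) at ``months``.

    Months 0-12 are the intervention year; the loss is assumed to build up
    linearly to ``loss_at_12m``.  Afterwards the non-permanent part is
    regained according to ``regain_mode``, floored at
    ``permanent_fraction * loss_at_12m``.
    """
    m = np.asarray(months, dtype=float)
    L = effect.loss_at_12m
    floor = effect.permanent_fraction * L
    ramp = L * np.clip(m / 12.0, 0.0, 1.0)
    since_end = np.clip(m - 12.0, 0.0, None)
    if effect.regain_mode == "empirical_rate":
        maintained = np.maximum(floor, L - effect.regain_rate * since_end)
    else:  # linear_3yr
        maintained = floor + (L - floor) * np.clip(1.0 - since_end / 36.0, 0.0, 1.0)
    out = np.where(m <= 12.0, ramp, maintained)
    return float(out) if np.isscalar(months) else out


def mean_loss_at_year(effect: WeightEffect, year: int) -> float:
    """Mean kg lost at the end of calendar ``year`` of the model (year 1 =
    intervention year, so year 1 returns the 12-month loss)."""
    if year < 1:
        raise ValueError("year must be >= 1 (year 1 is the intervention year)")
    return float(loss_at_month(effect, 12.0 * year))


def cycle_midpoint_loss(effect: WeightEffect, cycle: int) -> float:
    """Representative kg lost during annual ``cycle`` (0-based; cycle 0 is the
    intervention year), evaluated at the cycle midpoint."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return float(loss_at_month(effect, 12.0 * cycle + 6.0))


def months_to_full_regain(effect: WeightEffect) -> float:
    """Months from the start of treatment until the non-permanent loss is gone
    (``inf`` if the regain rate is zero in empirical mode)."""
    L = effect.loss_at_12m * (1.0 - effect.permanent_fraction)
    if effect.regain_mode == "linear_3yr":
        return 48.0
    if effect.regain_rate == 0.0:
        return float("inf") if L > 0 else 12.0
    return 12.0 + L / effect.regain_rate


# ---------------------------------------------------------------------------
# BMI densities


@dataclass(frozen=True)
class BmiDistribution:
    """Normal BMI density for one sex/age stratum (kg m^-2)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")

    def pdf(self, x):
        return stats.norm.pdf(x, loc=self.mean, scale=self.sd)

    def prob_obese(self) -> float:
        return float(stats.norm.sf(OBESITY_THRESHOLD, loc=self.mean, scale=self.sd))

    @property
    def quad_points(self) -> tuple[float, ...]:
        """Interior anchors so adaptive quadrature resolves narrow densities."""
        return tuple(self.mean + k * self.sd for k in (-6.0, -1.0, 0.0, 1.0, 6.0))


@dataclass(frozen=True)
class ShiftedObeseMixture:
    """Counterfactual density after treating a share of the obese segment.

    The recruited fraction ``uptake`` of the mass above the obesity threshold
    is translated left by ``shift`` BMI units; the remaining mass is
    unchanged.  The density integrates to one by construction.
    """

    base: BmiDistribution
    shift: float
    uptake: float

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if not 0.0 <= self.uptake <= 1.0:
            raise ValueError("uptake must lie in [0, 1]")

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        f = self.base.pdf
        untreated = f(x) * np.where(x >= OBESITY_THRESHOLD, 1.0 - self.uptake, 1.0)
        treated = self.uptake * f(x + self.shift) * (
            x + self.shift >= OBESITY_THRESHOLD
        )
        return untreated + treated

    @property
    def quad_points(self) -> tuple[float, ...]:
        """Kink locations and the base mode, for adaptive quadrature."""
        return (OBESITY_THRESHOLD - self.shift, OBESITY_THRESHOLD, self.base.mean)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        x = rng.normal(self.base.mean, self.base.sd, size)
        treated = (x >= OBESITY_THRESHOLD) & (rng.random(size) < self.uptake)
        return np.where(treated, x - self.shift, x)


def shift_obese_distribution(
    base: BmiDistribution, loss_kg: float, uptake: float, height: float
) -> ShiftedObeseMixture:
    """Translate the treated obese segment left by ``loss_kg / height**2``."""
    if height <= 0:
        raise ValueError("height must be > 0")
    if loss_kg < 0:
        raise ValueError("loss_kg must be >= 0")
    return ShiftedObeseMixture(base=base, shift=loss_kg / height**2, uptake=uptake)


def ideal_distribution() -> BmiDistribution:
    """Theoretical-minimum-risk BMI distribution: N(21, 1), all strata."""
    return BmiDistribution(mean=21.0, sd=1.0)
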