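"""Cost-effectiveness analysis: ICERs, Monte Carlo uncertainty, sensitivity.

The incremental cost-effectiveness ratio is the discounted net cost of the
intervention (intervention cost plus cost offsets, optionally patient
time/travel and unrelated costs in added years) divided by the DALYs
averted, as a *ratio of means* across Monte Carlo draws; uncertainty
intervals are the 2.5th/97.5th percentiles of the per-draw quantities.
Reported ratios are rounded to two significant figures; a non-positive
health gain yields the ``inf`` sentinel ("dominated").

Three cumulative costing perspectives are evaluated:

* ``health_sector``   - intervention costs + disease cost offsets
* ``plus_patient``    - ... + participants' time and travel
* ``plus_unrelated``  - ... + unrelated health-care costs in added years

The univariate sensitivity grid re-runs the deterministic pipeline under
alternative weight-regain assumptions, a per-BMI-unit utility weight, no
discounting, a disease-free baseline, and age-decade subgroups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import costing, exposure_model, multistate_lifetable as mslt, risk_engine

CE_THRESHOLD = 50_000.0  # AUD per DALY
PERSPECTIVES = ("health_sector", "plus_patient", "plus_unrelated")


@dataclass(frozen=True)
class ScenarioConfig:
    """One model scenario.

    ``age_group`` restricts benefits, costs and starters to cohorts whose
    5-year band lower bound lies in [lo, hi).  ``regain_scale`` multiplies
    the regain rate (0.5 = "regain halved").  ``bmi_utility`` adds QALYs of
    that utility weight per discounted BMI-unit-year of exposure reduction
    to the effect measure.
    """

    drug: str = "sibutramine"  # sibutramine | orlistat | none
    discount_rate: float = 0.03
    uptake: float | None = None  # default: recruitment_fraction()
    regain_scale: float = 1.0
    regain_mode: str = "empirical_rate"
    permanent_fraction: float = 0.0
    bmi_utility: float = 0.0
    disease_free_baseline: bool = False
    age_group: tuple | None = None
    loss_kg: float | None = None
    loss_se: float | None = None
    regain_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drug not in ("sibutramine", "orlistat", "none"):
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")

    def weight_effect(self) -> exposure_model.WeightEffect:
        if self.drug == "sibutramine":
            eff = exposure_model.sibutramine_effect()
        elif self.drug == "orlistat":
            eff = exposure_model.orlistat_effect()
        else:
            eff = exposure_model.WeightEffect(loss_at_12m=0.0)
        over: dict = {
            "regain_rate": (
                self.regain_rate if self.regain_rate is not None else eff.regain_rate
            )
            * self.regain_scale,
            "regain_mode": self.regain_mode,
            "permanent_fraction": self.permanent_fraction,
        }
        if self.loss_kg is not None:
            over["loss_at_12m"] = self.loss_kg
        if self.loss_se is not None:
            over["loss_se"] = self.loss_se
        return replace(eff, **over)

    def cost_params(self) -> tuple[costing.CostParams, costing.AttritionSpec] | None:
        if self.drug == "sibutramine":
            return costing.sibutramine_costs(), costing.sibutramine_attrition()
        if self.drug == "orlistat":
            return costing.orlistat_costs(), costing.orlistat_attrition()
        return None

    def effective_uptake(self) -> float:
        return self.uptake if self.uptake is not None else costing.recruitment_fraction()


@dataclass
class ParameterDraw:
    """One Monte Carlo parameter draw (held common across arms)."""

    loss_kg: float | None = None
    regain_rate: float | None = None
    ln_rr_shift: dict = field(default_factory=dict)  # rr-table row index -> shift
    minutes_initial: float | None = None
    minutes_followup: float | None = None
    travel_minutes: float | None = None


def draw_parameters(
    rng: np.random.Generator,
    effect: exposure_model.WeightEffect,
    costs: costing.CostParams,
    rr_table: pd.DataFrame,
) -> ParameterDraw:
    """Sample the uncertain parameters: normal weight loss and regain rate
    (truncated at 0), normal ln RR per table entry, triangular GP/travel
    minutes.  Drug prices carry no distribution."""
    shift = {}
    for idx, row in rr_table.iterrows():
        if row["rr"] > 1.0:
            se = float(risk_engine.ln_rr_se_from_ci(row["lo95"], row["hi95"]))
            shift[idx] = rng.normal(0.0, se) if se > 0 else 0.0
    return ParameterDraw(
        loss_kg=max(0.0, rng.normal(effect.loss_at_12m, effect.loss_se)),
        regain_rate=max(0.0, rng.normal(effect.regain_rate, effect.regain_se)),
        ln_rr_shift=shift,
        minutes_initial=costs.minutes_initial.draw(rng),
        minutes_followup=costs.minutes_followup.draw(rng),
        travel_minutes=costs.travel_minutes.draw(rng),
    )


class PreparedWorld:
    """Per-sex model arrays plus cached reference-arm simulations."""

    def __init__(self, world):
        self.world = world
        self.sex_arrays = {
            sex: mslt.build_sex_arrays(world, sex) for sex in ("male", "female")
        }
        self.cost_arrays = {
            sex: costing.cost_arrays(world.disease_costs, sex, sa.diseases)
            for sex, sa in self.sex_arrays.items()
        }
        # per sex/disease: list of (rr-table row index, age mask, ln-RR SE)
        self.rr_draw_info = {}
        for sex, sa in self.sex_arrays.items():
            info = []
            for masks in sa.ln_rr_rows:
                entries = []
                for idx, mask in masks:
                    row = world.rr_table.loc[idx]
                    se = float(risk_engine.ln_rr_se_from_ci(row["lo95"], row["hi95"]))
                    entries.append((idx, mask, se))
                info.append(entries)
            self.rr_draw_info[sex] = info
        self._ref_streams: dict = {}
        self._ref_agg: dict = {}

    def reference_streams(self, disease_free: bool) -> dict:
        if disease_free not in self._ref_streams:
            self._ref_streams[disease_free] = {
                sex: mslt.simulate_arm(
                    sa, prev0=np.zeros_like(sa.prev0) if disease_free else None
                )
                for sex, sa in self.sex_arrays.items()
            }
        return self._ref_streams[disease_free]

    def reference_aggregates(self, scenario: ScenarioConfig) -> dict:
        key = (scenario.disease_free_baseline, scenario.discount_rate, scenario.age_group)
        if key not in self._ref_agg:
            refs = self.reference_streams(scenario.disease_free_baseline)
            self._ref_agg[key] = {
                sex: mslt.aggregate_arm(
                    refs[sex],
                    self.sex_arrays[sex],
                    scenario.discount_rate,
                    self.cohort_mask(sex, scenario.age_group),
                )
                for sex in self.sex_arrays
            }
        return self._ref_agg[key]

    def cohort_mask(self, sex: str, age_group: tuple | None):
        if age_group is None:
            return None
        lo, hi = age_group
        band = self.sex_arrays[sex].cohort_age_lo
        return (band >= lo) & (band < hi)

    def ln_rr_with_draw(self, sex: str, draw: ParameterDraw | None) -> np.ndarray:
        sa = self.sex_arrays[sex]
        if draw is None or not draw.ln_rr_shift:
            return sa.ln_rr
        b = sa.ln_rr.copy()
        for d, entries in enumerate(self.rr_draw_info[sex]):
            for idx, mask, _se in entries:
                b[d, mask] += draw.ln_rr_shift.get(idx, 0.0)
        return b


@dataclass
class PointOutcome:
    """Deterministic (or single-draw) pipeline result."""

    dalys: float
    effect_measure: float  # dalys (+ BMI utility QALYs if enabled)
    starters: float
    intervention_health: float
    patient_cost: float
    offsets: float
    unrelated: float
    bmi_unit_years: float

    def net_cost(self, perspective: str) -> float:
        net = self.intervention_health + self.offsets
        if perspective in ("plus_patient", "plus_unrelated"):
            net += self.patient_cost
        if perspective == "plus_unrelated":
            net += self.unrelated
        return net

    def icer(self, perspective: str) -> float:
        return icer(self.net_cost(perspective), self.effect_measure)


def icer(net_cost: float, dalys_averted: float) -> float:
    """Cost per DALY averted; ``inf`` sentinel when no health gain."""
    if dalys_averted <= 0:
        return math.inf
    return net_cost / dalys_averted


def round_2sf(x: float) -> float:
    """Two-significant-figure rounding used for reported ratios."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp + 1)


def add_bmi_utility(
    dalys: float, bmi_unit_years: float, utility: float = 0.017
) -> float:
    """Add QALYs of ``utility`` per (discounted) BMI-unit-year averted."""
    if utility < 0:
        raise ValueError("utility must be >= 0")
    return dalys + utility * bmi_unit_years


def evaluate_scenario(
    prepared: PreparedWorld,
    scenario: ScenarioConfig,
    draw: ParameterDraw | None = None,
) -> PointOutcome:
    """Run the full pipeline once for a scenario (and optional draw)."""
    if scenario.drug == "none":
        return PointOutcome(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    effect = scenario.weight_effect()
    if draw is not None:
        effect = replace(
            effect,
            loss_at_12m=draw.loss_kg if draw.loss_kg is not None else effect.loss_at_12m,
            regain_rate=(
                draw.regain_rate if draw.regain_rate is not None else effect.regain_rate
            )
            * scenario.regain_scale,
        )
    uptake = scenario.effective_uptake()
    costs, attr = scenario.cost_params()
    refs = prepared.reference_streams(scenario.disease_free_baseline)
    ref_aggs = prepared.reference_aggregates(scenario)

    dalys = 0.0
    starters = 0.0
    bmi_unit_years = 0.0
    offsets = 0.0
    unrelated = 0.0
    for sex, sa in prepared.sex_arrays.items():
        mask = prepared.cohort_mask(sex, scenario.age_group)
        T = refs[sex].L.shape[0]
        loss_kg_t = np.array(
            [exposure_model.cycle_midpoint_loss(effect, t) for t in range(T)]
        )
        delta_units = loss_kg_t / sa.height**2
        b = prepared.ln_rr_with_draw(sex, draw)
        tail = risk_engine.obese_tail_factor(sa.mu_bmi, sa.sd_bmi, b)

        def pif_fn(t, idx, _b=b, _tail=tail, _du=delta_units):
            if _du[t] == 0.0:
                return 0.0
            return uptake * _tail[:, idx] * (1.0 - np.exp(-_b[:, idx] * _du[t]))

        prev0 = np.zeros_like(sa.prev0) if scenario.disease_free_baseline else None
        int_streams = mslt.simulate_arm(sa, pif_fn, ref=refs[sex], prev0=prev0)
        int_agg = mslt.aggregate_arm(int_streams, sa, scenario.discount_rate, mask)
        ref_agg = ref_aggs[sex]
        dalys += int_agg.lw - ref_agg.lw
        offsets += costing.cost_offsets(
            ref_agg.incident - int_agg.incident,
            ref_agg.prev_py - int_agg.prev_py,
            prepared.cost_arrays[sex],
        )
        unrelated += costing.unrelated_costs_in_added_years(
            int_agg.py - ref_agg.py, prepared.cost_arrays[sex]
        )
        w = sa.cohort_n * sa.p_obese[sa.cohort_start_idx] * uptake
        if mask is not None:
            w = w * mask
        starters += float(w.sum())
        disc = (1.0 + scenario.discount_rate) ** -np.arange(T)
        bmi_unit_years += float(
            np.einsum("t,tc,c->", disc * delta_units, int_streams.l_start, w)
        )

    kw = {}
    if draw is not None:
        kw = {
            "minutes_initial": draw.minutes_initial,
            "minutes_followup": draw.minutes_followup,
            "travel_minutes": draw.travel_minutes,
        }
    comp = costing.intervention_cost_components(costs, attr, **kw)
    effect_measure = dalys
    if scenario.bmi_utility > 0:
        effect_measure = add_bmi_utility(dalys, bmi_unit_years, scenario.bmi_utility)
    return PointOutcome(
        dalys=dalys,
        effect_measure=effect_measure,
        starters=starters,
        intervention_health=comp["health_sector"] * starters,
        patient_cost=comp["patient_time_travel"] * starters,
        offsets=offsets,
        unrelated=unrelated,
        bmi_unit_years=bmi_unit_years,
    )


def ideal_burden(prepared: PreparedWorld, discount_rate: float = 0.03) -> float:
    """DALYs gained under the theoretical-minimum scenario: the whole
    population at BMI N(21, 1) for the rest of their lifetime."""
    refs = prepared.reference_streams(False)
    total = 0.0
    for sex, sa in prepared.sex_arrays.items():
        pif = risk_engine.pif_to_ideal(sa.mu_bmi, sa.sd_bmi, sa.ln_rr)

        def pif_fn(t, idx, _p=pif):
            return _p[:, idx]

        streams = mslt.simulate_arm(sa, pif_fn, ref=refs[sex])
        agg = mslt.aggregate_arm(streams, sa, discount_rate)
        ref_agg = mslt.aggregate_arm(refs[sex], sa, discount_rate)
        total += agg.lw - ref_agg.lw
    return total


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class CeaResult:
    """Point estimates with 95% uncertainty intervals.

    ``dalys``, ``cost_components`` and ``net_cost`` entries are (mean, lo,
    hi); ``icers`` maps perspective -> (ratio-of-means, lo, hi) where the
    interval comes from the per-iteration ratio distribution; ``p_cost_
    effective`` is the share of iterations below the A$50,000/DALY
    threshold.
    """

    dalys: tuple
    cost_components: dict
    icers: dict
    p_cost_effective: dict
    starters: float
    burden_fraction: float | None = None
    n_iter: int = 0
    seed: int | None = None

    def icer_point(self, perspective: str = "health_sector") -> float:
        return self.icers[perspective][0]


def _summary(draws: np.ndarray) -> tuple:
    return (
        float(np.mean(draws)),
        float(np.percentile(draws, 2.5)),
        float(np.percentile(draws, 97.5)),
    )


def run_psa(
    prepared: PreparedWorld,
    scenario: ScenarioConfig,
    n_iter: int = 2000,
    seed: int | None = None,
) -> CeaResult:
    """Monte Carlo uncertainty analysis.

    Draws are held common across the reference and intervention arms of an
    iteration (the reference arm is deterministic, so coherence is automatic
    for the incremental comparison).  The ICER point estimate is the ratio
    of means; its interval is percentile-based on the per-iteration ratios.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2 for uncertainty intervals")
    if seed is None:
        seed = scenario.seed
    rng = np.random.default_rng(seed)
    effect = scenario.weight_effect()
    params = scenario.cost_params()
    if params is None:
        raise ValueError("PSA requires a drug scenario")
    costs, _ = params
    dalys = np.empty(n_iter)
    effect_m = np.empty(n_iter)
    comp = {k: np.empty(n_iter) for k in ("intervention_health", "patient", "offsets", "unrelated")}
    net = {p: np.empty(n_iter) for p in PERSPECTIVES}
    ratios = {p: np.empty(n_iter) for p in PERSPECTIVES}
    starters = 0.0
    for k in range(n_iter):
        draw = draw_parameters(rng, effect, costs, prepared.world.rr_table)
        out = evaluate_scenario(prepared, scenario, draw)
        dalys[k] = out.dalys
        effect_m[k] = out.effect_measure
        comp["intervention_health"][k] = out.intervention_health
        comp["patient"][k] = out.patient_cost
        comp["offsets"][k] = out.offsets
        comp["unrelated"][k] = out.unrelated
        starters = out.starters
        for p in PERSPECTIVES:
            net[p][k] = out.net_cost(p)
            ratios[p][k] = icer(net[p][k], out.effect_measure)
    icers = {}
    p_ce = {}
    for p in PERSPECTIVES:
        point = icer(float(net[p].mean()), float(effect_m.mean()))
        finite = ratios[p][np.isfinite(ratios[p])]
        if len(finite):
            lo, hi = np.percentile(finite, [2.5, 97.5])
        else:
            lo = hi = math.inf
        icers[p] = (point, float(lo), float(hi))
        p_ce[p] = float(np.mean(ratios[p] < CE_THRESHOLD))
    components = {
        "dalys": _summary(dalys),
        "effect_measure": _summary(effect_m),
        "intervention_health": _summary(comp["intervention_health"]),
        "patient_time_travel": _summary(comp["patient"]),
        "cost_offsets": _summary(comp["offsets"]),
        "unrelated_added_years": _summary(comp["unrelated"]),
    }
    return CeaResult(
        dalys=components["dalys"],
        cost_components=components,
        icers=icers,
        p_cost_effective=p_ce,
        starters=starters,
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Univariate sensitivity grid


SENSITIVITY_SCENARIOS = (
    "base",
    "regain_halved",
    "linear_3yr",
    "permanent_23pct",
    "utility_0.017_per_BMI",
    "discount_0",
    "disease_free_baseline",
    "age_20_29",
    "age_30_39",
    "age_40_49",
    "age_50_59",
    "age_60_69",
    "age_70_79",
)


def sensitivity_scenario(base: ScenarioConfig, key: str) -> ScenarioConfig:
    if key == "base":
        return base
    if key == "regain_halved":
        return replace(base, regain_scale=0.5)
    if key == "linear_3yr":
        return replace(base, regain_mode="linear_3yr")
    if key == "permanent_23pct":
        return replace(base, permanent_fraction=0.23)
    if key == "utility_0.017_per_BMI":
        return replace(base, bmi_utility=0.017)
    if key == "discount_0":
        return replace(base, discount_rate=0.0)
    if key == "disease_free_baseline":
        return replace(base, disease_free_baseline=True)
    if key.startswith("age_"):
        lo, hi = key.split("_")[1:]
        return replace(base, age_group=(int(lo), int(hi) + 1))
    raise ValueError(f"unknown sensitivity scenario {key!r}")


def run_sensitivity_grid(
    prepared: PreparedWorld,
    base: ScenarioConfig,
    scenarios=SENSITIVITY_SCENARIOS,
    perspective: str = "plus_unrelated",
) -> pd.DataFrame:
    """Deterministic univariate sensitivity table (one row per scenario).

    ICERs use the widest perspective (patient time/travel and unrelated
    costs in added years included) unless told otherwise.
    """
    rows = []
    for key in scenarios:
        out = evaluate_scenario(prepared, sensitivity_scenario(base, key))
        rows.append(
            {
                "scenario": key,
                "dalys_averted": out.effect_measure,
                "net_cost": out.net_cost(perspective),
                "icer": out.icer(perspective),
            }
        )
    return pd.DataFrame(rows)
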