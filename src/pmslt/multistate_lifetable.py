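"""Proportional multi-state life table (PMSLT) cohort engine.

The population is split into sex x 5-year cohorts that are followed in
annual cycles from their 2003 midpoint age until age 100.  Each cohort
carries a life table (survivorship l, total mortality q, person-years L
with half-cycle correction, disability-adjusted person-years Lw) and nine
parallel disease sub-models.  An intervention changes disease incidence via
potential impact fractions; the resulting prevalence and disease-mortality
deltas feed back proportionally into total mortality and the average
disability rate:

    q_int(a) = q(a) - sum_d [mort_d_ref(a) - mort_d_int(a)]   (clamped at 0)
    d_int(a) = d_base(a) - sum_d [prev_ref - prev_int] * w_d  (clamped to [0,1])

DALYs averted are the discounted difference in disability-adjusted
person-years between the intervention and reference populations, weighted
by cohort size.  Streams needed for costing (incident cases, prevalent
case-years, person-years) are accumulated into the cost-table age buckets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pmslt")

MAX_AGE = 100
AGES = np.arange(20, MAX_AGE + 1)  # 81 single-year ages
N_AGES = len(AGES)
COST_AGE_EDGES = (55, 65, 75, 85)  # buckets <55, 55-64, 65-74, 75-84, 85+
N_BUCKETS = 5


def cost_bucket_of_age(ages) -> np.ndarray:
    return np.searchsorted(COST_AGE_EDGES, np.asarray(ages), side="right")


@dataclass
class SexArrays:
    """Single-year-age model inputs for one sex, plus cohort structure."""

    sex: str
    mortality: np.ndarray        # all-cause annual mortality risk, by age
    yld_base: np.ndarray         # baseline disability (YLD) rate, by age
    mu_bmi: np.ndarray           # normal BMI mean, by age
    sd_bmi: np.ndarray           # normal BMI sd, by age
    p_obese: np.ndarray          # P(BMI >= 30), by age
    height: float                # m, for kg -> BMI-unit conversion
    diseases: list               # disease names, fixed order
    incidence: np.ndarray        # (n_dis, n_ages)
    case_fatality: np.ndarray    # (n_dis, n_ages)
    remission: np.ndarray        # (n_dis, n_ages)
    weights: np.ndarray          # (n_dis,) disability weights
    ln_rr: np.ndarray            # (n_dis, n_ages) point log relative risks
    ln_rr_rows: list             # per disease: list of (row_index, age_mask)
    prev0: np.ndarray            # (n_dis, n_ages) baseline prevalence by age
    cohort_start_idx: np.ndarray  # (n_coh,) index into AGES of cohort midpoint
    cohort_n: np.ndarray         # (n_coh,) persons per cohort
    cohort_age_lo: np.ndarray    # (n_coh,) band lower bound, for subgrouping

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_start_idx)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)


def _band_index(ages, band_lo) -> np.ndarray:
    """Map single-year ages onto rows of a sorted 5-year-band table."""
    return np.clip((np.asarray(ages) - 20) // 5, 0, len(band_lo) - 1)


def build_sex_arrays(world, sex: str, yld_base: np.ndarray | None = None) -> SexArrays:
    """Expand a :class:`~pmslt.cli_io.World` into per-single-year arrays."""
    from . import disease_models, risk_engine, synthetic_data

    pop = world.population[world.population["sex"] == sex].sort_values("age_lo")
    bmi = world.bmi_params[world.bmi_params["sex"] == sex].sort_values("age_lo")
    bidx = _band_index(AGES, pop["age_lo"].to_numpy())

    mortality = pop["mortality_rate"].to_numpy()[bidx]
    mu = bmi["mean_bmi"].to_numpy()[bidx]
    sd = bmi["sd_bmi"].to_numpy()[bidx]
    from scipy import stats as _st

    p_obese = _st.norm.sf(30.0, mu, sd)
    height = float(bmi["mean_height"].iloc[0])
    if yld_base is None:
        yld_base = synthetic_data.baseline_yld_rate(AGES)

    diseases = list(dict.fromkeys(world.disease_epi["disease"]))
    n_dis = len(diseases)
    incidence = np.zeros((n_dis, N_AGES))
    case_fatality = np.zeros((n_dis, N_AGES))
    remission = np.zeros((n_dis, N_AGES))
    weights = np.zeros(n_dis)
    ln_rr = np.zeros((n_dis, N_AGES))
    ln_rr_rows: list = []
    wtab = world.disability_weights
    for d, disease in enumerate(diseases):
        sub = world.disease_epi[
            (world.disease_epi["disease"] == disease) & (world.disease_epi["sex"] == sex)
        ].sort_values("age_lo")
        sidx = _band_index(AGES, sub["age_lo"].to_numpy())
        incidence[d] = sub["incidence"].to_numpy()[sidx]
        case_fatality[d] = sub["case_fatality"].to_numpy()[sidx]
        remission[d] = sub["remission"].to_numpy()[sidx]
        wrow = wtab[(wtab["disease"] == disease) & (wtab["sex"] == sex)]
        weights[d] = float(wrow["weight"].iloc[0]) if len(wrow) else 0.0
        ln_rr[d] = risk_engine.expand_rr_by_age(world.rr_table, disease, sex, AGES)
        rows = world.rr_table[
            (world.rr_table["disease"] == disease)
            & (world.rr_table["sex"].isin([sex, "both"]))
        ]
        masks = [
            (
                idx,
                (AGES >= row["age_lo"])
                & (AGES < (np.inf if row["age_hi"] >= 100 else row["age_hi"])),
            )
            for idx, row in rows.iterrows()
            if row["rr"] > 1.0
        ]
        ln_rr_rows.append(masks)

    prev0 = np.stack(
        [
            disease_models.prevalence_from_rates(incidence[d], case_fatality[d], remission[d])
            for d in range(n_dis)
        ]
    )
    age_lo = pop["age_lo"].to_numpy()
    start_ages = age_lo + 2  # integer cohort midpoint age in 2003
    return SexArrays(
        sex=sex,
        mortality=mortality,
        yld_base=np.asarray(yld_base, float),
        mu_bmi=mu,
        sd_bmi=sd,
        p_obese=p_obese,
        height=height,
        diseases=diseases,
        incidence=incidence,
        case_fatality=case_fatality,
        remission=remission,
        weights=weights,
        ln_rr=ln_rr,
        ln_rr_rows=ln_rr_rows,
        prev0=prev0,
        cohort_start_idx=(start_ages - 20).astype(int),
        cohort_n=pop["count"].to_numpy(),
        cohort_age_lo=age_lo.astype(int),
    )


@dataclass
class Streams:
    """Undiscounted per-cycle streams for one simulated arm.

    Arrays are indexed [t, cohort] or [t, disease, cohort]; entries for
    cycles after a cohort reaches age 100 are zero (``active`` is False).
    """

    l_start: np.ndarray      # survivorship entering cycle t
    q: np.ndarray            # total mortality risk applied in cycle t
    L: np.ndarray            # person-years lived in cycle t (half-cycle)
    disability: np.ndarray   # disability rate in cycle t
    Lw: np.ndarray           # disability-adjusted person-years
    C: np.ndarray            # start-of-cycle disease prevalence
    mort_d: np.ndarray       # disease-death rate C*f in cycle t
    inc_rate: np.ndarray     # incident-case rate S*i_eff in cycle t
    active: np.ndarray       # bool [t, cohort]
    clamp_events: int = 0


def simulate_arm(
    sa: SexArrays,
    pif_fn=None,
    ref: Streams | None = None,
    prev0: np.ndarray | None = None,
) -> Streams:
    """Run all cohorts of one sex to age 100.

    ``pif_fn(t, age_idx) -> (n_dis, len(age_idx))`` gives the potential
    impact fraction applied to incidence in cycle ``t`` for cohorts whose
    current-age indices are ``age_idx``; ``None`` means the reference arm.
    ``ref`` supplies the reference streams whose disease-mortality and
    prevalence deltas are linked to this arm's life table.
    """
    n_c, n_d = sa.n_cohorts, sa.n_diseases
    T = N_AGES - 1 - int(sa.cohort_start_idx.min())  # max number of cycles
    l_start = np.zeros((T, n_c))
    q_arr = np.zeros((T, n_c))
    L_arr = np.zeros((T, n_c))
    dis_arr = np.zeros((T, n_c))
    Lw_arr = np.zeros((T, n_c))
    C_arr = np.zeros((T, n_d, n_c))
    mort_arr = np.zeros((T, n_d, n_c))
    inc_arr = np.zeros((T, n_d, n_c))
    active_arr = np.zeros((T, n_c), dtype=bool)

    if prev0 is None:
        prev0 = sa.prev0
    C = prev0[:, sa.cohort_start_idx].copy()  # (n_d, n_c)
    l = np.ones(n_c)
    clamps = 0
    for t in range(T):
        age_idx = sa.cohort_start_idx + t
        active = age_idx <= N_AGES - 2  # cycle spans age a -> a+1, a <= 99
        if not active.any():
            break
        idx = np.where(active, age_idx, 0)
        i_t = sa.incidence[:, idx]
        f_t = sa.case_fatality[:, idx]
        r_t = sa.remission[:, idx]
        if pif_fn is not None:
            pif = pif_fn(t, idx)
            i_eff = i_t * (1.0 - pif)
        else:
            i_eff = i_t
        S = 1.0 - C
        inc_flow = S * i_eff
        mort_d = C * f_t
        C_next = C + inc_flow - C * r_t - mort_d

        q = sa.mortality[idx].copy()
        disability = sa.yld_base[idx].copy()
        if ref is not None:
            delta_mort = (ref.mort_d[t] - mort_d).sum(axis=0)
            q_new = q - delta_mort
            n_clamp = int((q_new < 0).sum())
            if n_clamp:
                clamps += n_clamp
            q = np.clip(q_new, 0.0, 1.0)
            delta_prev = ((ref.C[t] - C) * sa.weights[:, None]).sum(axis=0)
            disability = np.clip(disability - delta_prev, 0.0, 1.0)

        L = l * (1.0 - q / 2.0)
        Lw = L * (1.0 - disability)

        l_start[t] = np.where(active, l, 0.0)
        q_arr[t] = np.where(active, q, 0.0)
        L_arr[t] = np.where(active, L, 0.0)
        dis_arr[t] = np.where(active, disability, 0.0)
        Lw_arr[t] = np.where(active, Lw, 0.0)
        C_arr[t] = np.where(active, C, 0.0)
        mort_arr[t] = np.where(active, mort_d, 0.0)
        inc_arr[t] = np.where(active, inc_flow, 0.0)
        active_arr[t] = active

        l = np.where(active, l * (1.0 - q), l)
        C = np.where(active, C_next, C)

    if clamps:
        logger.warning(
            "%s: total-mortality clamped at 0 in %d cohort-cycles", sa.sex, clamps
        )
    return Streams(
        l_start=l_start,
        q=q_arr,
        L=L_arr,
        disability=dis_arr,
        Lw=Lw_arr,
        C=C_arr,
        mort_d=mort_arr,
        inc_rate=inc_arr,
        active=active_arr,
        clamp_events=clamps,
    )


@dataclass
class ArmAggregate:
    """Discounted, cohort-weighted totals for one arm."""

    lw: float                 # disability-adjusted person-years (discounted)
    py: np.ndarray            # person-years by cost age bucket (5,)
    incident: np.ndarray      # incident cases by (disease, bucket)
    prev_py: np.ndarray       # prevalent case-years by (disease, bucket)


def aggregate_arm(
    streams: Streams, sa: SexArrays, discount_rate: float, cohort_mask=None
) -> ArmAggregate:
    """Discount and population-weight an arm's streams.

    Discounting is referenced to the intervention year (cycle 0 is
    undiscounted); ``cohort_mask`` restricts to a subset of cohorts (age
    subgroup analyses).
    """
    T, n_c = streams.L.shape
    disc = (1.0 + discount_rate) ** -np.arange(T)
    w = sa.cohort_n.astype(float)
    if cohort_mask is not None:
        w = w * np.asarray(cohort_mask, float)
    lw = float(np.einsum("t,tc,c->", disc, streams.Lw, w))
    bucket = cost_bucket_of_age(20 + sa.cohort_start_idx[None, :] + np.arange(T)[:, None])
    wt = disc[:, None] * w[None, :]  # (T, n_c)
    py = np.zeros(N_BUCKETS)
    np.add.at(py, bucket, streams.L * wt)
    n_d = sa.n_diseases
    incident = np.zeros((n_d, N_BUCKETS))
    prev_py = np.zeros((n_d, N_BUCKETS))
    d_idx = np.broadcast_to(np.arange(n_d)[None, :, None], (T, n_d, n_c))
    b_idx = np.broadcast_to(bucket[:, None, :], (T, n_d, n_c))
    np.add.at(incident, (d_idx, b_idx), streams.inc_rate * streams.l_start[:, None, :] * wt[:, None, :])
    np.add.at(prev_py, (d_idx, b_idx), streams.C * streams.L[:, None, :] * wt[:, None, :])
    return ArmAggregate(lw=lw, py=py, incident=incident, prev_py=prev_py)


def dalys_averted_from_aggregates(ref: ArmAggregate, intervention: ArmAggregate) -> float:
    return intervention.lw - ref.lw


def lifetable_frame(streams: Streams, sa: SexArrays) -> pd.DataFrame:
    """Per-cohort life table as a tidy frame (sex, cohort, age, l, m, d, L, Lw)."""
    T, n_c = streams.L.shape
    recs = []
    for c in range(n_c):
        t_alive = np.where(streams.active[:, c])[0]
        ages = 20 + sa.cohort_start_idx[c] + t_alive
        recs.append(
            pd.DataFrame(
                {
                    "sex": sa.sex,
                    "cohort": 20 + sa.cohort_start_idx[c],
                    "age": ages,
                    "l": streams.l_start[t_alive, c],
                    "m": streams.q[t_alive, c],
                    "d": streams.disability[t_alive, c],
                    "L": streams.L[t_alive, c],
                    "Lw": streams.Lw[t_alive, c],
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def dalys_averted(
    ref: pd.DataFrame,
    intervention: pd.DataFrame,
    discount_rate: float = 0.03,
    cohort_weights: dict | None = None,
) -> float:
    """Discounted DALYs averted from two tidy life tables.

    Both tables must share the (sex, cohort, age) grid; ``cohort_weights``
    maps (sex, cohort start age) -> persons (default 1 per cohort).  Time is
    measured from the intervention year: t = age - cohort start age.
    """
    key = ["sex", "cohort", "age"]
    a = ref.sort_values(key).reset_index(drop=True)
    b = intervention.sort_values(key).reset_index(drop=True)
    if len(a) != len(b) or not (a[key].values == b[key].values).all():
        raise ValueError("life tables have mismatched cohort/age grids")
    t = (a["age"] - a["cohort"]).to_numpy()
    disc = (1.0 + discount_rate) ** -t
    if cohort_weights is None:
        w = np.ones(len(a))
    else:
        w = np.array([cohort_weights[(s, c)] for s, c in zip(a["sex"], a["cohort"])])
    return float(((b["Lw"].to_numpy() - a["Lw"].to_numpy()) * disc * w).sum())


def burden_fraction_averted(intervention_dalys: float, ideal_dalys: float) -> float:
    """Intervention health gain as a share of the theoretical-minimum gain."""
    if ideal_dalys <= 0:
        raise ValueError("ideal_dalys must be > 0")
    return intervention_dalys / ideal_dalys


def life_expectancy(q_by_age: np.ndarray, discount_rate: float = 0.0) -> float:
    """Life expectancy from a vector of annual mortality risks (half-cycle
    person-years, truncated when the vector ends)."""
    q = np.asarray(q_by_age, float)
    l = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    L = (l[:-1] + l[1:]) / 2.0
    disc = (1.0 + discount_rate) ** -np.arange(len(L))
    return float((L * disc).sum())
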