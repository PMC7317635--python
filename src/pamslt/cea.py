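"""Costing and cost-effectiveness analysis.

Turns paired BAU/intervention life-table runs into health-system cost
streams and summary measures: disease cost offsets (phase costs applied
to changes in incident cases, prevalent person-years, and disease-cause
deaths), unrelated health-system costs on incremental life years (people
who live longer keep using the health system), net cost, the incremental
cost-effectiveness ratio (ICER), and the equity adjustment that evaluates
the indigenous group's gains against reference-group background rates.

All monetary amounts are 2011 NZ$; QALYs and costs are discounted to the
intervention year (year 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lifetable import RunOutput, StratumKey, discount_factors
from .intervention import InterventionSpec, intervention_cost_stream

__all__ = [
    "CeaResult",
    "CostingError",
    "compute_icer",
    "disease_cost_offsets",
    "unrelated_costs",
    "equity_adjust",
    "run_cea",
    "AGE_GROUPS",
]

#: baseline-age reporting groups (lower inclusive, upper exclusive)
AGE_GROUPS: Tuple[Tuple[int, int], ...] = ((0, 40), (40, 60), (60, 80), (80, 110))

FLAG_OK = ""
FLAG_COST_SAVING = "cost-saving"
FLAG_DOMINATED = "dominated"
FLAG_UNDEFINED = "undefined"
FLAG_SOUTHWEST = "less-effective-cheaper"


class CostingError(ValueError):
    """Missing or inconsistent costing inputs."""


def compute_icer(net_cost: float, qaly_gain: float) -> Tuple[float, str]:
    """ICER with quadrant flags.

    Returns ``(icer, flag)``: the plain ratio when QALYs are gained; the
    ``cost-saving`` flag (dominant quadrant) when the intervention both
    saves money and gains health; ``dominated`` when it costs more and
    loses health; ``undefined`` (ICER = nan) at exactly zero QALY change.
    """
    if not (np.isfinite(net_cost) and np.isfinite(qaly_gain)):
        raise CostingError("net cost and QALY gain must be finite")
    if qaly_gain == 0.0:
        return float("nan"), FLAG_UNDEFINED
    icer = net_cost / qaly_gain
    if qaly_gain > 0:
        return icer, (FLAG_COST_SAVING if net_cost < 0 else FLAG_OK)
    return icer, (FLAG_DOMINATED if net_cost > 0 else FLAG_SOUTHWEST)


def _phase_costs(costs: pd.DataFrame) -> Dict[Tuple[str, str, str], Tuple[float, float, float]]:
    out = {}
    for _, row in costs.iterrows():
        out[(row["disease"], row["sex"], row["ethnicity"])] = (
            float(row["cost_first_year"]),
            float(row["cost_subsequent_year"]),
            float(row["cost_last_6m"]),
        )
    return out


def disease_cost_offsets(
    run_output: RunOutput, costs: pd.DataFrame
) -> Dict[StratumKey, np.ndarray]:
    """Per-stratum ``[cohort, year]`` disease cost difference (intervention - BAU).

    Each disease contributes Δ(first-year cases) x first-year cost +
    Δ(subsequent prevalent person-years) x subsequent-year cost +
    Δ(disease deaths) x last-6-months cost. Negative entries are savings.
    """
    phase = _phase_costs(costs)
    out: Dict[StratumKey, np.ndarray] = {}
    for key in run_output.population:
        sex, eth = key
        bau, itv = run_output.bau[key], run_output.intervention[key]
        total = None
        for disease in run_output.diseases:
            if (disease, sex, eth) not in phase:
                raise CostingError(f"missing phase costs for {disease} in stratum {key}")
            c_first, c_subs, c_last = phase[(disease, sex, eth)]
            d_inc = itv.incident_cases[disease] - bau.incident_cases[disease]
            subs_itv = np.clip(
                itv.prevalent_person_years[disease] - itv.incident_cases[disease], 0.0, None
            )
            subs_bau = np.clip(
                bau.prevalent_person_years[disease] - bau.incident_cases[disease], 0.0, None
            )
            d_subs = subs_itv - subs_bau
            d_dead = itv.disease_deaths[disease] - bau.disease_deaths[disease]
            contrib = d_inc * c_first + d_subs * c_subs + d_dead * c_last
            total = contrib if total is None else total + contrib
        out[key] = total
    return out


def unrelated_costs(
    run_output: RunOutput, unrelated: pd.DataFrame
) -> Dict[StratumKey, np.ndarray]:
    """Per-stratum ``[cohort, year]`` unrelated cost on incremental life years.

    Each extra person-year lived at age a incurs the per-capita annual
    health-system cost at that age; positive when the intervention
    extends life.
    """
    cost_by_age = unrelated.sort_values("age")["cost"].to_numpy()
    out: Dict[StratumKey, np.ndarray] = {}
    for key in run_output.population:
        d_ly = run_output.life_year_diff(key)
        n_coh, T = d_ly.shape
        ages = np.minimum(np.arange(n_coh)[:, None] + np.arange(T)[None, :], cost_by_age.size - 1)
        out[key] = d_ly * cost_by_age[ages]
    return out


def equity_adjust(
    demography: pd.DataFrame, indigenous: str = "indigenous", reference: str = "other"
) -> pd.DataFrame:
    """Replace indigenous background mortality and pYLD with reference-group values.

    Same-sex, same-age replacement; counts, disease epidemiology, exposure
    and intervention parameters are untouched. This avoids undervaluing
    health gains for a group with elevated background rates.
    """
    adjusted = demography.copy()
    ref = demography[demography["ethnicity"] == reference].set_index(["sex", "age"])
    if ref.empty:
        raise CostingError(f"reference ethnicity {reference!r} not present")
    mask = adjusted["ethnicity"] == indigenous
    if not mask.any():
        raise CostingError(f"indigenous ethnicity {indigenous!r} not present")
    idx = list(zip(adjusted.loc[mask, "sex"], adjusted.loc[mask, "age"]))
    try:
        adjusted.loc[mask, "mortality"] = ref.loc[idx, "mortality"].to_numpy()
        adjusted.loc[mask, "pyld"] = ref.loc[idx, "pyld"].to_numpy()
    except KeyError as err:
        raise CostingError(f"missing matched reference stratum cell: {err}") from err
    return adjusted


@dataclass
class CeaResult:
    """Lifetime cost-effectiveness summary (all present values at ``discount_rate``)."""

    discount_rate: float
    qaly_gain: float
    intervention_cost_pv: float
    offsets_pv: float
    unrelated_pv: float
    net_cost: float
    icer: float
    flag: str
    breakdown: pd.DataFrame
    clip_events: int = 0

    def components_sum(self) -> float:
        return self.intervention_cost_pv + self.offsets_pv + self.unrelated_pv


def _group_label(lo: int, hi: int) -> str:
    if lo == 0:
        return f"<{hi}"
    if hi >= 110:
        return f"{lo}+"
    return f"{lo}-{hi}"


def run_cea(
    run_output: RunOutput,
    costs: pd.DataFrame,
    unrelated: pd.DataFrame,
    spec: InterventionSpec,
    discount_rate: float = 0.03,
    age_groups: Sequence[Tuple[int, int]] = AGE_GROUPS,
) -> CeaResult:
    """Full cost-effectiveness analysis of one model run.

    Net cost = intervention cost + disease cost offsets + unrelated costs
    (each discounted). The breakdown allocates the campaign cost evenly
    across the eligible baseline population and reports per-stratum,
    per-baseline-age-group QALY gains per 1000 population and subgroup
    ICERs.
    """
    horizon = run_output.horizon
    dfac = discount_factors(horizon, discount_rate)
    offsets = disease_cost_offsets(run_output, costs)
    unrel = unrelated_costs(run_output, unrelated)
    cost_stream = intervention_cost_stream(spec, horizon)

    qaly_pv_by_cohort: Dict[StratumKey, np.ndarray] = {}
    offsets_pv_by_cohort: Dict[StratumKey, np.ndarray] = {}
    unrel_pv_by_cohort: Dict[StratumKey, np.ndarray] = {}
    eligible_counts: Dict[StratumKey, np.ndarray] = {}
    lo_e, hi_e = spec.eligible_ages
    for key, pop in run_output.population.items():
        qaly_pv_by_cohort[key] = run_output.qaly_diff(key) @ dfac
        offsets_pv_by_cohort[key] = offsets[key] @ dfac
        unrel_pv_by_cohort[key] = unrel[key] @ dfac
        ages = np.arange(pop.n_ages)
        eligible_counts[key] = np.where((ages >= lo_e) & (ages <= hi_e), pop.counts, 0.0)

    total_eligible = sum(e.sum() for e in eligible_counts.values())
    qaly_gain = float(sum(v.sum() for v in qaly_pv_by_cohort.values()))
    offsets_pv = float(sum(v.sum() for v in offsets_pv_by_cohort.values()))
    unrelated_pv = float(sum(v.sum() for v in unrel_pv_by_cohort.values()))
    intervention_pv = float(np.dot(cost_stream, dfac))
    net_cost = intervention_pv + offsets_pv + unrelated_pv
    icer, flag = compute_icer(net_cost, qaly_gain)

    rows = []
    for key, pop in run_output.population.items():
        sex, eth = key
        for lo, hi in age_groups:
            sel = slice(lo, min(hi, pop.n_ages))
            group_count = float(pop.counts[sel].sum())
            if group_count == 0:
                continue
            g_qaly = float(qaly_pv_by_cohort[key][sel].sum())
            g_elig = float(eligible_counts[key][sel].sum())
            g_int_cost = intervention_pv * (g_elig / total_eligible if total_eligible else 0.0)
            g_net = g_int_cost + float(offsets_pv_by_cohort[key][sel].sum()) + float(
                unrel_pv_by_cohort[key][sel].sum()
            )
            g_icer, g_flag = compute_icer(g_net, g_qaly)
            rows.append(
                {
                    "sex": sex,
                    "ethnicity": eth,
                    "age_group": _group_label(lo, hi),
                    "population": group_count,
                    "qaly_gain": g_qaly,
                    "qalys_per_1000": g_qaly / (group_count / 1000.0),
                    "net_cost": g_net,
                    "icer": g_icer,
                    "flag": g_flag,
                }
            )
    breakdown = pd.DataFrame(rows)

    return CeaResult(
        discount_rate=discount_rate,
        qaly_gain=qaly_gain,
        intervention_cost_pv=intervention_pv,
        offsets_pv=offsets_pv,
        unrelated_pv=unrelated_pv,
        net_cost=net_cost,
        icer=icer,
        flag=flag,
        breakdown=breakdown,
        clip_events=run_output.clip_events,
    )
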