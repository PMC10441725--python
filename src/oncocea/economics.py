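"""Discounted cost / life-year / QALY accrual and incremental comparison.

Accrual runs along a :class:`~oncocea.cohort.CohortTrace`.  Per-cycle
quantities (state utilities, drug and monitoring costs) are accumulated with
a trapezoidal half-cycle correction when enabled; genuine one-off costs
(biomarker testing, adverse-event management at model entry, terminal care
at death) are not half-cycle corrected.

Costing conventions, chosen to mirror the source analysis:

* maintenance drugs accrue on PFS occupancy up to each agent's protocol cap
  (olaparib 2 years, bevacizumab 15 months of 3-week cycles); bevacizumab is
  dosed by weight, so its per-cycle price scales with body weight / 70 kg;
* administration is charged on cycles where an intravenous agent is given;
* laboratory and imaging follow-up accrue while progression-free;
* germline BRCA and HRD testing are one-off per patient in both arms;
* a fraction of each cycle's progression inflow starts active second-line
  chemotherapy (carboplatin + paclitaxel + administration) for a fixed
  number of cycles; the *never-second-line* share of the progressed state
  receives best supportive care until death;
* every incident death incurs the terminal-care cost once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTrace, build_trace
from .parameters import AnalysisInputs, ArmParams, EconomicInputs, PatientProfile

REFERENCE_WEIGHT_KG = 70.0

COST_COMPONENTS = (
    "maintenance_drugs", "administration", "laboratory", "imaging",
    "testing", "ae_management", "second_line", "bsc", "terminal_care",
)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals (plus undiscounted variants) for one strategy arm."""

    name: str
    total_cost: float
    ly: float
    qaly: float
    cost_components: Mapping[str, float]
    total_cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float


@dataclass(frozen=True)
class CEComparison:
    """Incremental results of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float
    icer_per_ly: float
    status: str  # "tradeoff" | "dominant" | "dominated"


def _per_cycle_sums(occ, df, hcc, cap=None):
    """Accrued occupancy-cycles, discounted, over cycles 1..K (or 1..cap)."""
    y = occ * df
    s = 0.5 * (y[1:] + y[:-1]) if hcc else y[1:]
    if cap is not None:
        s = s[: max(int(cap), 0)]
    return float(np.sum(s))


def _effective_utilities(econ: EconomicInputs, arm: ArmParams):
    u_pfs = econ.utility_pfs if arm.utility_pfs is None else arm.utility_pfs
    u_pd = econ.utility_pd if arm.utility_pd is None else arm.utility_pd
    return u_pfs, u_pd


def accrue_effects(
    trace: CohortTrace,
    econ: EconomicInputs,
    arm: ArmParams,
    *,
    half_cycle_correction: bool = True,
    discount: bool = True,
) -> tuple[float, float]:
    """Life-years and QALYs along the trace.

    QALYs weight PFS/PD occupancy by the state utilities and subtract a
    one-off adverse-event decrement ``sum_AE risk * disutility * cycle-years``
    applied at the first cycle.
    """
    df = trace.discount_factor if discount else np.ones_like(trace.discount_factor)
    dt_years = trace.cycle_length_months / 12.0
    pfs_cycles = _per_cycle_sums(trace.pfs, df, half_cycle_correction)
    pd_cycles = _per_cycle_sums(trace.pd, df, half_cycle_correction)
    ly = (pfs_cycles + pd_cycles) * dt_years
    u_pfs, u_pd = _effective_utilities(econ, arm)
    qaly = (u_pfs * pfs_cycles + u_pd * pd_cycles) * dt_years
    ae_decrement = sum(
        risk * econ.disutilities.get(name, 0.0) * dt_years
        for name, risk in arm.ae_risks.items()
    )
    qaly -= ae_decrement * float(df[1]) if len(df) > 1 else ae_decrement
    return ly, qaly


def _second_line_occupancy(trace: CohortTrace, arm: ArmParams, duration_cycles: int):
    """Share of the cohort on active second-line chemo each cycle.

    A fraction ``second_line_proportion`` of each cycle's progression inflow
    (the floored PFS decrement) receives chemo for ``duration_cycles``
    cycles from entry; occupancy is capped by the progressed state so chemo
    never outlives its recipients.
    """
    inflow = np.clip(-np.diff(trace.pfs, prepend=trace.pfs[0]), 0.0, None)
    window = np.ones(max(int(duration_cycles), 0))
    if len(window) == 0:
        return np.zeros_like(trace.pfs)
    on_chemo = arm.second_line_proportion * np.convolve(inflow, window)[: len(inflow)]
    return np.minimum(on_chemo, trace.pd)


def accrue_costs(
    trace: CohortTrace,
    econ: EconomicInputs,
    arm: ArmParams,
    patient: PatientProfile,
    *,
    half_cycle_correction: bool = True,
    discount: bool = True,
) -> dict[str, float]:
    """Itemised discounted costs for one arm along the trace."""
    df = trace.discount_factor if discount else np.ones_like(trace.discount_factor)
    hcc = half_cycle_correction
    weight_scale = patient.body_weight / REFERENCE_WEIGHT_KG
    bev_price = arm.bevacizumab_cost_per_cycle * weight_scale

    pfs_to_ola_cap = _per_cycle_sums(trace.pfs, df, hcc, cap=arm.olaparib_max_cycles)
    pfs_to_bev_cap = _per_cycle_sums(trace.pfs, df, hcc, cap=arm.bevacizumab_max_cycles)
    pfs_all = _per_cycle_sums(trace.pfs, df, hcc)

    c: dict[str, float] = {}
    c["maintenance_drugs"] = (
        arm.olaparib_cost_per_cycle * pfs_to_ola_cap + bev_price * pfs_to_bev_cap
    )
    c["administration"] = econ.admin_cost_per_cycle * pfs_to_bev_cap
    c["laboratory"] = econ.lab_cost_per_cycle * pfs_all
    c["imaging"] = econ.imaging_cost_per_cycle * pfs_all
    c["testing"] = econ.brca_test_cost + econ.hrd_test_cost
    c["ae_management"] = arm.ae_management_cost

    sl_occ = _second_line_occupancy(trace, arm, econ.second_line_duration_cycles)
    c["second_line"] = (
        econ.second_line_drug_cost_per_cycle + econ.admin_cost_per_cycle
    ) * _per_cycle_sums(sl_occ, df, hcc)

    # best supportive care covers the never-second-line share of PD until death
    bsc_occ = (1.0 - arm.second_line_proportion) * trace.pd
    c["bsc"] = econ.bsc_cost_per_cycle * _per_cycle_sums(bsc_occ, df, hcc)

    c["terminal_care"] = econ.terminal_care_cost * float(
        np.sum(trace.incident_deaths * df)
    )
    return c


def evaluate_strategy(inputs: AnalysisInputs, arm: str | ArmParams) -> StrategyOutcome:
    """Trace + accrual for one arm; deterministic given the inputs."""
    if isinstance(arm, str):
        if arm not in ("intervention", "comparator"):
            raise ValueError("arm must be 'intervention' or 'comparator'")
        arm = inputs.arms[arm]
    settings, econ = inputs.settings, inputs.econ
    trace = build_trace(arm.pfs, arm.os, settings, econ.discount_rate_annual)
    hcc = settings.half_cycle_correction
    ly, qaly = accrue_effects(trace, econ, arm, half_cycle_correction=hcc)
    ly0, qaly0 = accrue_effects(trace, econ, arm, half_cycle_correction=hcc, discount=False)
    comp = accrue_costs(trace, econ, arm, inputs.patient, half_cycle_correction=hcc)
    comp0 = accrue_costs(
        trace, econ, arm, inputs.patient, half_cycle_correction=hcc, discount=False
    )
    return StrategyOutcome(
        name=arm.name,
        total_cost=sum(comp.values()),
        ly=ly,
        qaly=qaly,
        cost_components=comp,
        total_cost_undiscounted=sum(comp0.values()),
        ly_undiscounted=ly0,
        qaly_undiscounted=qaly0,
    )


def _ratio(delta_cost, delta_effect):
    if delta_effect == 0.0:
        if delta_cost == 0.0:
            return math.nan
        return math.copysign(math.inf, delta_cost)
    return delta_cost / delta_effect


def compare(intervention: StrategyOutcome, comparator: StrategyOutcome) -> CEComparison:
    """Incremental cost-effectiveness of intervention vs comparator."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qaly - comparator.qaly
    dl = intervention.ly - comparator.ly
    if dc < 0 and dq > 0:
        status = "dominant"
    elif dc > 0 and dq < 0:
        status = "dominated"
    else:
        status = "tradeoff"
    return CEComparison(
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer_per_qaly=_ratio(dc, dq),
        icer_per_ly=_ratio(dc, dl),
        status=status,
    )


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """NMB = WTP * dQALY - dCost; positive means cost-effective at that WTP."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * delta_qaly - delta_cost


def run_base_case(inputs: AnalysisInputs) -> tuple[StrategyOutcome, StrategyOutcome, CEComparison]:
    """Evaluate both arms and their incremental comparison."""
    inter = evaluate_strategy(inputs, "intervention")
    comp = evaluate_strategy(inputs, "comparator")
    return inter, comp, compare(inter, comp)


def outcome_table(inputs: AnalysisInputs) -> pd.DataFrame:
    """Per-arm outcome table (total cost, LYs, QALYs, ICERs vs comparator)."""
    inter, comp, ce = run_base_case(inputs)
    rows = []
    for out, icer_ly, icer_q in (
        (comp, math.nan, math.nan),
        (inter, ce.icer_per_ly, ce.icer_per_qaly),
    ):
        rows.append({
            "strategy": out.name,
            "total_cost_usd": out.total_cost,
            "ly": out.ly,
            "icer_usd_per_ly": icer_ly,
            "qaly": out.qaly,
            "icer_usd_per_qaly": icer_q,
        })
    return pd.DataFrame(rows)
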