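"""Cost and utility streams, discounting, and incremental cost-effectiveness.

The parameter set mirrors the study's base-case inputs from the US payer
perspective (2020 USD): per-unit drug acquisition prices, administration fees,
laboratory/monitoring costs, per-cycle adverse-event costs, per-cycle
progressed-disease costs (subsequent-treatment weighted), health-state
utilities, hazard ratios, body size, the 3% annual discount rate and the
$150,000/QALY willingness-to-pay threshold.

Costing conventions (package design choices, exposed as flags):

- drug doses are converted to whole billable units by ceiling (no vial
  sharing); ``exact_dose_costing`` switches to fractional units;
- the progressed-disease cost is charged per model cycle of occupancy
  (``pd_cost_once`` instead charges it once on entry to the state);
- adverse-event costs accrue only during on-treatment cycles
  (``ae_all_cycles`` extends them to every progression-free cycle);
- the annual discount rate is converted to a monthly rate by compounding.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import yaml

from .markov import CohortTrace

__all__ = [
    "ParameterSet",
    "DrugLine",
    "RegimenSchedule",
    "CEResult",
    "default_schedules",
    "cycle_cost",
    "accumulate",
    "icer",
]

# mg per billable unit for each drug price in the parameter set
DRUG_UNIT_MG = {
    "daratumumab": 10.0,
    "bortezomib": 0.1,
    "prednisone": 1.0,
    "dexamethasone": 0.25,
    "paracetamol": 650.0,
    "diphenhydramine": 50.0,
    "melphalan": 2.0,
    "lenalidomide": 25.0,
    "carfilzomib": 1.0,
}


@dataclass(frozen=True)
class ParameterSet:
    """Base-case model inputs. Defaults are the study's Table-1 base-case column."""

    # drug cost per billable unit, USD
    cost_daratumumab: float = 56.063
    cost_bortezomib: float = 24.167
    cost_prednisone: float = 0.012
    cost_dexamethasone: float = 0.103
    cost_paracetamol: float = 0.037
    cost_diphenhydramine: float = 0.017
    cost_melphalan: float = 9.159
    cost_lenalidomide: float = 763.010
    cost_carfilzomib: float = 38.972
    # progressed-disease costs, USD (per model cycle under the default reading)
    pd_cost_dvmp: float = 17766.986
    pd_cost_vmp: float = 16440.419
    # administration, USD per administration event
    admin_dvmp_per_infusion: float = 349.821
    admin_vmp_per_injection: float = 49.928
    # tests and monitoring, USD
    cost_lab_tests: float = 36.145
    cost_pd_monitoring: float = 481.695
    # adverse events, USD per on-treatment cycle
    ae_cost_dvmp: float = 240.318
    ae_cost_vmp: float = 621.084
    # survival and utilities
    hr_pfs: float = 0.42
    hr_os: float = 0.60
    u_pfs_dvmp: float = 0.685
    u_pfs_vmp: float = 0.627
    u_pd_dvmp: float = 0.59
    u_pd_vmp: float = 0.59
    # other
    body_weight: float = 79.0  # kg
    bsa: float = 1.91  # m^2
    discount_rate: float = 0.03  # annual
    wtp: float = 150_000.0  # USD per QALY
    start_age: float = 71.0  # years
    # behaviour flags
    exact_dose_costing: bool = False
    pd_cost_once: bool = False
    ae_all_cycles: bool = False
    half_cycle_correction: bool = False

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("cost_", "pd_cost_", "admin_", "ae_cost_")) and isinstance(v, float) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        for u in ("u_pfs_dvmp", "u_pfs_vmp", "u_pd_dvmp", "u_pd_vmp"):
            if not 0.0 <= getattr(self, u) <= 1.0:
                raise ValueError(f"{u} must lie in [0, 1]")
        if not 0.0 <= self.discount_rate <= 0.05:
            raise ValueError("discount_rate must lie in [0, 0.05]")
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValueError("hazard ratios must be positive")

    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)

    @property
    def monthly_discount(self) -> float:
        return (1.0 + self.discount_rate) ** (1.0 / 12.0) - 1.0

    def utility(self, state: str, strategy: str) -> float:
        key = "dvmp" if _is_dvmp(strategy) else "vmp"
        if state == "pfs":
            return getattr(self, f"u_pfs_{key}")
        if state == "pd":
            return getattr(self, f"u_pd_{key}")
        return 0.0

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _is_dvmp(strategy: str) -> bool:
    return strategy.replace("-", "").replace("_", "").lower().startswith("dvmp")


@dataclass(frozen=True)
class DrugLine:
    """One drug in a regimen: dose rule and per-model-cycle administration count.

    ``cycle_start``/``cycle_end`` bound the applicable model cycles (inclusive
    start, exclusive end; ``None`` end means until leaving the PFS state).
    """

    drug: str
    dose_rule: str  # 'per_kg' | 'per_m2' | 'flat'
    dose_amount: float  # mg per kg, mg per m^2, or mg
    admins_per_cycle: float
    cycle_start: int = 0
    cycle_end: int | None = None
    admin_cost_param: str | None = None  # ParameterSet field charged per administration

    def __post_init__(self):
        if self.drug not in DRUG_UNIT_MG:
            raise KeyError(f"unknown drug {self.drug!r} in schedule")
        if self.dose_rule not in ("per_kg", "per_m2", "flat"):
            raise ValueError(f"unknown dose rule {self.dose_rule!r}")
        if self.admins_per_cycle < 0 or self.dose_amount < 0:
            raise ValueError("doses and administration counts must be non-negative")

    def active(self, cycle: int) -> bool:
        return cycle >= self.cycle_start and (self.cycle_end is None or cycle < self.cycle_end)

    def dose_mg(self, params: ParameterSet) -> float:
        if self.dose_rule == "per_kg":
            return self.dose_amount * params.body_weight
        if self.dose_rule == "per_m2":
            return self.dose_amount * params.bsa
        return self.dose_amount

    def cost_per_cycle(self, cycle: int, params: ParameterSet) -> float:
        if not self.active(cycle):
            return 0.0
        mg = self.dose_mg(params)
        units = mg / DRUG_UNIT_MG[self.drug]
        if not params.exact_dose_costing:
            units = math.ceil(units - 1e-9)
        unit_price = getattr(params, f"cost_{self.drug}")
        c = units * unit_price * self.admins_per_cycle
        if self.admin_cost_param:
            c += getattr(params, self.admin_cost_param) * self.admins_per_cycle
        return c


@dataclass(frozen=True)
class RegimenSchedule:
    """The drug lines making up one strategy's on-treatment schedule."""

    strategy: str
    lines: tuple[DrugLine, ...]

    def on_treatment(self, cycle: int) -> bool:
        return any(line.active(cycle) for line in self.lines)

    @classmethod
    def from_yaml(cls, path) -> "RegimenSchedule":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data["strategy"], tuple(DrugLine(**ln) for ln in data["lines"]))

    def to_yaml(self, path) -> None:
        data = {"strategy": self.strategy, "lines": [dataclasses.asdict(l) for l in self.lines]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_schedules() -> dict[str, RegimenSchedule]:
    """Package-default monthly-cycle schedules for the two strategies.

    Monthly averages of the trial regimen's 6-week cycles: the VMP backbone
    runs 12 model cycles (bortezomib 1.3 mg/m^2, 40 doses; melphalan 9 mg/m^2
    and prednisone 60 mg/m^2, 36 doses each); daratumumab 16 mg/kg is weekly in
    the first model cycle, ~3-weekly through cycle 12, then monthly until
    progression, with premedication (dexamethasone 20 mg, paracetamol 1000 mg,
    diphenhydramine 50 mg) at each infusion.
    """
    backbone = lambda admin: (
        DrugLine("bortezomib", "per_m2", 1.3, 40 / 12, 0, 12, admin_cost_param=admin),
        DrugLine("melphalan", "per_m2", 9.0, 3.0, 0, 12),
        DrugLine("prednisone", "per_m2", 60.0, 3.0, 0, 12),
    )
    dara = [
        (4.0, 0, 1),    # weekly loading month
        (1.5, 1, 12),   # every ~3 weeks
        (1.0, 12, None),  # monthly until progression
    ]
    dara_lines = []
    for n, lo, hi in dara:
        dara_lines.append(DrugLine("daratumumab", "per_kg", 16.0, n, lo, hi,
                                   admin_cost_param="admin_dvmp_per_infusion"))
        dara_lines.append(DrugLine("dexamethasone", "flat", 20.0, n, lo, hi))
        dara_lines.append(DrugLine("paracetamol", "flat", 1000.0, n, lo, hi))
        dara_lines.append(DrugLine("diphenhydramine", "flat", 50.0, n, lo, hi))
    return {
        "VMP": RegimenSchedule("VMP", backbone("admin_vmp_per_injection")),
        "D-VMP": RegimenSchedule("D-VMP", backbone("admin_vmp_per_injection") + tuple(dara_lines)),
    }


def cycle_cost(state: str, strategy: str, cycle: int, params: ParameterSet,
               schedule: RegimenSchedule) -> float:
    """Cost of one model cycle spent entirely in ``state``.

    Progression-free: drug acquisition + administration + laboratory tests +
    (on-treatment) adverse-event cost. Progressed: progressed-disease cost
    (per cycle unless ``pd_cost_once``) + monitoring. Dead: 0.
    """
    key = "dvmp" if _is_dvmp(strategy) else "vmp"
    if state == "dead":
        return 0.0
    if state == "pd":
        c = params.cost_pd_monitoring
        if not params.pd_cost_once:
            c += getattr(params, f"pd_cost_{key}")
        return c
    if state != "pfs":
        raise ValueError(f"unknown state {state!r}")
    c = params.cost_lab_tests
    c += sum(line.cost_per_cycle(cycle, params) for line in schedule.lines)
    if params.ae_all_cycles or schedule.on_treatment(cycle):
        c += getattr(params, f"ae_cost_{key}")
    return c


def _pfs_cost_vector(cycles: np.ndarray, params: ParameterSet, schedule: RegimenSchedule,
                     strategy: str) -> np.ndarray:
    """Vector of per-cycle PFS costs (cycle-range logic vectorized over cycles)."""
    key = "dvmp" if _is_dvmp(strategy) else "vmp"
    out = np.full(len(cycles), params.cost_lab_tests)
    on_treat = np.zeros(len(cycles), dtype=bool)
    for line in schedule.lines:
        active = (cycles >= line.cycle_start)
        if line.cycle_end is not None:
            active &= cycles < line.cycle_end
        on_treat |= active
        mg = line.dose_mg(params)
        units = mg / DRUG_UNIT_MG[line.drug]
        if not params.exact_dose_costing:
            units = math.ceil(units - 1e-9)
        c = units * getattr(params, f"cost_{line.drug}") * line.admins_per_cycle
        if line.admin_cost_param:
            c += getattr(params, line.admin_cost_param) * line.admins_per_cycle
        out += np.where(active, c, 0.0)
    ae = getattr(params, f"ae_cost_{key}")
    out += np.where(params.ae_all_cycles | on_treat, ae, 0.0)
    return out


def accumulate(trace: CohortTrace, params: ParameterSet, schedule: RegimenSchedule,
               strategy: str) -> tuple[float, float, float]:
    """Discounted (LY, QALY, cost) totals for one strategy's cohort trace.

    Cycle c is weighted by (1 + r_m)^(-c) with the compound monthly rate r_m.
    Each occupied cycle contributes 1/12 year of life. With the half-cycle
    correction flag, state occupancies are averaged over adjacent cycle
    boundaries before accumulation.
    """
    df = trace.df
    cycles = df["cycle"].to_numpy()[:-1]  # last row is the end-of-horizon boundary
    m_pfs = df["m_pfs"].to_numpy()
    m_pd = df["m_pd"].to_numpy()
    inflow = df["m_pd_inflow"].to_numpy()
    if params.half_cycle_correction:
        m_pfs = 0.5 * (m_pfs[:-1] + m_pfs[1:])
        m_pd = 0.5 * (m_pd[:-1] + m_pd[1:])
    else:
        m_pfs = m_pfs[:-1]
        m_pd = m_pd[:-1]

    w = (1.0 + params.monthly_discount) ** (-cycles.astype(float))
    key = "dvmp" if _is_dvmp(strategy) else "vmp"
    u_pfs, u_pd = params.utility("pfs", strategy), params.utility("pd", strategy)

    ly = float(np.sum((m_pfs + m_pd) / 12.0 * w))
    qaly = float(np.sum((m_pfs * u_pfs + m_pd * u_pd) / 12.0 * w))

    pfs_cost = _pfs_cost_vector(cycles, params, schedule, strategy)
    pd_cost = params.cost_pd_monitoring + (
        0.0 if params.pd_cost_once else getattr(params, f"pd_cost_{key}")
    )
    cost = float(np.sum((m_pfs * pfs_cost + m_pd * pd_cost) * w))
    if params.pd_cost_once:
        cost += float(np.sum(inflow[1:] * getattr(params, f"pd_cost_{key}") * w))
    return ly, qaly, cost


@dataclass(frozen=True)
class CEResult:
    """Per-strategy discounted totals plus incremental cost-effectiveness."""

    strategies: tuple[str, str]  # (comparator, intervention)
    ly: dict
    qaly: dict
    cost: dict
    d_ly: float = 0.0
    d_qaly: float = 0.0
    d_cost: float = 0.0
    icer_per_ly: float | None = None
    icer_per_qaly: float | None = None
    dominance: str = "icer"  # 'icer' | 'dominant' | 'dominated' | 'equivalent'

    def to_dict(self) -> dict:
        return {
            "strategies": list(self.strategies),
            "ly": self.ly, "qaly": self.qaly, "cost": self.cost,
            "d_ly": self.d_ly, "d_qaly": self.d_qaly, "d_cost": self.d_cost,
            "icer_per_ly": self.icer_per_ly, "icer_per_qaly": self.icer_per_qaly,
            "dominance": self.dominance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self) -> str:
        """Human-readable base-case table (regimen, LYs, QALYs, cost, ICERs)."""
        comp, intv = self.strategies
        lines = [f"{'Regimen':8s} {'LYs':>8s} {'QALYs':>8s} {'Cost':>14s} {'ICER/LY':>12s} {'ICER/QALY':>12s}"]
        ipl = f"${self.icer_per_ly:,.0f}" if self.icer_per_ly is not None else self.dominance
        ipq = f"${self.icer_per_qaly:,.0f}" if self.icer_per_qaly is not None else self.dominance
        lines.append(f"{intv:8s} {self.ly[intv]:8.3f} {self.qaly[intv]:8.3f} "
                     f"${self.cost[intv]:>13,.0f} {ipl:>12s} {ipq:>12s}")
        lines.append(f"{comp:8s} {self.ly[comp]:8.3f} {self.qaly[comp]:8.3f} "
                     f"${self.cost[comp]:>13,.0f}")
        return "\n".join(lines)


def icer(comparator: tuple[float, float, float], intervention: tuple[float, float, float],
         labels: tuple[str, str] = ("VMP", "D-VMP")) -> CEResult:
    """Incremental cost-effectiveness of ``intervention`` vs ``comparator``.

    Inputs are (LY, QALY, cost) triples. Ratios are reported only when the
    incremental effect is positive; otherwise a dominance category is set:
    'dominant' (more effective, cheaper), 'dominated' (less effective, costlier)
    or 'equivalent'.
    """
    (ly_c, q_c, c_c), (ly_i, q_i, c_i) = comparator, intervention
    comp, intv = labels
    d_ly, d_q, d_c = ly_i - ly_c, q_i - q_c, c_i - c_c
    dominance = "icer"
    ipl = ipq = None
    if d_q == 0 and d_c == 0 and d_ly == 0:
        dominance = "equivalent"
    elif d_q >= 0 and d_ly >= 0 and d_c <= 0 and (d_q > 0 or d_ly > 0 or d_c < 0):
        dominance = "dominant"
    elif d_q <= 0 and d_ly <= 0 and d_c >= 0:
        dominance = "dominated"
    if d_ly > 0:
        ipl = d_c / d_ly
    if d_q > 0:
        ipq = d_c / d_q
    return CEResult(
        strategies=labels,
        ly={comp: ly_c, intv: ly_i},
        qaly={comp: q_c, intv: q_i},
        cost={comp: c_c, intv: c_i},
        d_ly=d_ly, d_qaly=d_q, d_cost=d_c,
        icer_per_ly=ipl, icer_per_qaly=ipq, dominance=dominance,
    )
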