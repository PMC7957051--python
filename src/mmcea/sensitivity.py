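"""Deterministic and probabilistic sensitivity analysis.

One-way analysis (OWSA) swings each parameter between its bounds — the 95% CI
where the study reports one, otherwise ±20% of the base value — with all
others held at base, and orders parameters by the induced ICER range (tornado
order). The probabilistic analysis (PSA) draws all parameters jointly and
independently: Gamma for costs and body-size parameters, Beta for utilities
and hazard ratios, moment-matched to mean = base value and
sd = (high - low) / (2 * 1.96), i.e. the bounds are read as a 95% interval.
Each draw reruns the deterministic pipeline; the cost-effectiveness
acceptability curve (CEAC) reports, per willingness-to-pay value, the fraction
of draws with positive incremental net monetary benefit WTP*dQALY - dCost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import ParameterSet
from .pipeline import CEPipeline

__all__ = [
    "ParamSpec",
    "default_param_specs",
    "owsa",
    "sample_params",
    "psa",
    "PSAResult",
    "DEFAULT_WTP_GRID",
]

DEFAULT_WTP_GRID = np.arange(0, 500_001, 10_000, dtype=float)


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, bounds, and PSA distribution tag."""

    name: str  # ParameterSet field name
    base: float
    low: float
    high: float
    dist: str = "gamma"  # 'gamma' | 'beta' | 'fixed'
    source: str = "pct20"  # 'ci95' | 'pct20'

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: bounds must bracket the base value")
        if self.dist not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist == "beta" and not 0.0 < self.base < 1.0:
            raise ValueError(f"{self.name}: beta-tagged base must lie in (0, 1)")
        if self.dist == "gamma" and self.base <= 0:
            raise ValueError(f"{self.name}: gamma-tagged base must be positive")
        if self.dist == "beta" and self.high >= 1.0:
            warnings.warn(f"{self.name}: beta-tagged parameter with upper bound >= 1", stacklevel=2)

    @property
    def sd(self) -> float:
        return (self.high - self.low) / (2.0 * 1.96)


def _pct20(name, base, dist="gamma") -> ParamSpec:
    return ParamSpec(name, base, 0.8 * base, 1.2 * base, dist, "pct20")


def default_param_specs(params: ParameterSet | None = None) -> list[ParamSpec]:
    """The study's uncertain-parameter list: CIs where reported, else ±20%."""
    p = params or ParameterSet()
    specs = [
        _pct20("cost_daratumumab", p.cost_daratumumab),
        _pct20("cost_bortezomib", p.cost_bortezomib),
        _pct20("cost_prednisone", p.cost_prednisone),
        _pct20("cost_dexamethasone", p.cost_dexamethasone),
        _pct20("cost_paracetamol", p.cost_paracetamol),
        _pct20("cost_diphenhydramine", p.cost_diphenhydramine),
        _pct20("cost_melphalan", p.cost_melphalan),
        _pct20("cost_lenalidomide", p.cost_lenalidomide),
        _pct20("cost_carfilzomib", p.cost_carfilzomib),
        _pct20("pd_cost_dvmp", p.pd_cost_dvmp),
        _pct20("pd_cost_vmp", p.pd_cost_vmp),
        _pct20("admin_dvmp_per_infusion", p.admin_dvmp_per_infusion),
        _pct20("admin_vmp_per_injection", p.admin_vmp_per_injection),
        _pct20("cost_lab_tests", p.cost_lab_tests),
        _pct20("cost_pd_monitoring", p.cost_pd_monitoring),
        _pct20("ae_cost_dvmp", p.ae_cost_dvmp),
        _pct20("ae_cost_vmp", p.ae_cost_vmp),
        ParamSpec("hr_pfs", p.hr_pfs, 0.34, 0.51, "beta", "ci95"),
        ParamSpec("hr_os", p.hr_os, 0.46, 0.80, "beta", "ci95"),
        _pct20("u_pfs_dvmp", p.u_pfs_dvmp, "beta"),
        _pct20("u_pfs_vmp", p.u_pfs_vmp, "beta"),
        _pct20("u_pd_dvmp", p.u_pd_dvmp, "beta"),
        _pct20("u_pd_vmp", p.u_pd_vmp, "beta"),
        ParamSpec("body_weight", p.body_weight, 49.8, 199.0, "gamma", "ci95"),
        ParamSpec("bsa", p.bsa, 1.40, 2.53, "gamma", "ci95"),
        ParamSpec("discount_rate", p.discount_rate, 0.0, 0.05, "fixed", "ci95"),
    ]
    return specs


def owsa(specs: list[ParamSpec], pipeline: CEPipeline) -> pd.DataFrame:
    """One-way sensitivity analysis; rows in tornado order.

    Returns a DataFrame with ICERs per QALY at each parameter's low and high
    bound, the induced range, and a dominance flag for bounds at which the
    incremental QALY gain is not positive (such rows sort after ranged rows).
    """
    base = pipeline.evaluate()
    rows = []
    for spec in specs:
        vals, flags = {}, []
        for tag, v in (("low", spec.low), ("high", spec.high)):
            res = pipeline.evaluate({spec.name: v})
            vals[tag] = res.icer_per_qaly
            if res.icer_per_qaly is None:
                flags.append(tag)
        dominance = bool(flags)
        rng = abs(vals["high"] - vals["low"]) if not dominance else np.nan
        rows.append({
            "parameter": spec.name, "base": spec.base, "low": spec.low, "high": spec.high,
            "icer_low": vals["low"], "icer_high": vals["high"],
            "icer_base": base.icer_per_qaly, "range": rng, "dominance": dominance,
        })
    df = pd.DataFrame(rows)
    df["_dom"] = df["dominance"].astype(int)
    df = df.sort_values(["_dom", "range"], ascending=[True, False], kind="stable")
    return df.drop(columns="_dom").reset_index(drop=True)


def _gamma_ab(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def _beta_ab(mean: float, sd: float, name: str) -> tuple[float, float]:
    if sd**2 >= mean * (1.0 - mean):
        raise ValueError(f"beta moment-matching infeasible for {name}: sd too large for mean")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_params(specs: list[ParamSpec], n_draws: int, seed: int) -> pd.DataFrame:
    """Independent seeded draws of every spec; one column per parameter."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for spec in specs:
        if spec.dist == "fixed" or spec.sd == 0:
            cols[spec.name] = np.full(n_draws, spec.base)
        elif spec.dist == "gamma":
            shape, scale = _gamma_ab(spec.base, spec.sd)
            cols[spec.name] = rng.gamma(shape, scale, size=n_draws)
        else:
            a, b = _beta_ab(spec.base, spec.sd, spec.name)
            cols[spec.name] = rng.beta(a, b, size=n_draws)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class PSAResult:
    """Draw-level incremental outcomes and the acceptability curve."""

    draws: pd.DataFrame  # draw, cost/qaly per strategy, d_cost, d_qaly
    ceac: pd.DataFrame  # wtp, p_intervention, p_comparator

    def acceptability_at(self, wtp: float, strategy: str = "intervention") -> float:
        col = "p_intervention" if strategy.lower().startswith("i") or "d" in strategy.lower() else "p_comparator"
        i = int(np.argmin(np.abs(self.ceac["wtp"].to_numpy() - wtp)))
        return float(self.ceac[col].iloc[i])


def psa(
    specs: list[ParamSpec],
    pipeline: CEPipeline,
    n_draws: int = 1000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis: rerun the pipeline per joint draw.

    The CEAC gives P(WTP * dQALY - dCost > 0) over the WTP grid for the
    intervention, and its complement for the comparator (two strategies).
    """
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    sampled = sample_params(specs, n_draws, seed)
    comp, intv = pipeline.evaluate().strategies
    rows = []
    for i in range(n_draws):
        res = pipeline.evaluate(sampled.iloc[i].to_dict())
        rows.append({
            "draw": i,
            f"cost_{comp}": res.cost[comp], f"qaly_{comp}": res.qaly[comp],
            f"cost_{intv}": res.cost[intv], f"qaly_{intv}": res.qaly[intv],
            "d_cost": res.d_cost, "d_qaly": res.d_qaly, "dominance": res.dominance,
        })
    draws = pd.DataFrame(rows)
    nmb = grid[None, :] * draws["d_qaly"].to_numpy()[:, None] - draws["d_cost"].to_numpy()[:, None]
    p_int = (nmb > 0).mean(axis=0)
    ceac = pd.DataFrame({"wtp": grid, "p_intervention": p_int, "p_comparator": 1.0 - p_int})
    return PSAResult(draws=draws, ceac=ceac)
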