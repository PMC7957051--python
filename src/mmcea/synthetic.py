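"""Synthetic inputs: Weibull arms, digitized curves, life table, calibration.

The source figures of the underlying trial are not redistributable, so every
input the pipeline needs is generated here from known Weibull truth:
patient-level event times, step-function KM curves sampled at a digitization
grid, number-at-risk tables at fixed calendar times, a 2017-US-format life
table (synthetic, Gompertz-Makeham), and the base-case parameter set.

``calibrate_fixture`` tunes the Weibull truth so the deterministic pipeline
reproduces the published per-arm life-years and QALYs, giving the repository a
self-contained acceptance fixture. Because the two arms are linked through the
hazard ratios, the two per-endpoint targets (comparator + intervention)
identify both Weibull parameters, so scale and shape are solved jointly per
endpoint.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .economics import ParameterSet, default_schedules
from .km_ipd import DigitizedCurve, ReconstructedIPD, RiskTable, km_estimate
from .markov import LifeTable
from .pipeline import COMPARATOR, INTERVENTION, CEPipeline
from .survfit import SurvivalFunction

__all__ = [
    "TruthSpec",
    "CalibrationResult",
    "simulate_arm",
    "make_life_table",
    "calibrate_fixture",
    "calibrated_pipeline",
    "PUBLISHED_BASE_CASE",
]

# Published base-case outputs used as calibration targets:
# per-arm discounted life-years, QALYs and total costs.
PUBLISHED_BASE_CASE = {
    "ly_vmp": 7.296, "ly_dvmp": 10.300,
    "qaly_vmp": 4.373, "qaly_dvmp": 6.404,
    "cost_vmp": 1_139_094.0, "cost_dvmp": 1_927_635.0,
    "icer_per_ly": 262_526.0, "icer_per_qaly": 388_364.0,
}


@dataclass(frozen=True)
class TruthSpec:
    """Known Weibull truth for both endpoints of the comparator arm.

    Intervention-arm curves are hazard-ratio-linked (lam * HR) unless explicit
    ``lam_*_dvmp`` overrides are given. Censoring fraction is the target share
    of randomly censored records; ``followup_months`` adds administrative
    censoring at a fixed calendar time (None = none).
    """

    lam_pfs: float
    gam_pfs: float
    lam_os: float
    gam_os: float
    hr_pfs: float = 0.42
    hr_os: float = 0.60
    lam_pfs_dvmp: float | None = None
    lam_os_dvmp: float | None = None
    n_vmp: int = 356
    n_dvmp: int = 350
    censor_frac: float = 0.2
    followup_months: float | None = None
    grid_size: int = 40
    risk_interval: float = 6.0
    seed: int = 0

    def __post_init__(self):
        for f in ("lam_pfs", "gam_pfs", "lam_os", "gam_os", "hr_pfs", "hr_os"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 <= self.censor_frac <= 0.5:
            raise ValueError("censor_frac must lie in [0, 0.5]")

    def weibull(self, endpoint: str, arm: str = COMPARATOR) -> tuple[float, float]:
        """(lam, gam) for one endpoint/arm; intervention is HR-linked by default."""
        lam = getattr(self, f"lam_{endpoint}")
        gam = getattr(self, f"gam_{endpoint}")
        if arm == INTERVENTION:
            override = getattr(self, f"lam_{endpoint}_dvmp")
            hr = getattr(self, f"hr_{endpoint}")
            lam = override if override is not None else lam * hr
        return lam, gam

    def survival(self, endpoint: str, arm: str = COMPARATOR) -> SurvivalFunction:
        return SurvivalFunction("weibull", self.weibull(endpoint, arm))


def _censor_cap(lam: float, gam: float, frac: float) -> float:
    """Upper bound of the Uniform(0, c) censoring law giving P(censored) = frac.

    For C ~ U(0, c) independent of the Weibull event time T,
    P(C < T) = (1/c) * int_0^c S(t) dt, monotone decreasing in c.
    """
    S = SurvivalFunction("weibull", (lam, gam))

    def p_cens(c):
        val, _ = integrate.quad(S, 0.0, c, limit=200)
        return val / c

    hi = 1.0
    while p_cens(hi) > frac and hi < 1e7:
        hi *= 2.0
    return optimize.brentq(lambda c: p_cens(c) - frac, 1e-6, hi, xtol=1e-8)


def simulate_arm(
    lam: float,
    gam: float,
    n: int,
    censor_frac: float = 0.0,
    followup_months: float | None = None,
    grid_size: int = 40,
    risk_interval: float = 6.0,
    seed: int = 0,
    label: str = "arm",
) -> tuple[ReconstructedIPD, DigitizedCurve, RiskTable]:
    """Simulate one arm's true IPD and its digitized KM curve + risk table.

    Event times come from the Weibull inverse CDF on seeded uniforms,
    t = (-log(1-u)/lam)^(1/gam); random censoring times are Uniform(0, c) with
    c solved so the expected censored fraction equals ``censor_frac``; an
    administrative cut at ``followup_months`` censors everything beyond it.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.power(-np.log1p(-u) / lam, 1.0 / gam)
    if censor_frac > 0:
        cmax = _censor_cap(lam, gam, censor_frac)
        c = rng.uniform(0.0, cmax, size=n)
    else:
        c = np.full(n, np.inf)
    obs = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    if followup_months is not None:
        admin = obs > followup_months
        obs = np.where(admin, followup_months, obs)
        event = np.where(admin, 0, event)
    ipd = ReconstructedIPD(obs, event)

    t_max = followup_months if followup_months is not None else float(obs.max())
    km = km_estimate(ipd, endpoint_label=label)
    # A practitioner digitizes every visible step, so clicks are dense where the
    # curve drops fast: spend half the grid budget on uniform time points and
    # half on uniform survival levels, and always include the risk anchors.
    t_grid = np.linspace(0.0, t_max, grid_size // 2 + 1)
    levels = np.linspace(1.0, float(km.surv.min()), grid_size - grid_size // 2)
    q_grid = np.interp(-levels, -km.surv, km.times)  # first time S falls to each level
    anchors = np.arange(0.0, t_max + 1e-9, risk_interval)
    grid = np.unique(np.round(np.concatenate((t_grid, q_grid, anchors)), 6))
    grid = grid[grid <= t_max + 1e-9]
    s = km.step_at(grid)
    s[0] = 1.0
    curve = DigitizedCurve(label, grid, np.minimum.accumulate(s))

    risk_times = np.arange(0.0, t_max + 1e-9, risk_interval)
    n_at_risk = np.array([(obs >= rt - 1e-12).sum() for rt in risk_times], dtype=int)
    risk = RiskTable(risk_times, n_at_risk)
    return ipd, curve, risk


def make_life_table(max_age: int = 100) -> LifeTable:
    """Synthetic annual life table in 2017-US format (age, qx).

    Gompertz-Makeham hazard with plausible US magnitudes (qx ~ 0.02 at 70,
    ~0.08 at 85, ~0.35 at 100); a stand-in for the 2017 US life table, which
    is not packaged.
    """
    ages = np.arange(0, max_age + 1)
    qx = np.clip(5e-4 + 2.6e-5 * np.exp(0.095 * ages), 0.0, 1.0)
    return LifeTable(ages, qx)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated truth plus achieved-vs-target diagnostics."""

    truth: TruthSpec
    targets: dict
    achieved: dict
    converged: bool

    def max_rel_error(self, keys=("ly_vmp", "ly_dvmp", "qaly_vmp", "qaly_dvmp")) -> float:
        return max(abs(self.achieved[k] / self.targets[k] - 1.0) for k in keys)


def _pipeline_from_weibull(x: np.ndarray, params: ParameterSet, lifetable, background: str,
                           schedules=None) -> CEPipeline:
    lam_p, gam_p, lam_o, gam_o = np.exp(x)
    return CEPipeline(
        base_pfs=SurvivalFunction("weibull", (lam_p, gam_p)),
        base_os=SurvivalFunction("weibull", (lam_o, gam_o)),
        lifetable=lifetable,
        params=params,
        schedules=schedules,
        background=background,
    )


def calibrate_fixture(
    targets: dict | None = None,
    params: ParameterSet | None = None,
    lifetable: LifeTable | None = None,
    background: str = "off",
    schedules=None,
) -> CalibrationResult:
    """Solve the comparator Weibull truth against the published base case.

    Four unknowns (lam, gam per endpoint) are solved against four targets: the
    two arms' life-years (OS curve) and QALYs (PFS curve), with the
    intervention arm derived from the comparator by the base-case hazard
    ratios. Costs are not calibrated; they follow from the regimen schedules
    and are reported in the diagnostics.

    ``background`` defaults to 'off' for this fixture: the published
    life-years are only attainable when background mortality never binds (see
    docs/methods.md).
    """
    targets = dict(PUBLISHED_BASE_CASE if targets is None else targets)
    params = params or ParameterSet()
    schedules = schedules or default_schedules()

    goal = np.array([targets["ly_vmp"], targets["ly_dvmp"],
                     targets["qaly_vmp"], targets["qaly_dvmp"]])

    def residual(x):
        pipe = _pipeline_from_weibull(x, params, lifetable, background, schedules)
        ly_c, q_c, _ = pipe.arm_outcomes(params, COMPARATOR)
        ly_i, q_i, _ = pipe.arm_outcomes(params, INTERVENTION)
        return np.array([ly_c, ly_i, q_c, q_i]) / goal - 1.0

    x0 = np.log([0.03, 1.2, 0.02, 0.9])
    markov_logger = logging.getLogger("mmcea.markov")
    prev_level = markov_logger.level
    markov_logger.setLevel(logging.ERROR)  # silence per-iteration horizon warnings
    try:
        sol = optimize.root(residual, x0, method="hybr", options={"xtol": 1e-10})
    finally:
        markov_logger.setLevel(prev_level)
    if not sol.success and np.max(np.abs(sol.fun)) > 0.02:
        raise RuntimeError(f"calibration did not converge: {sol.message}; residuals {sol.fun}")

    lam_p, gam_p, lam_o, gam_o = np.exp(sol.x)
    truth = TruthSpec(lam_pfs=lam_p, gam_pfs=gam_p, lam_os=lam_o, gam_os=gam_o,
                      hr_pfs=params.hr_pfs, hr_os=params.hr_os)
    pipe = _pipeline_from_weibull(sol.x, params, lifetable, background, schedules)
    res = pipe.evaluate()
    achieved = {
        "ly_vmp": res.ly[COMPARATOR], "ly_dvmp": res.ly[INTERVENTION],
        "qaly_vmp": res.qaly[COMPARATOR], "qaly_dvmp": res.qaly[INTERVENTION],
        "cost_vmp": res.cost[COMPARATOR], "cost_dvmp": res.cost[INTERVENTION],
        "icer_per_ly": res.icer_per_ly, "icer_per_qaly": res.icer_per_qaly,
    }
    return CalibrationResult(truth=truth, targets=targets, achieved=achieved,
                             converged=bool(sol.success))


def calibrated_pipeline(
    params: ParameterSet | None = None,
    lifetable: LifeTable | None = None,
    background: str = "off",
) -> tuple[CEPipeline, CalibrationResult]:
    """Convenience: calibrate and return the ready-to-run base-case pipeline."""
    params = params or ParameterSet()
    cal = calibrate_fixture(params=params, lifetable=lifetable, background=background)
    pipe = CEPipeline(
        base_pfs=cal.truth.survival("pfs"),
        base_os=cal.truth.survival("os"),
        lifetable=lifetable,
        params=params,
        background=background,
    )
    return pipe, cal


def generate_bundle(spec: TruthSpec, outdir) -> dict:
    """Write the full synthetic input bundle (curves, risk tables, life table,
    parameter config) into ``outdir``; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    rng = np.random.default_rng(spec.seed)
    for arm, n in ((COMPARATOR, spec.n_vmp), (INTERVENTION, spec.n_dvmp)):
        for endpoint in ("pfs", "os"):
            lam, gam = spec.weibull(endpoint, arm)
            sub = int(rng.integers(0, 2**31 - 1))
            ipd, curve, risk = simulate_arm(
                lam, gam, n, spec.censor_frac, spec.followup_months,
                spec.grid_size, spec.risk_interval, seed=sub,
                label=f"{endpoint.upper()}-{arm}",
            )
            tag = f"{endpoint}_{arm.lower().replace('-', '')}"
            curve.to_csv(p := f"{outdir}/curve_{tag}.csv"); paths[f"curve_{tag}"] = p
            risk.to_csv(p := f"{outdir}/risk_{tag}.csv"); paths[f"risk_{tag}"] = p
            ipd.to_csv(p := f"{outdir}/ipd_true_{tag}.csv"); paths[f"ipd_true_{tag}"] = p
    make_life_table().to_csv(p := f"{outdir}/life_table.csv"); paths["life_table"] = p
    ParameterSet().to_file(p := f"{outdir}/params.yaml"); paths["params"] = p
    with open(f"{outdir}/truth.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(dataclasses.asdict(spec), fh, sort_keys=False)
    paths["truth"] = f"{outdir}/truth.yaml"
    return paths
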