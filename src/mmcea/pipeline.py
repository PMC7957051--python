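"""End-to-end deterministic pipeline: survival functions -> cohort -> ICER.

``CEPipeline`` holds everything fixed across sensitivity-analysis reruns (the
comparator-fitted PFS/OS survival functions, life table, regimen schedules,
horizon and background-mortality mode) and exposes ``evaluate(params)``, which
rebuilds both arms under a (possibly perturbed) parameter set and returns the
incremental result. The intervention arm is always derived from the comparator
curves by proportional hazards, S**HR, with the HRs taken from the parameter
set so that sensitivity analyses propagate through the survival model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .economics import CEResult, ParameterSet, RegimenSchedule, accumulate, default_schedules, icer
from .markov import LifeTable, StrategyModel, run_cohort

__all__ = ["CEPipeline"]

COMPARATOR = "VMP"
INTERVENTION = "D-VMP"


@dataclass
class CEPipeline:
    """Deterministic cost-effectiveness pipeline for the two-strategy comparison."""

    base_pfs: object  # comparator PFS survival, callable with .adjusted(hr)
    base_os: object
    lifetable: LifeTable | None
    params: ParameterSet = field(default_factory=ParameterSet)
    schedules: dict[str, RegimenSchedule] | None = None
    horizon_cycles: int | None = None
    background: str = "floor"

    def __post_init__(self):
        if self.schedules is None:
            self.schedules = default_schedules()

    def arm_outcomes(self, params: ParameterSet, strategy: str) -> tuple[float, float, float]:
        """Discounted (LY, QALY, cost) for one arm under ``params``."""
        if strategy == COMPARATOR:
            model = StrategyModel(COMPARATOR, self.base_pfs, self.base_os)
        else:
            model = StrategyModel.from_comparator(
                INTERVENTION, self.base_pfs, self.base_os, params.hr_pfs, params.hr_os
            )
        trace = run_cohort(model, params.start_age, self.lifetable,
                           self.horizon_cycles, background=self.background)
        return accumulate(trace, params, self.schedules[strategy], strategy)

    def evaluate(self, overrides: dict | None = None) -> CEResult:
        """Run both arms and return the incremental result; ``overrides`` patch
        individual ``ParameterSet`` fields for sensitivity analyses."""
        params = self.params.replace(**overrides) if overrides else self.params
        comp = self.arm_outcomes(params, COMPARATOR)
        intv = self.arm_outcomes(params, INTERVENTION)
        return icer(comp, intv, labels=(COMPARATOR, INTERVENTION))
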