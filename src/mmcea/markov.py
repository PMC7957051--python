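"""Three-state Markov cohort engine (progression-free -> progressed -> dead).

The cohort starts entirely progression-free and is advanced in monthly cycles.
Per-cycle transition probabilities are derived from the fitted progression-free
survival (PFS) and overall survival (OS) functions:

- probability of leaving PFS this cycle: 1 - S_PFS(t+1)/S_PFS(t)
- probability of dying this cycle:       1 - S_OS(t+1)/S_OS(t)

The death probability applies uniformly to progression-free and progressed
occupants, which locks the cohort's overall survival to the fitted OS curve;
progression is the remainder of the PFS exit. Both probabilities can be
floored at the age-matched monthly background mortality from an annual life
table (``background='floor'``, the default) or left purely curve-driven
(``background='off'``). S_OS is clamped to be at least S_PFS before deriving
transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "StrategyModel", "CohortTrace", "transition_probs", "run_cohort"]

logger = logging.getLogger(__name__)

MAX_AGE = 100.0


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities (age in whole years, qx in [0,1])."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "qx", q)
        if a.shape != q.shape or a.ndim != 1 or len(a) == 0:
            raise ValueError("ages and qx must be equal-length 1-d arrays")
        if np.any(np.diff(a) != 1):
            raise ValueError("ages must be contiguous")
        if q.min() < 0 or q.max() > 1:
            raise ValueError("qx must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx_annual"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx_annual": self.qx}).to_csv(path, index=False)

    def annual_q(self, age: float) -> float:
        """qx at the (clamped) integer age; the last row is reused beyond the table."""
        i = int(np.clip(np.floor(age) - self.ages[0], 0, len(self.ages) - 1))
        return float(self.qx[i])

    def monthly_q(self, age: float) -> float:
        """Compound conversion of the annual probability: 1 - (1-qx)^(1/12)."""
        return 1.0 - (1.0 - self.annual_q(age)) ** (1.0 / 12.0)


@dataclass(frozen=True)
class StrategyModel:
    """One treatment arm: PFS/OS survival functions plus the HRs applied to them."""

    label: str
    pfs_surv: object  # callable S(t)
    os_surv: object
    hr_pfs: float = 1.0
    hr_os: float = 1.0

    @classmethod
    def from_comparator(cls, label, base_pfs, base_os, hr_pfs, hr_os) -> "StrategyModel":
        """Build an intervention arm by proportional-hazards adjustment S**HR."""
        return cls(label, base_pfs.adjusted(hr_pfs), base_os.adjusted(hr_os), hr_pfs, hr_os)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy. ``m_pd_inflow`` is the fraction newly progressed."""

    df: pd.DataFrame  # columns: cycle, age, m_pfs, m_pd, m_dead, m_pd_inflow

    def __len__(self):
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _curve_probs(S: np.ndarray, c: int) -> float:
    """1 - S(c+1)/S(c) with an absorbed-state guard for S -> 0."""
    if S[c] <= 1e-300:
        return 1.0
    return min(max(1.0 - S[c + 1] / S[c], 0.0), 1.0)


def transition_probs(
    strategy: StrategyModel,
    cycle: int,
    age: float,
    lifetable: LifeTable | None,
    background: str = "floor",
) -> dict:
    """Per-cycle transition probabilities at the start of ``cycle``.

    Returns ``p_pfs_exit`` (leave PFS by progression or death), ``p_pfs_death``
    and ``p_pd_death`` (equal by design; see module docstring).
    """
    t = np.array([cycle, cycle + 1], dtype=float)
    s_pfs = np.asarray(strategy.pfs_surv(t), dtype=float)
    s_os = np.maximum(np.asarray(strategy.os_surv(t), dtype=float), s_pfs)  # clamp S_OS >= S_PFS
    p_exit = _curve_probs(s_pfs, 0)
    d = _curve_probs(s_os, 0)
    if background == "floor" and lifetable is not None:
        qm = lifetable.monthly_q(age)
        p_exit = max(p_exit, qm)
        d = max(d, qm)
    return {"p_pfs_exit": p_exit, "p_pfs_death": d, "p_pd_death": d}


def run_cohort(
    strategy: StrategyModel,
    start_age: float,
    lifetable: LifeTable | None,
    horizon_cycles: int | None = None,
    background: str = "floor",
) -> CohortTrace:
    """Advance the cohort until it is absorbed, age 100, or ``horizon_cycles``.

    The default horizon is the number of months from ``start_age`` to age 100;
    the run also stops early once more than 99.9% of the cohort has died.
    """
    if background not in ("floor", "off"):
        raise ValueError("background must be 'floor' or 'off'")
    if horizon_cycles is None:
        horizon_cycles = int(np.ceil((MAX_AGE - start_age) * 12))
    H = int(horizon_cycles)

    t = np.arange(H + 1, dtype=float)
    S_pfs = np.clip(np.asarray(strategy.pfs_surv(t), dtype=float), 0.0, 1.0)
    S_os = np.maximum(np.clip(np.asarray(strategy.os_surv(t), dtype=float), 0.0, 1.0), S_pfs)
    clamped = np.any(strategy.os_surv(t) < S_pfs - 1e-12)
    if clamped:
        logger.info("%s: S_OS clamped to S_PFS on part of the horizon", strategy.label)

    rows = np.empty((H + 1, 6))
    m_pfs, m_pd, m_dead = 1.0, 0.0, 0.0
    inflow = 0.0
    for c in range(H + 1):
        age = start_age + c / 12.0
        rows[c] = (c, age, m_pfs, m_pd, m_dead, inflow)
        if c == H:
            break
        p_exit = _curve_probs(S_pfs, c)
        d = _curve_probs(S_os, c)
        if background == "floor" and lifetable is not None:
            qm = lifetable.monthly_q(age)
            p_exit = max(p_exit, qm)
            d = max(d, qm)
        p_prog = max(p_exit - d, 0.0)
        inflow = m_pfs * p_prog
        m_dead_next = m_dead + (m_pfs + m_pd) * d
        m_pd = m_pd * (1.0 - d) + inflow
        m_pfs = m_pfs * (1.0 - d - p_prog)
        m_dead = m_dead_next
        if m_dead > 0.999:
            rows = rows[: c + 2]
            age = start_age + (c + 1) / 12.0
            rows[c + 1] = (c + 1, age, m_pfs, m_pd, m_dead, inflow)
            break
    if rows[-1, 4] < 0.999:
        logger.warning(
            "%s: horizon of %d cycles absorbed only %.1f%% of the cohort",
            strategy.label, H, 100 * rows[-1, 4],
        )
    df = pd.DataFrame(rows, columns=["cycle", "age", "m_pfs", "m_pd", "m_dead", "m_pd_inflow"])
    df["cycle"] = df["cycle"].astype(int)
    return CohortTrace(df)
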