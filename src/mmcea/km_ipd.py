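"""Pseudo individual-patient-data reconstruction from digitized Kaplan-Meier curves.

Published survival figures give only the step curve and the number-at-risk
table. To refit parametric models one needs patient-level (time, event)
records, so this module inverts the product-limit estimator interval by
interval: within each risk-table interval the at-risk decrement not explained
by the curve's drops is attributed to censoring (spread uniformly over the
interval), and event counts are chosen so the recomputed KM step function
interpolates the digitized survival values. This is the interval-wise
censoring-allocation scheme of the Hoyle/Henley-Guyot family of methods.

Time is in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "ReconstructedIPD",
    "ReconstructionError",
    "reconstruct_ipd",
    "km_estimate",
    "roundtrip_error",
]


class ReconstructionError(ValueError):
    """Raised when a digitized curve and risk table are mutually infeasible."""


@dataclass(frozen=True)
class DigitizedCurve:
    """A KM step curve sampled at digitization grid points.

    ``times`` must be strictly increasing starting at 0, ``surv`` non-increasing
    in [0, 1] with ``surv[0] == 1``.
    """

    endpoint_label: str
    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", s)
        if t.ndim != 1 or s.shape != t.shape or len(t) == 0:
            raise ValueError("times and surv must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if t[0] != 0 or s[0] != 1.0:
            raise ValueError("curve must start at (0, 1.0)")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        if s.min() < 0 or s.max() > 1:
            raise ValueError("survival values must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, endpoint_label: str = "") -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(endpoint_label, df["time_months"].to_numpy(), df["survival"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.times, "survival": self.surv}).to_csv(path, index=False)

    def step_at(self, t) -> np.ndarray:
        """Evaluate the step curve (last value carried forward) at times ``t``."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.surv[np.clip(idx, 0, len(self.surv) - 1)]


@dataclass(frozen=True)
class RiskTable:
    """Number-at-risk anchors at fixed calendar times; first entry is the arm size."""

    times: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.n_at_risk, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_at_risk", n)
        if t.ndim != 1 or n.shape != t.shape or len(t) == 0:
            raise ValueError("times and n_at_risk must be equal-length 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if t[0] != 0:
            raise ValueError("risk table must start at t=0 (arm size)")
        if np.any(np.diff(n) > 0) or np.any(n < 0):
            raise ValueError("n_at_risk must be non-increasing and non-negative")

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["n_at_risk"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.times, "n_at_risk": self.n_at_risk}).to_csv(path, index=False)


@dataclass(frozen=True)
class ReconstructedIPD:
    """Per-patient (time, event) records implied by a digitized curve."""

    times: np.ndarray
    events: np.ndarray  # 1 = event, 0 = censored
    n_total: int = field(default=0)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("events must be 0/1 flags")
        n = self.n_total or len(t)
        object.__setattr__(self, "n_total", int(n))
        if self.n_total != len(t):
            raise ValueError("n_total must equal the number of records")

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_csv(cls, path) -> "ReconstructedIPD":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.times, "event": self.events}).to_csv(path, index=False)


def _largest_remainder(frac: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative fractional counts to integers summing to ``total``.

    Largest-remainder method; ties broken toward earlier indices.
    """
    frac = np.maximum(np.asarray(frac, dtype=float), 0.0)
    base = np.floor(frac).astype(int)
    short = int(total) - int(base.sum())
    if short < 0:
        # floor already exceeds the target: trim from the largest entries, late first
        order = np.argsort(base, kind="stable")[::-1]
        for i in order:
            if short == 0:
                break
            take = min(base[i], -short)
            base[i] -= take
            short += take
        return base
    rem = frac - np.floor(frac)
    # stable sort on -remainder keeps earlier indices first on ties
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: int | None = None,
    max_iter: int = 50,
    spread_events: bool = True,
) -> ReconstructedIPD:
    """Invert a digitized KM curve + risk table into pseudo patient records.

    Within each risk-table interval the algorithm iterates between (a) a
    provisional censoring count, distributed uniformly over the interval, and
    (b) event counts at each digitized drop chosen so the recomputed KM curve
    matches the digitized survival values, until the implied at-risk count at
    the interval end matches the risk table. Fractional event counts are
    integerized by largest-remainder rounding within the interval. Patients
    still at risk after the last digitized time are censored there
    (administrative censoring). If ``total_events`` is given, events in the
    final interval are adjusted so the overall event count matches it.

    With ``spread_events`` (default), the events belonging to a digitized drop
    are placed evenly across the gap back to the previous digitized point
    instead of stacked at the drop time. The true step times are only known to
    lie in that gap, and stacking them creates atoms that bias downstream
    maximum-likelihood fits on grouped times; spreading leaves the KM value at
    every digitized time unchanged.
    """
    t_d, s_d = curve.times, curve.surv
    t_r, n_r = risk.times, risk.n_at_risk
    if t_r[-1] > t_d[-1] + 1e-9:
        raise ReconstructionError("risk-table times extend beyond the digitized curve")

    # interval boundaries: risk-table times, plus the end of the digitized curve
    bounds = list(t_r)
    if t_d[-1] > t_r[-1] + 1e-9:
        bounds.append(t_d[-1])
    n_targets = list(n_r) + [None] * (len(bounds) - len(n_r))

    event_times: list[float] = []
    censor_times: list[float] = []
    n_cur = int(n_r[0])
    s_cur = 1.0  # reconstructed KM value entering the interval

    for j in range(len(bounds) - 1):
        lo, hi = bounds[j], bounds[j + 1]
        # digitized drop points inside (lo, hi]
        mask = (t_d > lo + 1e-12) & (t_d <= hi + 1e-12)
        tk = t_d[mask]
        sk = s_d[mask]
        n_end = n_targets[j + 1]

        c_j = 0.0
        d_frac = np.zeros(len(tk))
        for _ in range(max_iter):
            # censorings spread uniformly; count falling in each sub-interval (tk[i-1], tk[i]]
            n = float(n_cur)
            s_run = s_cur
            d_frac = np.zeros(len(tk))
            cen_after = np.zeros(len(tk))
            if c_j > 0 and len(tk) > 0:
                cpos = lo + (np.arange(int(round(c_j))) + 0.5) / max(round(c_j), 1) * (hi - lo)
                # censoring events assigned to the sub-interval *before* each drop point
                edges = np.concatenate(([lo], tk))
                cen_before = np.histogram(cpos, bins=np.concatenate((edges, [hi + 1e-9])))[0]
            else:
                cen_before = np.zeros(len(tk) + 1)
            for i in range(len(tk)):
                n -= cen_before[i]
                if n <= 0 or s_run <= 0:
                    break
                d = n * (1.0 - sk[i] / s_run)
                d = min(max(d, 0.0), n)
                s_run *= 1.0 - d / n
                n -= d
                d_frac[i] = d
            if n_end is None:
                break  # tail interval: no at-risk anchor, keep zero interior censoring
            c_new = n_cur - float(n_end) - d_frac.sum()
            if abs(c_new - c_j) < 0.5:
                c_j = max(c_new, 0.0)
                break
            c_j = max(c_new, 0.0)

        # integerize event counts for this interval
        if n_end is not None:
            decrement = n_cur - int(n_end)
            if decrement < 0:
                raise ReconstructionError(
                    f"risk table infeasible in interval [{lo}, {hi}]: at-risk count increases"
                )
            d_int = _largest_remainder(d_frac, int(round(d_frac.sum())))
            c_int = decrement - int(d_int.sum())
            if c_int < 0:
                raise ReconstructionError(
                    f"risk table infeasible in interval [{lo}, {hi}]: implied censorings negative"
                )
        else:
            d_int = _largest_remainder(d_frac, int(round(d_frac.sum())))
            c_int = 0

        for i, tki in enumerate(tk):
            d = int(d_int[i])
            if d == 0:
                continue
            if spread_events:
                # previous digitized point (global grid) = left end of the gap;
                # midpoints keep every event strictly inside (prev, tki), so a
                # subject with an event in the gap is not counted at risk at a
                # boundary anchor
                j_prev = int(np.searchsorted(t_d, tki - 1e-12)) - 1
                prev = float(t_d[j_prev]) if j_prev >= 0 else 0.0
                event_times.extend((prev + (np.arange(d) + 0.5) / d * (tki - prev)).tolist())
            else:
                event_times.extend([tki] * d)
        if c_int > 0:
            cpos = lo + (np.arange(c_int) + 0.5) / c_int * (hi - lo)
            censor_times.extend(cpos.tolist())
        n_cur -= int(d_int.sum()) + c_int
        # re-walk with integer counts to keep the running KM value consistent
        n = float(n_cur + int(d_int.sum()) + c_int)
        s_run = s_cur
        if n_end is not None and c_int > 0 and len(tk) > 0:
            cpos = np.asarray(censor_times[-c_int:])
            edges = np.concatenate(([lo], tk))
            cen_before = np.histogram(cpos, bins=np.concatenate((edges, [hi + 1e-9])))[0]
        else:
            cen_before = np.zeros(len(tk) + 1)
        for i in range(len(tk)):
            n -= cen_before[i]
            if n > 0 and d_int[i] > 0:
                s_run *= 1.0 - d_int[i] / n
            n -= d_int[i]
        s_cur = s_run

    if total_events is not None:
        have = len(event_times)
        delta = int(total_events) - have
        if delta > 0:
            # promote the latest censorings (interval or administrative) to
            # events at their own times
            n_admin = min(delta, n_cur)
            event_times.extend([t_d[-1]] * n_admin)
            n_cur -= n_admin
            delta -= n_admin
            if delta > 0:
                censor_times.sort()
                promoted = censor_times[-delta:]
                censor_times = censor_times[:-delta]
                event_times.extend(promoted)
        elif delta < 0:
            # demote the latest events to censorings at their own times
            event_times.sort()
            demoted = event_times[delta:]
            event_times = event_times[:delta]
            censor_times.extend(demoted)

    # administrative censoring of everyone still at risk
    censor_times.extend([t_d[-1]] * n_cur)

    times = np.concatenate((event_times, censor_times)) if event_times or censor_times else np.array([])
    events = np.concatenate((np.ones(len(event_times), dtype=int), np.zeros(len(censor_times), dtype=int)))
    order = np.lexsort((1 - events, times))
    return ReconstructedIPD(times[order], events[order], n_total=int(n_r[0]))


def km_estimate(ipd: ReconstructedIPD, endpoint_label: str = "KM") -> DigitizedCurve:
    """Product-limit estimator of ``ipd``, evaluated at 0 and every event time."""
    if len(ipd.times) == 0:
        raise ValueError("cannot estimate a KM curve from empty records")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    ev = np.unique(ipd.times[ipd.events == 1])
    t = np.concatenate(([0.0], ev))
    s = np.atleast_1d(np.asarray(kmf.predict(t), dtype=float))
    s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    s[0] = 1.0
    return DigitizedCurve(endpoint_label, t, s)


def roundtrip_error(curve: DigitizedCurve, ipd: ReconstructedIPD) -> float:
    """Max |KM(ipd) - s| over the digitized grid — the reconstruction fidelity."""
    km = km_estimate(ipd)
    return float(np.max(np.abs(km.step_at(curve.times) - curve.surv)))
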