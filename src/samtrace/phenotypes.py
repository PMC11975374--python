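"""Developmental-timing and survival statistics.

Pupation is treated as the event in a survival framework: cumulative
percent-pupated curves per arm, a t50 delay estimator (time to 50% of each
arm's own final pupation fraction, linearly interpolated between census
points), log-rank comparisons, survival-to-adult percentages with
melanized-egg exclusion, and lamellocyte summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .isotopologue import group_compare

logger = logging.getLogger(__name__)


@dataclass
class PupationCurve:
    """Step function of cumulative percent pupated vs h AEL."""

    arm: str
    times: np.ndarray      # census times with at least one new pupa
    percent: np.ndarray    # cumulative % of all larvae in the arm
    n_total: int

    @property
    def plateau(self) -> float:
        return float(self.percent[-1]) if len(self.percent) else 0.0

    def t50(self) -> float:
        """Interpolated time at 50% of this arm's final pupation fraction."""
        if self.plateau <= 0:
            raise ValueError(f"arm {self.arm!r}: no larva pupated")
        target = 0.5 * self.plateau
        pct = np.concatenate([[0.0], self.percent])
        t = np.concatenate([[self.times[0] - 1e-9], self.times])
        idx = int(np.searchsorted(pct, target))
        if idx == 0:
            return float(t[0])
        lo_p, hi_p = pct[idx - 1], pct[idx]
        lo_t, hi_t = t[idx - 1], t[idx]
        if hi_p == lo_p:
            return float(hi_t)
        return float(lo_t + (target - lo_p) / (hi_p - lo_p) * (hi_t - lo_t))


def pupation_curve(data: pd.DataFrame, arm: str) -> PupationCurve:
    """Build the cumulative pupation curve of one arm.

    The curve is non-decreasing and plateaus at ``pupated / total * 100``;
    larvae that never pupate in the observation window only contribute to
    the denominator.
    """
    sub = data[data["arm"] == arm]
    if sub.empty:
        raise ValueError(f"unknown or empty arm: {arm!r}")
    n = len(sub)
    events = sub[sub["pupated"]]
    times = np.sort(events["pupation_h_AEL"].unique())
    counts = events.groupby("pupation_h_AEL").size().reindex(times).to_numpy()
    percent = 100.0 * np.cumsum(counts) / n
    return PupationCurve(arm=arm, times=times, percent=percent, n_total=n)


@dataclass
class DelayEstimate:
    delta_h: float
    ci95: tuple[float, float] | None
    t50_a: float
    t50_b: float


def pupation_delay(
    data: pd.DataFrame,
    arm_a: str,
    arm_b: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> DelayEstimate:
    """t50 delay of ``arm_b`` relative to ``arm_a`` with a bootstrap CI.

    Both arms must reach 50% of their own plateau; the CI is a percentile
    interval over larva-level resamples within each arm.
    """
    curve_a = pupation_curve(data, arm_a)
    curve_b = pupation_curve(data, arm_b)
    for c in (curve_a, curve_b):
        if c.plateau <= 0:
            raise ValueError(f"arm {c.arm!r} never reaches its 50% landmark")
    delta = curve_b.t50() - curve_a.t50()

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sub_a = data[data["arm"] == arm_a].reset_index(drop=True)
        sub_b = data[data["arm"] == arm_b].reset_index(drop=True)
        deltas = []
        for _ in range(n_boot):
            ra = sub_a.sample(len(sub_a), replace=True,
                              random_state=rng.integers(2**31))
            rb = sub_b.sample(len(sub_b), replace=True,
                              random_state=rng.integers(2**31))
            try:
                d = (pupation_curve(rb, arm_b).t50()
                     - pupation_curve(ra, arm_a).t50())
            except ValueError:
                continue
            deltas.append(d)
        if deltas:
            lo, hi = np.percentile(deltas, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return DelayEstimate(delta_h=float(delta), ci95=ci,
                         t50_a=curve_a.t50(), t50_b=curve_b.t50())


def logrank(data: pd.DataFrame, arm_a: str, arm_b: str) -> dict:
    """Log-rank comparison of two arms' pupation curves.

    Pupation is the event; larvae that never pupate are right-censored at
    their last observation time.
    """
    sub_a = data[data["arm"] == arm_a]
    sub_b = data[data["arm"] == arm_b]
    for arm, sub in ((arm_a, sub_a), (arm_b, sub_b)):
        if sub.empty:
            raise ValueError(f"unknown or empty arm: {arm!r}")
    if not (sub_a["pupated"].any() or sub_b["pupated"].any()):
        raise ValueError("no pupation events in the pooled data")
    res = logrank_test(
        sub_a["pupation_h_AEL"], sub_b["pupation_h_AEL"],
        event_observed_A=sub_a["pupated"], event_observed_B=sub_b["pupated"])
    return {"statistic": float(res.test_statistic),
            "p_value": float(res.p_value)}


def survival_to_adult(records: pd.DataFrame) -> pd.DataFrame:
    """Percent surviving to adulthood per arm.

    For infected arms, adults lacking a melanized wasp egg were never
    actually infected: they are excluded from both numerator and
    denominator.  Uninfected arms use plain adults / larvae.
    """
    rows = []
    for arm, sub in records.groupby("arm"):
        if sub.empty:
            raise ValueError(f"empty arm: {arm!r}")
        infected = bool(sub["infected"].iloc[0])
        adults = sub[sub["adult"]]
        if infected:
            egg_free_adults = int((~adults["egg_present"]).sum())
            numerator = int(adults["egg_present"].sum())
            denominator = len(sub) - egg_free_adults
        else:
            numerator = len(adults)
            denominator = len(sub)
        pct = 100.0 * numerator / denominator if denominator else np.nan
        rows.append((arm, infected, numerator, denominator, pct))
    return pd.DataFrame(rows, columns=["arm", "infected", "survivors",
                                       "denominator", "percent_survival"])


def lamellocyte_summary(
    records: pd.DataFrame, control_arm: str,
) -> pd.DataFrame:
    """Per-arm lamellocyte means with an unpaired t test vs the control arm.

    Arms with a single larva are summarized but their comparison is skipped
    with a warning.
    """
    if control_arm not in set(records["arm"]):
        raise ValueError(f"unknown control arm: {control_arm!r}")
    control = records.loc[records["arm"] == control_arm, "lamellocytes"]
    rows = []
    for arm, sub in records.groupby("arm"):
        counts = sub["lamellocytes"].to_numpy(dtype=float)
        mean = float(counts.mean())
        p = np.nan
        if arm != control_arm:
            if len(counts) < 2 or len(control) < 2:
                logger.warning("arm %s: single-larva arm, comparison skipped",
                               arm)
            else:
                res = group_compare({control_arm: control.to_numpy(float),
                                     arm: counts})
                p = res["p_value"]
        rows.append((arm, len(counts), mean, p))
    return pd.DataFrame(rows, columns=["arm", "n", "mean_lamellocytes",
                                       "p_vs_control"])
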