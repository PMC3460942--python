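"""Kaplan-Meier curves, logrank test, and univariate hazard ratio for risk groups.

The classifier's high/low risk calls are evaluated on follow-up data with the
product-limit survival estimate per group, the two-group logrank test, and a
univariate proportional-hazards coefficient for the group indicator. The
hazard ratio is fit by Newton iterations on the Breslow partial likelihood
(simplest standard tie handling); the observed/expected event ratio is also
reported. Censored observations at an event time are processed after the
events at that time (the standard convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) at the sorted distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival function must be non-increasing")


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    hazard_ratio: float
    observed: np.ndarray  # events per group (group 0, group 1)
    expected: np.ndarray
    oe_hazard_ratio: float  # (O1/E1) / (O0/E0), reported alongside the PH fit
    log_hr_se: float


def _validate(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if times.shape != events.shape:
        raise ValueError("times and events must be aligned")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if set(np.unique(events)) - {0.0, 1.0}:
        raise ValueError("events must be binary 0/1")
    return times, events.astype(int)


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator over the distinct event times."""
    times, events = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    has_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[has_event]
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()[
        has_event.to_numpy()
    ]
    return SurvivalCurve(
        event_times=event_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy()[has_event.to_numpy()],
        n_events=table["observed"].to_numpy()[has_event.to_numpy()],
    )


def median_survival(curve: SurvivalCurve) -> float:
    """Smallest event time with S(t) <= 0.5; NaN when the curve never reaches 0.5."""
    below = curve.survival <= 0.5 + 1e-12  # tolerate product-limit round-off at exactly 0.5
    if not np.any(below):
        warnings.warn("survival never reaches 0.5; median undefined")
        return float("nan")
    return float(curve.event_times[np.argmax(below)])


def _breslow_newton(times, events, group, max_iter=50, tol=1e-12, cap=20.0):
    """Univariate PH coefficient for a binary covariate, Breslow tie handling."""
    order = np.argsort(times, kind="mergesort")
    t, e, x = times[order], events[order], group[order]
    ev_times = np.unique(t[e == 1])
    # per distinct event time: events in group 1, total events, risk counts
    d1 = np.array([int(((t == u) & (e == 1) & (x == 1)).sum()) for u in ev_times])
    d = np.array([int(((t == u) & (e == 1)).sum()) for u in ev_times])
    n1 = np.array([int(((t >= u) & (x == 1)).sum()) for u in ev_times])
    n0 = np.array([int(((t >= u) & (x == 0)).sum()) for u in ev_times])
    m1 = int(d1.sum())
    b = 0.0
    for _ in range(max_iter):
        eb = np.exp(b)
        denom = n0 + n1 * eb
        U = m1 - float((d * n1 * eb / denom).sum())
        I = float((d * n0 * n1 * eb / denom**2).sum())
        if I <= 0:
            break
        step = U / I
        b = float(np.clip(b + step, -cap, cap))
        if abs(step) < tol or abs(b) >= cap:
            break
    if abs(b) >= cap:
        warnings.warn("hazard-ratio estimate diverged (monotone likelihood); capped")
    eb = np.exp(b)
    I = float((d * n0 * n1 * eb / (n0 + n1 * eb) ** 2).sum())
    se = float(1.0 / np.sqrt(I)) if I > 0 else float("inf")
    return b, se


def fit_hazard_ratio(times, events, group):
    """Hazard ratio (group 1 vs group 0) from the Breslow partial likelihood."""
    times, events = _validate(times, events)
    group = np.asarray(group, dtype=int)
    b, se = _breslow_newton(times, events, group)
    return float(np.exp(b)), se


def logrank_test(times, events, group) -> LogrankResult:
    """Two-group logrank test plus the univariate proportional-hazards ratio.

    The chi-square statistic (1 df) comes from the standard hypergeometric
    observed-minus-expected sum; the hazard ratio from a Breslow partial-
    likelihood fit of the group indicator, with the cruder observed/expected
    ratio reported alongside.
    """
    times, events = _validate(times, events)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    g = (group == levels[1]).astype(int)
    if events.sum() == 0:
        raise ValueError("no events observed in either group")
    res = _ll_logrank(times[g == 0], times[g == 1], events[g == 0], events[g == 1])
    observed = np.array([int(events[g == 0].sum()), int(events[g == 1].sum())])
    # expected events per group from the hypergeometric expectation at each event time
    ev_times = np.unique(times[events == 1])
    e1 = 0.0
    for u in ev_times:
        at_risk = times >= u
        d = int(((times == u) & (events == 1)).sum())
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        e1 += d * n1 / n
    expected = np.array([events.sum() - e1, e1])
    hr, se = fit_hazard_ratio(times, events, g)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = (observed[1] / expected[1]) / (observed[0] / expected[0])
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        hazard_ratio=hr,
        observed=observed,
        expected=expected,
        oe_hazard_ratio=float(oe),
        log_hr_se=se,
    )


def group_curves(times, events, group) -> dict:
    """Kaplan-Meier curve per group level (keys are the group labels)."""
    times, events = _validate(times, events)
    group = np.asarray(group)
    return {
        lvl: km_curve(times[group == lvl], events[group == lvl])
        for lvl in np.unique(group)
    }


def plot_km(times, events, group, ax=None, labels=None):
    """Step plot of the per-group Kaplan-Meier curves (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    times = np.asarray(times, dtype=float)
    group = np.asarray(group)
    for lvl in np.unique(group):
        kmf = KaplanMeierFitter()
        mask = group == lvl
        name = labels.get(lvl, str(lvl)) if labels else str(lvl)
        kmf.fit(times[mask], np.asarray(events)[mask], label=name)
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("relapse-free fraction")
    return ax
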