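"""Outcome estimation from trajectories: survival, MCC, LOS, contrasts, bands.

Survival here is all-cause: death is the only absorbing risk, so the
cumulative incidence of death is exactly ``1 - S(t)``.  Recurrent
ED/hospital events are summarized by the Mean Cumulative Count (MCC) — the
expected cumulative number of events per person by time t with death acting
as a competing risk.  Two estimators are provided: a direct count for fully
followed (simulated) cohorts, and the Dong et al. sum-of-increments
estimator ``MCC(t) = sum_{u <= t} S(u-) d(u) / r(u)`` for tables with
censoring, where ``S`` is the Kaplan-Meier overall-survival estimate,
``d(u)`` the number of events of interest at u and ``r(u)`` the number at
risk just before u.  The two coincide when nobody is censored.

Replicate-level uncertainty from the nested simulation is summarized by
pointwise empirical percentile bands, optionally smoothed with a
monotonicity-preserving (PCHIP) spline on thinned knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .states import EVENT_TYPES, HOSPITAL_STATES, MO, Trajectory

__all__ = [
    "OutcomeCurves",
    "ConfidenceBand",
    "LOSSummary",
    "survival_curve",
    "cohort_outcomes",
    "mcc_naive",
    "mcc_dong",
    "los_summary",
    "contrast",
    "empirical_band",
    "write_curves",
    "plot_outcome_panels",
]


@dataclass
class OutcomeCurves:
    """Time-gridded outcome summary of one cohort (or one replicate)."""

    grid: np.ndarray  # days
    survival: np.ndarray
    mcc: Dict[str, np.ndarray] = field(default_factory=dict)
    n: int = 0

    @property
    def cumulative_incidence(self) -> np.ndarray:
        """All-cause death incidence; complements survival exactly."""
        return 1.0 - self.survival


@dataclass
class ConfidenceBand:
    """Pointwise empirical band around a replicate mean."""

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    raw_lower: Optional[np.ndarray] = None
    raw_upper: Optional[np.ndarray] = None

    def covers(self, values: np.ndarray) -> np.ndarray:
        """Closed-interval coverage of an observed curve on the same grid."""
        v = np.asarray(values, dtype=float)
        return (self.lower <= v) & (v <= self.upper)


@dataclass
class LOSSummary:
    n_stays: int
    mean: float
    lower: float
    upper: float
    level: float = 0.95


class EmptySummaryError(ValueError):
    """No qualifying stays (or events) to summarize."""


def survival_curve(
    trajectories: Sequence[Trajectory], grid: np.ndarray
) -> np.ndarray:
    """Proportion of subjects alive (not yet absorbed) at each grid time.

    All subjects share the simulation origin; the only censoring is the
    common horizon, so the estimate is the empirical complement of the
    death-time distribution.
    """
    if len(trajectories) == 0:
        raise ValueError("no trajectories")
    grid = np.asarray(grid, dtype=float)
    deaths = np.array(
        [tr.death_time for tr in trajectories if tr.died], dtype=float
    )
    if deaths.size == 0:
        return np.ones_like(grid)
    deaths.sort()
    n = len(trajectories)
    return 1.0 - np.searchsorted(deaths, grid, side="right") / n


def mcc_naive(
    trajectories: Sequence[Trajectory], event_type: str, grid: np.ndarray
) -> np.ndarray:
    """Mean cumulative event count per person under full follow-up.

    Total events of the type at or before each grid time divided by the
    initial cohort size; the dead contribute no further events by
    construction of the trajectories.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}; one of {EVENT_TYPES}")
    if len(trajectories) == 0:
        raise ValueError("no trajectories")
    grid = np.asarray(grid, dtype=float)
    times = np.sort(np.concatenate(
        [np.asarray(tr.event_times(event_type), dtype=float) for tr in trajectories]
    )) if trajectories else np.array([])
    n = len(trajectories)
    return np.searchsorted(times, grid, side="right") / n


def mcc_dong(
    event_table: pd.DataFrame, grid: np.ndarray
) -> np.ndarray:
    """Dong et al. MCC estimator for recurrent events with death and censoring.

    ``event_table`` has one row per subject: ``event_times`` (sequence of
    event times), ``followup`` (death or censoring time) and ``died``
    (bool).  At each event time u the curve jumps by S(u-) d(u)/r(u), with
    S the Kaplan-Meier estimate of overall survival (death = event,
    censoring = censored) and r(u) the number still at risk just before u.
    """
    from lifelines import KaplanMeierFitter

    grid = np.asarray(grid, dtype=float)
    followup = event_table["followup"].to_numpy(dtype=float)
    died = event_table["died"].to_numpy(dtype=bool)
    ev_times: List[float] = []
    for times, fu in zip(event_table["event_times"], followup):
        t = np.asarray(list(times), dtype=float)
        if np.any(t > fu):
            raise ValueError("event after the subject's death/censoring time")
        ev_times.extend(t.tolist())
    km = KaplanMeierFitter().fit(followup, event_observed=died)

    u, d = np.unique(np.asarray(ev_times, dtype=float), return_counts=True)
    if u.size == 0:
        return np.zeros_like(grid)
    # at risk just before u: followup >= u (events can occur at the death day)
    r = (followup[None, :] >= u[:, None]).sum(axis=1).astype(float)
    # left limit of the KM curve at u
    s_minus = np.asarray(
        km.survival_function_at_times(np.nextafter(u, -np.inf)), dtype=float
    )
    jumps = np.where(r > 0, s_minus * d / r, 0.0)
    mcc_at_u = np.cumsum(jumps)
    idx = np.searchsorted(u, grid, side="right") - 1
    out = np.where(idx >= 0, mcc_at_u[np.clip(idx, 0, None)], 0.0)
    return out


def event_table_from_trajectories(
    trajectories: Sequence[Trajectory], event_type: str
) -> pd.DataFrame:
    """Per-subject (event_times, followup, died) table for :func:`mcc_dong`."""
    rows = []
    for tr in trajectories:
        rows.append({
            "subject": tr.subject_id,
            "event_times": tr.event_times(event_type),
            "followup": tr.end_time,
            "died": tr.died,
        })
    return pd.DataFrame(rows)


def cohort_outcomes(
    trajectories: Sequence[Trajectory],
    grid: np.ndarray,
    event_types: Sequence[str] = EVENT_TYPES,
) -> OutcomeCurves:
    """Bundle survival and the requested MCC curves for one trajectory set."""
    grid = np.asarray(grid, dtype=float)
    return OutcomeCurves(
        grid=grid,
        survival=survival_curve(trajectories, grid),
        mcc={et: mcc_naive(trajectories, et, grid) for et in event_types},
        n=len(trajectories),
    )


def los_summary(
    trajectories: Sequence[Trajectory],
    hospital_state: str,
    discharged_alive_only: bool = True,
    level: float = 0.95,
) -> LOSSummary:
    """Mean length of stay (days) in one hospital state, with a normal CI.

    ``discharged_alive_only`` drops stays that end in death, matching the
    usual reporting convention for hospital LOS.
    """
    if hospital_state not in HOSPITAL_STATES:
        raise ValueError(f"{hospital_state} is not a hospital state")
    los = []
    for tr in trajectories:
        for entry, exit_, nxt in tr.hospital_stays(hospital_state):
            if discharged_alive_only and nxt == MO:
                continue
            los.append(exit_ - entry)
    if not los:
        raise EmptySummaryError(
            f"no qualifying {hospital_state} stays"
            + (" (discharged alive)" if discharged_alive_only else "")
        )
    arr = np.asarray(los, dtype=float)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    return LOSSummary(arr.size, mean, mean - z * se, mean + z * se, level)


def contrast(
    a: np.ndarray, b: np.ndarray, mode: str = "absolute",
    grid_a: Optional[np.ndarray] = None, grid_b: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pointwise difference of two curves on a common grid.

    ``absolute`` is a - b; ``relative`` is 100 (a - b) / b, with NaN where
    b = 0 (flagged, never fabricated).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if grid_a is not None and grid_b is not None and not np.array_equal(grid_a, grid_b):
        raise ValueError("curves are on different grids")
    if a.shape != b.shape:
        raise ValueError("curves are on different grids")
    if mode == "absolute":
        return a - b
    if mode == "relative":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * (a - b) / b
        return np.where(b == 0, np.nan, out)
    raise ValueError("mode must be 'absolute' or 'relative'")


def _pchip_smooth(grid: np.ndarray, y: np.ndarray, n_knots: int) -> np.ndarray:
    """Shape-preserving smoothing: PCHIP through thinned knots.

    PCHIP through monotone knot values is monotone between knots, so a
    monotone percentile curve stays monotone after smoothing.
    """
    finite = np.isfinite(y)
    if finite.sum() < 4 or len(grid) <= n_knots:
        return y
    idx = np.unique(np.linspace(0, len(grid) - 1, n_knots).round().astype(int))
    sm = PchipInterpolator(grid[idx], y[idx])(grid)
    return np.where(finite, sm, y)


def empirical_band(
    replicate_curves: Sequence[np.ndarray],
    grid: np.ndarray,
    level: float = 0.95,
    smooth: bool = True,
    n_knots: int = 25,
) -> ConfidenceBand:
    """Pointwise empirical percentile band across nested-simulation replicates.

    Percentiles (e.g. 2.5/97.5) are taken across replicates at each grid
    point and optionally smoothed by a monotone spline; raw percentiles are
    always kept alongside.  The band is clipped to bracket the replicate
    mean pointwise.
    """
    curves = np.asarray(list(replicate_curves), dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need at least two replicate curves")
    grid = np.asarray(grid, dtype=float)
    alpha = (1.0 - level) / 2.0
    mean = curves.mean(axis=0)
    raw_lo = np.quantile(curves, alpha, axis=0)
    raw_hi = np.quantile(curves, 1.0 - alpha, axis=0)
    lo, hi = raw_lo, raw_hi
    if smooth:
        lo = _pchip_smooth(grid, raw_lo, n_knots)
        hi = _pchip_smooth(grid, raw_hi, n_knots)
    lo = np.minimum(lo, mean)
    hi = np.maximum(hi, mean)
    return ConfidenceBand(grid, mean, lo, hi, level, raw_lo, raw_hi)


def write_curves(band: ConfidenceBand, path) -> None:
    """Delimited-text curve export: time_days, estimate, lower, upper."""
    pd.DataFrame({
        "time_days": band.grid,
        "estimate": band.mean,
        "lower": band.lower,
        "upper": band.upper,
    }).to_csv(path, index=False)


def plot_outcome_panels(
    bands: Dict[str, Dict[str, ConfidenceBand]],
    path=None,
    outcomes: Sequence[str] = ("survival", "copd_ed", "copd_hosp"),
    titles: Optional[Dict[str, str]] = None,
):
    """Panel figure: one column per outcome, one shaded band per group.

    ``bands`` maps group label -> outcome name -> band.  Returns the figure;
    saves to ``path`` (vector format by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    default_titles = {
        "survival": "All-cause survival",
        "copd_ed": "MCC, COPD-related ED visits",
        "other_ed": "MCC, other ED visits",
        "copd_hosp": "MCC, COPD-related hospitalizations",
        "other_hosp": "MCC, other hospitalizations",
    }
    titles = {**default_titles, **(titles or {})}
    fig, axes = plt.subplots(
        1, len(outcomes), figsize=(4.2 * len(outcomes), 3.4), squeeze=False
    )
    for j, out in enumerate(outcomes):
        ax = axes[0, j]
        for label, group in bands.items():
            band = group[out]
            years = band.grid / 365.25
            ax.plot(years, band.mean, label=label)
            ax.fill_between(years, band.lower, band.upper, alpha=0.25)
        ax.set_title(titles.get(out, out))
        ax.set_xlabel("Years since diagnosis")
        if j == 0:
            ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
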