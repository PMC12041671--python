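"""Discrete-time Bayesian time-to-event model for GTN after hCG normalisation.

Follow-up from the first normal hCG value is divided into contiguous
half-open intervals ``[start, end)`` in 30-day months (default width 3, horizon
90).  Within each interval * group cell the number of events among patients
still at risk is binomial, ``d_kg ~ Binomial(n_kg, h_kg)`` with
``logit(h_kg) = alpha_kg`` and an independent ``Normal(-12, 3)`` prior — lower
than the overall-incidence prior because a single time window carries only a
fraction of the total risk.  The parameterisation is saturated (one
coefficient per cell, no pooling or smoothing), so each cell's posterior is
one-dimensional; cumulative incidence is accumulated per posterior draw as
``1 - prod_k (1 - h_kg)``, giving median curves with 95% credible bands (the
Bayesian analogue of a Kaplan-Meier life table).

Risk-set conventions (whole-day data, exact event times in months = days/30):
an event occurring inside interval k keeps the patient at risk through k; a
patient censored at time c is at risk in every interval whose start is
strictly before c, so censoring exactly at an interval start removes the
patient from that interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_CUTOFF_DAYS, Group, Outcome, PatientRecord, assign_group
from .inference import (
    HAZARD_PRIOR,
    McmcConfig,
    PosteriorDraws,
    PosteriorSummary,
    PriorSpec,
    inv_logit,
    sample_posterior_1d,
    split_rhat,
)

__all__ = [
    "RiskTable",
    "HazardFit",
    "CumulativeIncidenceCurve",
    "RiskAtTime",
    "build_risk_table",
    "fit_interval_hazards",
    "cumulative_incidence",
    "risk_at_time",
]

_GROUPS = (Group.EARLY, Group.LATE)


@dataclass
class RiskTable:
    """Interval * group at-risk/event/censoring counts (a grouped life table).

    ``edges`` holds the K+1 finite interval boundaries in months; when any
    event falls at or beyond the horizon an extra open-ended interval
    ``[horizon, inf)`` is appended and ``overflow_flagged`` is set, in which
    case the count arrays have K+1 entries.
    """

    edges: np.ndarray
    n_at_risk: Dict[Group, np.ndarray]
    events: Dict[Group, np.ndarray]
    censored: Dict[Group, np.ndarray]
    overflow_flagged: bool = False

    @property
    def n_intervals(self) -> int:
        return len(self.events[Group.EARLY])

    @property
    def interval_ends(self) -> np.ndarray:
        """Finite interval end times; the overflow interval has none."""
        ends = self.edges[1:]
        return ends

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n_finite = len(self.edges) - 1
        for g in _GROUPS:
            for k in range(self.n_intervals):
                start = self.edges[k]
                end = self.edges[k + 1] if k + 1 <= n_finite else np.inf
                rows.append(
                    {
                        "group": g.value,
                        "t_start_months": float(start),
                        "t_end_months": float(end),
                        "n_at_risk": int(self.n_at_risk[g][k]),
                        "events": int(self.events[g][k]),
                        "censored": int(self.censored[g][k]),
                    }
                )
        return pd.DataFrame(rows)


def build_risk_table(
    cohort: Sequence[PatientRecord],
    interval_months: float = 3.0,
    horizon_months: float = 90.0,
    cutoff_days: int = DEFAULT_CUTOFF_DAYS,
) -> RiskTable:
    """Tabulate at-risk counts, events and censorings per interval and group.

    Event and censoring times are the exact quotient days/30 (no presentation
    rounding).  Events at or beyond the horizon go into a flagged open-ended
    final interval.  Censored patients are assigned, for bookkeeping, to the
    last interval in which they were at risk, so that within each group
    ``n_at_risk[k+1] = n_at_risk[k] - events[k] - censored[k]`` holds over the
    finite intervals.
    """
    if interval_months <= 0 or horizon_months <= 0:
        raise ValueError("interval and horizon must be positive")
    n_finite = int(np.ceil(horizon_months / interval_months))
    edges = np.arange(n_finite + 1, dtype=float) * interval_months

    times = {g: {"event": [], "censor": []} for g in _GROUPS}
    for rec in cohort:
        g = assign_group(rec, cutoff_days)
        kind = "event" if rec.outcome is Outcome.GTN else "censor"
        times[g][kind].append(rec.days_normal_to_end / 30.0)

    overflow = any(t >= horizon_months for g in _GROUPS for t in times[g]["event"])
    n_cells = n_finite + (1 if overflow else 0)
    # one start per cell; the overflow cell, when present, starts at the horizon
    cell_starts = edges[:-1] if not overflow else np.append(edges[:-1], horizon_months)

    n_at_risk = {}
    events = {}
    censored = {}
    for g in _GROUPS:
        t_ev = np.asarray(times[g]["event"])
        t_cen = np.asarray(times[g]["censor"])
        # events: half-open [start, end), so a boundary event falls in the
        # later interval; an event keeps its patient at risk through its own cell
        ev_cell = np.searchsorted(cell_starts, t_ev, side="right") - 1
        events[g] = np.bincount(ev_cell, minlength=n_cells).astype(int)
        # censored: at risk in cell k iff censor time > start_k (strict), so
        # censoring exactly at a start removes the patient from that cell;
        # bookkeeping assigns each censored patient to the last at-risk cell
        cen_cell = np.searchsorted(cell_starts, t_cen, side="left") - 1
        cen_cell = cen_cell[cen_cell >= 0]  # censored at time 0: never at risk
        censored[g] = np.bincount(cen_cell, minlength=n_cells).astype(int)
        # at risk in cell k = all patients whose terminal cell is >= k
        terminal = np.concatenate([ev_cell, cen_cell]).astype(int)
        term_hist = np.bincount(terminal, minlength=n_cells)
        n_at_risk[g] = term_hist[::-1].cumsum()[::-1].astype(int)

    return RiskTable(
        edges=edges,
        n_at_risk=n_at_risk,
        events=events,
        censored=censored,
        overflow_flagged=overflow,
    )


@dataclass
class HazardFit:
    """Posterior hazard draws per interval * group cell."""

    table: RiskTable
    prior: PriorSpec
    draws: Dict[Group, List[PosteriorDraws]]
    rhat: Dict[Group, np.ndarray]
    prior_only: Dict[Group, np.ndarray]  # True where n_at_risk == 0

    def hazard_summary(self) -> pd.DataFrame:
        rows = []
        for g in _GROUPS:
            for k, d in enumerate(self.draws[g]):
                p = inv_logit(d.pooled())
                q = np.percentile(p, (2.5, 50.0, 97.5))
                rows.append(
                    {
                        "group": g.value,
                        "interval": k,
                        "q2.5": q[0],
                        "median": q[1],
                        "q97.5": q[2],
                        "rhat": float(self.rhat[g][k]),
                        "prior_only": bool(self.prior_only[g][k]),
                    }
                )
        return pd.DataFrame(rows)


def fit_interval_hazards(
    table: RiskTable,
    prior: PriorSpec = HAZARD_PRIOR,
    config: McmcConfig = McmcConfig(),
) -> HazardFit:
    """Fit one independent 1-D posterior per interval * group cell.

    Cells with no patients at risk return the prior pushforward (the sampler
    run against an empty likelihood) and are flagged ``prior_only``; with the
    default prior their hazard median is expit(-12), about 6 per million, so
    credible bands stay essentially at zero where no data exist.
    """
    draws: Dict[Group, List[PosteriorDraws]] = {}
    rhat: Dict[Group, np.ndarray] = {}
    prior_only: Dict[Group, np.ndarray] = {}
    cell_index = 0
    for g in _GROUPS:
        per_group: List[PosteriorDraws] = []
        rh = np.empty(table.n_intervals)
        po = np.zeros(table.n_intervals, dtype=bool)
        for k in range(table.n_intervals):
            n = int(table.n_at_risk[g][k])
            y = int(table.events[g][k])
            cfg = replace(config, seed=config.seed + cell_index)
            d = sample_posterior_1d(y, n, prior, cfg, name=f"alpha[{g.value},{k}]")
            per_group.append(d)
            rh[k] = split_rhat(d)
            po[k] = n == 0
            cell_index += 1
        draws[g] = per_group
        rhat[g] = rh
        prior_only[g] = po
    return HazardFit(table=table, prior=prior, draws=draws, rhat=rhat, prior_only=prior_only)


@dataclass
class CumulativeIncidenceCurve:
    """Posterior cumulative incidence at each finite interval end."""

    group: Group
    t_end_months: np.ndarray
    q2_5: np.ndarray
    median: np.ndarray
    q97_5: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group.value,
                "t_end_months": self.t_end_months,
                "q2.5": self.q2_5,
                "median": self.median,
                "q97.5": self.q97_5,
            }
        )


def cumulative_incidence(fit: HazardFit, group: Group) -> CumulativeIncidenceCurve:
    """Accumulate hazards into a cumulative-incidence band for one group.

    Per posterior draw d and interval k,
    ``CI_d(k) = 1 - prod_{i<=k} (1 - h_id)``; centiles are taken over draws at
    each interval end, so all three reported curves are non-decreasing.  Only
    the finite intervals (up to the horizon) enter the curve; a flagged
    overflow interval is excluded because it has no finite end time.
    """
    per_interval = fit.draws[group]
    n_finite = len(fit.table.edges) - 1
    if len(per_interval) < n_finite:
        raise ValueError("missing interval draws")
    pooled = [d.pooled() for d in per_interval[:n_finite]]
    sizes = {p.size for p in pooled}
    if len(sizes) != 1:
        raise ValueError("interval draw counts differ; cannot pair draws")
    hazards = inv_logit(np.vstack(pooled))  # (intervals, draws)
    ci = 1.0 - np.cumprod(1.0 - hazards, axis=0)
    q = np.percentile(ci, (2.5, 50.0, 97.5), axis=1)
    return CumulativeIncidenceCurve(
        group=group,
        t_end_months=fit.table.edges[1:].copy(),
        q2_5=q[0],
        median=q[1],
        q97_5=q[2],
    )


@dataclass(frozen=True)
class RiskAtTime:
    """Cumulative risk at a requested time, with the '1 in N' counselling form."""

    months: float
    summary: PosteriorSummary
    one_in_n: Optional[int]
    phrase: str


def risk_at_time(curve: CumulativeIncidenceCurve, months: float) -> RiskAtTime:
    """Read the curve at the last interval end at or before ``months``.

    The median risk is also expressed as "X%, about 1 in N" with
    N = round(1 / median), the form used when counselling patients.
    """
    ends = curve.t_end_months
    if months < ends[0]:
        raise ValueError(f"{months} months precedes the first interval end {ends[0]}")
    if months > ends[-1]:
        raise ValueError(f"{months} months exceeds the horizon {ends[-1]}")
    k = int(np.searchsorted(ends, months, side="right") - 1)
    summary = PosteriorSummary(
        float(curve.q2_5[k]), float(curve.median[k]), float(curve.q97_5[k])
    )
    if summary.median > 0:
        n = round(1.0 / summary.median)
        phrase = f"{100 * summary.median:.2f}%, about 1 in {n}"
    else:
        n = None
        phrase = "0.00%, no risk accumulated"
    return RiskAtTime(months=float(ends[k]), summary=summary, one_in_n=n, phrase=phrase)
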