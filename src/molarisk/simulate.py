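"""Seeded synthetic cohorts with the statistical structure the models assume.

The national registry data behind the published analysis are not deposited, so
this module generates cohorts with the same shape: two normalisation-speed
groups whose sizes sum to ~17 424, rare GTN events (about 6 per 10 000 in the
EARLY group and 22 per 10 000 in the LATE group), event times from
normalisation spanning roughly 0.1-90 months, and administrative censoring.

Censoring follows the registry's ascertainment process, not the hCG monitoring
schedule: because any later presentation is re-referred to centralised care,
events remain observable until the database lock, so non-events are censored
at an administrative follow-up time drawn uniformly between the guaranteed
two-year minimum and the four-decade registry span (``followup_model =
"registry"``, the default).  Setting ``followup_model = "protocol"`` instead
censors non-events when scheduled monitoring ends (six months for most
patients, two years under the older pre-2000 protocols) — a stress-test mode
in which late risk sets consist almost entirely of future cases.  Events are
never censored by default; ``censor_events=True`` subjects them to the same
follow-up limit for stress tests.

Every draw is reproducible under a fixed seed, and the generator returns a
bookkeeping object recording exactly what was planted so pipeline tallies can
be cross-checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .cohort import EXCLUSION_FLAGS, Genetics, Group, Outcome, PatientRecord

__all__ = ["SimulationParams", "SimulationTruth", "simulate_cohort", "simulate_replicates"]


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate the published study conditions.

    Group sizes default to 5 000 / 12 424 (summing to the published 17 424;
    the true split is unpublished) so that the expected event counts are about
    3 and 27, echoing the published 3 / 28 case split.  Event times from
    normalisation are log-normal in months, centred on one year with a wide
    spread, truncated to [0.1, 90] months to match the observed range.  Days
    to normalisation are uniform over [14, 55] (EARLY) and [56, 306] (LATE),
    the published fixture's span.  Under the default ``"registry"`` follow-up
    model, non-events are censored at Uniform(24, 480) months; under
    ``"protocol"``, at 6 months for a default 80% of patients (current
    protocol era) and 24 months for the rest (pre-2000 protocols).
    """

    n_early: int = 5_000
    n_late: int = 12_424
    p_early: float = 0.0006
    p_late: float = 0.0022
    event_time_log_mean: float = math.log(12.0)  # months
    event_time_log_sd: float = 1.0
    event_time_bounds: Tuple[float, float] = (0.1, 90.0)
    normal_days_early: Tuple[int, int] = (14, 55)
    normal_days_late: Tuple[int, int] = (56, 306)
    followup_model: str = "registry"  # "registry" or "protocol"
    registry_followup_months: Tuple[float, float] = (24.0, 480.0)
    followup_months_short: float = 6.0
    followup_months_long: float = 24.0
    frac_short_followup: float = 0.8
    censor_events: bool = False  # stress-test flag; the registry observes all events
    n_flagged_extra: int = 0  # additional records planted with exclusion flags
    seed: int = 0

    def __post_init__(self):
        # tolerate list-valued pairs (e.g. read back from YAML)
        for name in ("event_time_bounds", "normal_days_early", "normal_days_late",
                     "registry_followup_months"):
            value = getattr(self, name)
            if not isinstance(value, tuple):
                object.__setattr__(self, name, tuple(value))
        for p in (self.p_early, self.p_late):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"event probability must be in [0, 1), got {p}")
        if min(self.n_early, self.n_late) <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.frac_short_followup <= 1.0:
            raise ValueError("frac_short_followup must be in [0, 1]")
        if self.followup_model not in ("registry", "protocol"):
            raise ValueError(f"unknown followup_model {self.followup_model!r}")


@dataclass
class SimulationTruth:
    """Exactly what the generator planted, for bookkeeping cross-checks."""

    params: SimulationParams
    n: Dict[Group, int]
    events: Dict[Group, int]
    event_months: Dict[Group, np.ndarray]  # observed event times (months)
    n_censored_events: Dict[Group, int]  # events lost when censor_events=True
    n_flagged: int

    def interval_event_counts(
        self, interval_months: float = 3.0, horizon_months: float = 90.0
    ) -> Dict[Group, np.ndarray]:
        """Planted events per half-open interval [k*w, (k+1)*w), plus overflow."""
        n_finite = int(np.ceil(horizon_months / interval_months))
        edges = np.arange(n_finite + 1) * interval_months
        out = {}
        for g, times in self.event_months.items():
            counts = np.zeros(n_finite + 1, dtype=int)
            if times.size:
                idx = np.searchsorted(edges[1:], times, side="right")
                np.add.at(counts, idx, 1)
            out[g] = counts
        return out


def _simulate_group(
    rng: np.random.Generator,
    group: Group,
    n: int,
    p: float,
    params: SimulationParams,
    id_prefix: str,
) -> Tuple[List[PatientRecord], np.ndarray, int]:
    lo_d, hi_d = (
        params.normal_days_early if group is Group.EARLY else params.normal_days_late
    )
    normal_days = rng.integers(lo_d, hi_d + 1, size=n)
    is_event = rng.random(n) < p

    if params.followup_model == "registry":
        lo_f, hi_f = params.registry_followup_months
        followup_months = rng.uniform(lo_f, hi_f, size=n)
    else:
        # protocol-era mix: follow-up ends with scheduled monitoring
        short = rng.random(n) < params.frac_short_followup
        followup_months = np.where(
            short, params.followup_months_short, params.followup_months_long
        )

    # truncated log-normal event times, resampled until inside the bounds
    n_events = int(is_event.sum())
    lo_t, hi_t = params.event_time_bounds
    times = np.empty(n_events)
    remaining = np.arange(n_events)
    while remaining.size:
        draw = rng.lognormal(params.event_time_log_mean, params.event_time_log_sd, remaining.size)
        ok = (draw >= lo_t) & (draw <= hi_t)
        times[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]

    records: List[PatientRecord] = []
    event_months: List[float] = []
    n_censored_events = 0
    ev_idx = 0
    for i in range(n):
        if is_event[i]:
            t = times[ev_idx]
            ev_idx += 1
            if params.censor_events and t > followup_months[i]:
                n_censored_events += 1
                outcome, days_end = Outcome.CENSORED, int(round(followup_months[i] * 30))
            else:
                outcome, days_end = Outcome.GTN, max(1, int(round(t * 30)))
                event_months.append(days_end / 30.0)
        else:
            outcome, days_end = Outcome.CENSORED, int(round(followup_months[i] * 30))
        records.append(
            PatientRecord(
                patient_id=f"{id_prefix}{i:05d}",
                days_evac_to_normal=int(normal_days[i]),
                outcome=outcome,
                days_normal_to_end=days_end,
                presentation_tags=frozenset({"raised_hcg"}) if outcome is Outcome.GTN else frozenset(),
                treatment_text="MTX" if outcome is Outcome.GTN else "",
                n_interval_pregnancies=0,
                genetics=Genetics.UNKNOWN,
            )
        )
    return records, np.asarray(event_months), n_censored_events


def simulate_cohort(params: SimulationParams = SimulationParams()):
    """Generate one cohort; returns ``(records, truth)``.

    Each patient is an independent Bernoulli(p_group) event indicator; event
    times come from the truncated log-normal model and are stored as whole
    days (months * 30, rounded), so the bookkeeping truth records the
    *observed* day-resolution event times that the pipeline will tabulate.
    Optionally appends ``n_flagged_extra`` records carrying exclusion flags to
    exercise the exclusion filter.
    """
    rng = np.random.default_rng(params.seed)
    early, em_early, ce_early = _simulate_group(
        rng, Group.EARLY, params.n_early, params.p_early, params, "E"
    )
    late, em_late, ce_late = _simulate_group(
        rng, Group.LATE, params.n_late, params.p_late, params, "L"
    )
    records = early + late

    flags = sorted(EXCLUSION_FLAGS)
    for j in range(params.n_flagged_extra):
        records.append(
            PatientRecord(
                patient_id=f"X{j:05d}",
                days_evac_to_normal=int(rng.integers(14, 307)),
                outcome=Outcome.CENSORED,
                days_normal_to_end=int(rng.integers(0, 731)),
                exclusion_flags=frozenset({flags[int(rng.integers(len(flags)))]}),
            )
        )

    truth = SimulationTruth(
        params=params,
        n={Group.EARLY: params.n_early, Group.LATE: params.n_late},
        events={Group.EARLY: em_early.size, Group.LATE: em_late.size},
        event_months={Group.EARLY: em_early, Group.LATE: em_late},
        n_censored_events={Group.EARLY: ce_early, Group.LATE: ce_late},
        n_flagged=params.n_flagged_extra,
    )
    return records, truth


def simulate_replicates(
    params: SimulationParams, n_replicates: int, base_seed: int
) -> Iterator[tuple]:
    """Yield ``(records, truth)`` for replicate seeds ``base_seed + r``.

    Cohorts are materialised one at a time so recovery studies over many
    replicates stay memory-bounded.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    from dataclasses import replace

    for r in range(n_replicates):
        yield simulate_cohort(replace(params, seed=base_seed + r))
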