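# Methods

## Problem and data model

After uterine evacuation of a complete hydatidiform mole, serum hCG is
monitored until it returns to the reference range; gestational trophoblastic
neoplasia (GTN) occasionally develops *after* that first normal value. Each
patient record carries two whole-day offsets: evacuation → first normal hCG
(`days_evac_to_normal`) and first normal hCG → GTN treatment start or end of
follow-up (`days_normal_to_end`), plus descriptive fields for the case series
(presentation tags, treatment text, intervening pregnancies, tumour
genetics). Patients are stratified by normalisation speed at a 56-day cutoff:
strictly fewer than 56 days is EARLY, 56 or more is LATE (the boundary is
deliberately inclusive on the LATE side). Records flagged for any exclusion
reason (treated before normalisation, twin pregnancy with a healthy co-twin,
recurrent mole, incomplete follow-up) never enter an analysis cohort.

Day counts are converted to 30-day months. This is the only convention that
reproduces both published presentation endpoints (4 days → 0.13 months and
2697 days → 89.9 months); display values are rounded half-up to two decimals
below one month and one decimal at or above, while all interval arithmetic
uses the exact quotient.

The 31 published GTN cases are encoded once, as data, in
`molarisk.table1`. Presentation free text was tokenised once into a
controlled vocabulary so descriptive counts are deterministic; "Unknown"
cells become explicit unknown values, which descriptive output reports as
their own category over the fixed denominator of 31.

## Bayesian machinery

Both models are saturated binomial-logit models: every group (incidence) or
interval×group cell (time-to-event) has its own coefficient α with

    y ~ Binomial(n, expit(α)),   α ~ Normal(m, s²).

The log posterior is written as `y·α − n·log(1 + e^α)` plus the Normal log
prior, which is exact at the boundary counts y = 0 and y = n and finite for
all finite α. Because each posterior is one-dimensional and independent, two
engines cover all inference:

* **Random-walk Metropolis** (production engine). Chains are vectorised and
  advance in lockstep. The proposal scale starts at 2.4 × a Laplace
  approximation of the posterior SD (precision = prior precision +
  n·p̂·(1−p̂) with p̂ = (y+½)/(n+1)) and is adapted per chain in batches of 50
  during warmup toward the 1-D-optimal acceptance rate ≈ 0.44, then frozen.
  Chains initialise overdispersed (SD 1 on the logit scale) around the
  approximate posterior centre so split-chain R̂ is an honest diagnostic.
  Defaults: 4 chains × 2000 post-warmup draws after 1000 warmup iterations;
  R̂ above 1.01 is a warning, not a failure. All randomness flows through a
  single seeded `numpy` Generator, so draws are bit-for-bit reproducible.
* **Trapezoid quadrature** (deterministic oracle). The unnormalised posterior
  is evaluated on a fixed grid of 4001 nodes over α ∈ [−30, 10], normalised
  by the trapezoid rule, and centiles are read off the CDF by linear
  interpolation. Because expit is strictly increasing, probability-scale
  centiles are the transformed α-centiles (exact, no re-gridding). The grid
  bounds comfortably contain every posterior that arises here (risks between
  ~10⁻¹³ and ~1); the node spacing of 0.01 logits limits median error to
  well under 0.1% for the rare-event posteriors this package targets.

Posteriors are summarised as 2.5th/50th/97.5th centiles. Split R̂ uses the
half-chain Gelman–Rubin form with a zero-variance guard (identical constant
chains → 1.0 by convention); it is cross-checked against arviz in the test
suite, as is the sampler against the quadrature engine over a grid of
(y, n) pairs with tolerances calibrated by the Monte-Carlo standard error of
the relevant quantile.

## Incidence model and relative risk

Priors default to Normal(−8, 3): centred on expit(−8) ≈ 3.4 per 10 000 —
"relatively informative" in location, reflecting prior evidence that
post-normalisation GTN is rare — but wide enough (SD 3 logits) for the data
to dominate. The posterior relative risk EARLY/LATE is computed draw-by-draw
on pooled chains (equal pooled counts enforced), matching the direction in
which the published estimate is below 1. The prior-sensitivity table runs the
quadrature engine over means {−12, −10, −8, −6, −4} × SDs {1, 3, 10} (plus
the default), and shows posterior medians moving far less than prior medians.

The published per-group posterior medians (0.06% vs 0.22%) and relative risk
0.25 (0.06–0.72) depend on per-group denominators that were never printed;
the package therefore treats them as a scenario requiring user-supplied group
sizes, and validates the machinery by parameter recovery on synthetic cohorts
at plausible denominators instead.

## Discrete-time time-to-event model

Follow-up from the first normal hCG value is divided into half-open
intervals [start, end) of 3 months (configurable) up to a 90-month horizon —
the published risks are quoted at 39 months (a multiple of 3) and the
observed event times extend to 89.9 months. Conventions, chosen once:

* event times use the exact days/30 quotient; a boundary event (exactly at an
  interval start) falls in the *later* interval and its patient counts as at
  risk there;
* a censored patient is at risk in interval k iff their censoring time is
  strictly greater than the interval's start, so censoring exactly at an
  interval start removes them from that interval;
* censored patients are book-kept in the last interval in which they were at
  risk, giving the life-table conservation identity
  `n_at_risk[k+1] = n_at_risk[k] − events[k] − censored[k]`;
* events at or beyond the horizon go to a flagged open-ended final interval,
  which is excluded from cumulative-incidence curves (it has no finite end).

Cell priors default to Normal(−12, 3) — deliberately lower than the overall
risk prior since one window carries only a fraction of total risk. Cells with
nobody at risk return the prior pushforward (median hazard ≈ 6 per million)
and are flagged, which keeps credible bands pinned near zero where no data
exist. Cumulative incidence is accumulated per posterior draw as
1 − Π(1 − h); with near-flat priors (SD 100) and large cells the median curve
reproduces the classical product-limit estimate on the same table within 2%,
which the test suite checks against an independently coded Kaplan–Meier
product. `risk_at_time` reads the curve at the last interval end at or before
the requested month and renders the counselling form "X%, about 1 in N" with
N = round(1/median).

## Surveillance protocol and case-series descriptives

Monitoring under the current UK schedule ends six months after evacuation for
EARLY patients and six months after the first normal value for LATE patients.
Six months is encoded as 183 days (365.25/2, rounded); measured from
normalisation the window is max(0, 183 − days_evac_to_normal) for EARLY and
183 for LATE. The classification of the 31 published cases is identical under
the 180-day convention (the nearest case values are 161 and 207 days), which
the tests assert. The older pre-2000 two-year schedule is deliberately not
used by the classifier: the published "diagnosed after protocol" figure
refers to the current schedule.

Chemotherapy regimens are classified from free text by whole-token,
case-insensitive matching against a frozen lexicon: methotrexate/dactinomycin
tokens are monotherapies; combination tokens (EMACO, EMAEP, EP, HuMMP,
CHAMOCA, VAC, IVA, TETP, pembrolizumab) force MULTI_AGENT; text with no
chemotherapy token is SURGERY_ONLY; an unrecognised chemotherapy mention
(not explicitly declined/withheld) warns and is conservatively classed
MULTI_AGENT. FIGO prognostic scores are stored but never computed — the
scoring rules are out of scope.

## Synthetic cohorts

The registry data are not publicly deposited, so the generator emulates their
structure with seeded draws: group sizes 5 000/12 424 (summing to the
published 17 424; the true split is unpublished, and these sizes make the
expected event counts ≈3 and ≈27, echoing the observed 3/28 case split); true
risks 6 and 22 per 10 000; normalisation days uniform on [14, 55] (EARLY) and
[56, 306] (LATE); event times from normalisation log-normal in months
(log-mean ln 12, log-SD 1) truncated to [0.1, 90] by resampling, stored as
whole days.

Censoring follows the registry's *ascertainment* process rather than the hCG
monitoring schedule. Because any later presentation is re-referred to
centralised care, events remain observable until the database lock; the
default (`followup_model="registry"`) therefore censors non-events at an
administrative follow-up drawn uniformly between the guaranteed two-year
minimum and the four-decade registry span (24–480 months). The alternative
`"protocol"` mode censors non-events when scheduled monitoring ends (6 months
for 80% of patients, 24 for the rest) — useful as a stress test, but note
that its late risk sets consist almost entirely of future cases, so interval
hazards are grossly inflated; it does not represent the registry. Events are
never censored by default; `censor_events=True` subjects them to the same
follow-up limit.

What the generator does *not* emulate: hCG trajectories and assay values,
secular trends in incidence or management, inter-centre differences,
competing risks from intervening pregnancies, and any dependence of event
risk on the exact normalisation day beyond the two-group split. Passing
recovery tests therefore demonstrates that the estimators are consistent and
the credible intervals calibrated *under the assumed sampling model*, not
that the model is correct for real registry data.

## Test strategy and problem sizes

Deterministic facts (fixture aggregates, protocol classification, life-table
examples) are asserted exactly. Stochastic checks are seeded and sized to
keep the default suite fast: the oracle-equivalence grid uses 40
(y, n, prior) combinations at the default 8 000-draw budget with tolerances
of max(2% relative, 3 quantile-MCSEs); parameter recovery runs 100 replicate
cohorts of 17 424 patients (coverage threshold ≥90/100 for each group risk
and the relative risk); the Kaplan–Meier limit uses a 5 000-patient cohort
with ~30% event rates on 9-month intervals so every cell stays large.

## Known limitations

* Per-group denominators of the real cohort are unpublished, so the
  published per-group posteriors can be reproduced only as a user-supplied
  scenario, not asserted.
* The real interval scheme behind the published cumulative-incidence figures
  is unprinted; the 3-month default is a package choice.
* The era mix of follow-up durations is a placeholder; the real distribution
  of administrative censoring times is unknown.
* The sampler is 1-D by design and does not generalise to models with shared
  coefficients (e.g. covariate-adjusted hazards), which are out of scope.
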