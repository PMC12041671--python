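# molarisk

Bayesian risk analysis of gestational trophoblastic neoplasia (GTN) arising
*after* serum hCG has returned to normal following uterine evacuation of a
complete hydatidiform mole.

After evacuation of a complete mole, patients undergo serial hCG monitoring
because residual trophoblastic tissue becomes malignant in a minority of
cases. Almost all malignancies declare themselves before hCG normalises; the
question this package addresses is the small residual risk *after* the first
normal value, and how it differs between patients whose hCG normalised
quickly (<56 days from evacuation, "EARLY") and slowly (≥56 days, "LATE") —
the evidence base for shortening post-normalisation surveillance. It is aimed
at biostatisticians and clinical epidemiologists working with
trophoblastic-disease registry data.

## Models

**Incidence model.** Per group $g$, with $y_g$ GTN cases among $n_g$ patients,

$$y_g \sim \mathrm{Binomial}(n_g, p_g), \qquad
  \operatorname{logit}(p_g) = \alpha_g, \qquad
  \alpha_g \sim \mathcal N(-8,\, 3^2),$$

a saturated parameterisation (one free coefficient per group, no reference
level), so the posteriors factorise. The posterior relative risk is formed
draw-by-draw as $p_{\text{EARLY}}/p_{\text{LATE}}$.

**Discrete-time time-to-event model.** Follow-up from the first normal hCG
value is split into 3-month intervals up to 90 months. With $d_{kg}$ events
among $n_{kg}$ patients at risk in interval $k$,

$$d_{kg} \sim \mathrm{Binomial}(n_{kg}, h_{kg}), \qquad
  \operatorname{logit}(h_{kg}) = \alpha_{kg}, \qquad
  \alpha_{kg} \sim \mathcal N(-12,\, 3^2),$$

and cumulative incidence per posterior draw is
$1 - \prod_{i \le k} (1 - h_{ig})$ — a Bayesian life table with credible
bands.

Both models are fit with a seeded, adaptively tuned 1-D random-walk
Metropolis sampler, cross-validated against a deterministic trapezoid
quadrature engine; convergence is monitored with split-chain
$\widehat R$. A prior-sensitivity grid and a surveillance-protocol classifier
(monitoring ends 183 days after evacuation for EARLY patients, 183 days after
normalisation for LATE) round out the analysis, and a seeded synthetic-cohort
generator reproduces the registry's statistical structure for end-to-end
recovery studies. The 31 published GTN cases ship as a built-in fixture
(`load_table1_fixture()`).

## Worked example

```python
from molarisk import *
from molarisk.cohort import Group

records, truth = simulate_cohort(SimulationParams(seed=1))   # 17 424 patients
counts = build_incidence_counts(records)
fit = fit_incidence(counts, config=McmcConfig(seed=1))
for g in (Group.EARLY, Group.LATE):
    c, s = counts[g], fit.summaries[g]
    print(f"{g.value}: y={c.y}, n={c.n}, risk median {100*s.median:.3f}% "
          f"(95% CrI {100*s.q2_5:.3f}% to {100*s.q97_5:.3f}%)")
s = relative_risk(fit.draws[Group.EARLY], fit.draws[Group.LATE]).summary
print(f"relative risk EARLY/LATE: {s.median:.2f} ({s.q2_5:.2f} to {s.q97_5:.2f})")

table = build_risk_table(records)
hazards = fit_interval_hazards(table, config=McmcConfig(seed=2))
for g in (Group.EARLY, Group.LATE):
    r = risk_at_time(cumulative_incidence(hazards, g), 39)
    print(f"{g.value} cumulative risk at 39 months: {r.phrase}")
```

prints

```
EARLY: y=4, n=5000, risk median 0.072% (95% CrI 0.022% to 0.172%)
LATE: y=29, n=12424, risk median 0.231% (95% CrI 0.155% to 0.325%)
relative risk EARLY/LATE: 0.31 (0.09 to 0.79)
EARLY cumulative risk at 39 months: 0.06%, about 1 in 1708
LATE cumulative risk at 39 months: 0.20%, about 1 in 500
```

The EARLY group's posterior risk of post-normalisation GTN is about 7 per
10 000 in this simulated registry, roughly a third of the LATE group's, and
the cumulative risk accrued by 39 months after normalisation is below 0.1%
for EARLY patients — the kind of number used when counselling patients on
stopping surveillance early.

A command-line interface mirrors the library:

```bash
molarisk simulate --seed 1 --out cohort.csv --truth truth.json
molarisk fit-incidence --cohort cohort.csv --seed 1
molarisk fit-tte --cohort cohort.csv --out curves.csv --seed 1
molarisk descriptives --cohort cohort.csv
molarisk run --config run.yaml          # full pipeline -> report bundle
```

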