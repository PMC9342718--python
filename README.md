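# livessaved

Deterministic lives-saved modelling of child-health intervention coverage
change, with missed-opportunity and universal scale-up scenario analyses.

## The problem

National programmes scale dozens of child-health interventions — vaccines,
malaria control, case management of neonatal sepsis, water and sanitation,
nutrition — at the same time. When under-five mortality falls (or fails to
fall), programme planners need to know *which* interventions contributed
how many of the deaths averted, and which would save the most additional
lives if their coverage were raised. This package answers those questions
with a deterministic, multi-cause population model of the kind used in
national programme evaluations, for analysts who have coverage survey
anchors, headline mortality rates, and a cause-of-death structure, but want
a transparent, testable, scriptable engine.

## The model

Expected baseline deaths in year *t* are split by age band and cause:

```
D0(a, k, t) = births(t) × rate(a)/1000 × codfrac(a, k)
```

with `rate(neonatal) = NMR₀` and `rate(1–59m) = U5MR₀ − NMR₀` (deaths per
1,000 live births). Each intervention *i* has an effectiveness *Eᵢ* and an
affected fraction *AFᵢₖ* — the share of cause *k*'s mortality amenable to
it. At coverage *cᵢ* (a proportion; linearly interpolated between percent
survey anchors) the intervention leaves the residual `1 − cᵢ·Eᵢ·AFᵢₖ` of
the cause's deaths in place; a portfolio combines multiplicatively:

```
D(a, k, t) = D0(a, k, t) × Π_i (1 − cᵢ(t)·Eᵢ·AFᵢₖ) / (1 − cᵢ(t0)·Eᵢ·AFᵢₖ)
```

Normalising by the baseline-year residual makes "no coverage change" give
exactly zero lives saved, a coverage rise give positive lives saved, and a
coverage fall give excess deaths (negative lives saved). The single-change
case reduces to the familiar impact formula *coverage change × effectiveness
× affected fraction* (divided by the baseline residual). Nutrition risk
factors (stunting, wasting) enter the same product as population mean
relative risks `ρ(P) = P·RR + (1−P)`, either driven directly by measured
prevalence anchors (*direct entry* mode) or moved by linked nutrition
interventions (*intervention-only* mode). Joint deaths averted are
attributed to individual channels by signed log-residual shares, which sum
exactly and give an unchanged channel exactly zero.

Three scenarios are built on the engine:

* **evaluate** — lives saved between a baseline and an endline year;
* **missed opportunity** — every intervention below a threshold (default
  90%) is individually stepped to the threshold one year after the base
  year and ranked by deaths averted over a five-year horizon;
* **universal scale-up** — every intervention is raised to a common target
  (default 100%), with counterfactual NMR/U5MR reported.

The published Ghana evaluation tables that motivated the package
(2008→2014 coverage anchors, lives saved by intervention, missed
opportunity ranking, 100% scale-up) ship as fixtures; their printed totals,
shares, and coverage arithmetic are reproduced exactly by the reporting
layer and serve as the regression surface.

## Worked example

```python
from livessaved import LivesSavedModel, ScenarioSpec

model = LivesSavedModel.from_synthetic(seed=0, n_interventions=6, n_causes=4)
print(model.fit().summary())
```

```
Lives-saved projection
======================================================
profile:      synthetic-0
scenario:     evaluate  span (2008, 2014]
mode:         direct_entry
grand total:  47,273 lives saved
rates 2014:   NMR 26.3, U5MR 59.0 per 1,000 live births
------------------------------------------------------
channel                        lives saved   share %
stunting                            15,253      32.3
iv04                                10,773      22.8
wasting                              8,441      17.9
iv00                                 7,061      14.9
iv03                                 2,729       5.8
iv02                                 2,559       5.4
iv05                                   290       0.6
iv01                                   167       0.4
Total                               47,273     100.0
```

The grand total is the sum over years 2009–2014 of deaths averted relative
to a counterfactual in which every coverage and prevalence is held at its
2008 value; the share column divides each channel's (unrounded) total by
the grand total. The endline rates are the mortality rates implied by the
scenario's projected deaths. Ranking future opportunities from the same
profile:

```python
mot = LivesSavedModel(model.profile,
                      ScenarioSpec(kind="missed_opportunity", t0=2014)).fit()
print(mot.summary())
```

```
Missed-opportunity ranking
==================================================================
profile:    synthetic-0
base year:  2014   threshold: 90%   horizon: 5 years
------------------------------------------------------------------
intervention            coverage %  neonatal     1-59m     total
iv03                          57.1         0    24,968    24,968
iv00                          58.4     4,024     4,605     8,629
iv02                          61.6       150     6,372     6,522
iv01                          61.8         0     2,925     2,925
iv05                          44.3         5     1,064     1,069
```

Each row answers: if only this intervention were stepped from its base-year
coverage to 90% next year, how many deaths would be averted over five
years, split by age band? Interventions already at or above 90% are
excluded.

The same analyses run from the shell on a profile directory of
tab-separated tables:

```
livessaved synth --seed 0 --out profile/
livessaved evaluate --profile profile/ --t0 2008 --t1 2014 --out run/
livessaved mot --profile profile/ --base-year 2014 --threshold 90
livessaved scaleup --profile profile/ --t0 2008 --t1 2014 --target 100
livessaved fixtures --check
```

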