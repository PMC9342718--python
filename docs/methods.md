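# Methods

## Model

The engine is a deterministic, multi-cause, two-age-band projection of
under-five deaths. For age band *a* ∈ {neonatal (0–1 month), 1–59 months}
and cause *k*, expected baseline deaths in year *t* are

    D0(a, k, t) = births(t) · rate(a)/1000 · codfrac(a, k),

with rate(neonatal) = NMR₀ and rate(1–59m) = U5MR₀ − NMR₀. This is a
simple cohort-synthetic conversion of the two headline rates; it is *not*
a life table. Full life-table or cohort-component machinery (demographic
projection, fertility/family-planning effects, HIV-specific dynamics) is
deliberately outside the model: births are an exogenous input series and
only the two baseline rates are used. Deaths are real-valued throughout;
rounding happens only at the reporting boundary.

Under a scenario, deaths scale multiplicatively:

    D(a, k, t) = D0(a, k, t) · Π_ch term_ch(t) / term_ch(t0),

where each *channel* contributes one term per (band, cause):

* intervention *i* with effectiveness Eᵢ ∈ [0,1] and affected fraction
  AFᵢₖ ∈ [0,1], active on band *a*: term = 1 − c_eff,ᵢ(t)·Eᵢ·AFᵢₖ (its
  residual — the share of the cause's deaths it does not avert);
* a risk factor (stunting or wasting) with relative risk RRₖ ≥ 1 and
  prevalence P(t): term = ρ(P(t)) = P·RRₖ + (1−P), the population mean
  relative risk.

Multiplicative combination within a cause is the standard joint-portfolio
convention: it bounds total aversion below 100% for any number of
interventions, and it makes each channel's contribution a well-defined
factor. Dividing by the baseline-year terms normalises the model so that
unchanged inputs reproduce baseline deaths exactly — "no change in
coverage saves zero lives" is an identity, not an approximation.

### Time stepping and the "previous lives saved" adjustment

The run proceeds in annual steps over (t0, t1]. Coverage is linearly
interpolated between percent anchors and clamped outside the anchored
span; a coverage value changed within a year acts for the whole year. Each
year's lives saved are computed against the counterfactual with *all*
inputs held at their t0 values, recomputed for that year's births. Because
the comparison is always scenario-vs-held-baseline within the same year,
children saved by a coverage delta in year *j* are not saved again in year
*j+1* by the same delta; only the year-*t* gap between the two residual
products counts. Multi-year cohort survival tracking (children saved in
one year remaining at risk in later years, cohorts born before the
baseline) is out of scope; totals are deaths averted among the analysis
span's annual birth cohorts.

### Attribution

Per (band, cause, year), the joint deaths averted D0 − D(t) are allocated
to channels with weights

    w_ch = ln term_ch(t0) − ln term_ch(t),

each channel receiving total · w_ch / Σw. Properties: order-independent
(no sequential-removal arbitrariness), exact-summing by construction, an
unchanged channel receives exactly zero, a channel whose coverage fell
receives a negative allocation, and with a single changed channel the
formula reduces to the closed form

    lives saved = D0 · (c1 − c0) · E · AF / (1 − c0·E·AF).

The log-weights cancel (Σw = 0) exactly when the residual products cancel,
in which case the total is zero and every allocation is zero; a guard
raises on the numerically impossible combination of zero net log-change
with a materially nonzero total. Published per-intervention lives-saved
tables from tools with unpublished internals need not match this
allocation rule channel-by-channel; the joint totals are the comparable
quantity.

### Risk-factor modes

The two analysis modes are mutually exclusive to prevent double counting
(the source tables mark the complementary channel NA, never zero):

* **direct_entry** — measured prevalence anchors drive one channel per
  risk factor (term ρ(P(t))/ρ(P(t0))); linked-intervention prevalence
  effects are disabled.
* **intervention_only** — prevalence anchors beyond the baseline are
  ignored; each linked intervention *j* (efficacy e_j) moves prevalence by
  its own factor P_j(t) = P0 · max(0, 1 − e_j·(c_j(t) − c_j(t0))), and the
  joint mortality effect is the *product* of per-channel ratios
  ρ(P_j(t))/ρ(P0). Defining the joint effect as a product of
  single-intervention effects (rather than ρ of a jointly shifted
  prevalence) keeps every channel a multiplicative term, so attribution
  stays exact; with one linked intervention the two definitions coincide.
  No functional form for how a nutrition intervention moves prevalence is
  standard; this one is linear in the coverage delta, saturates at zero
  prevalence, and is stated here so users can judge it.

Risk factors carry no age-band field; their reach is bounded by which
causes appear in each band's cause-of-death profile (infection causes
typically sit in the 1–59-month band).

### Herd effect

Off by default (identity) for every intervention. The opt-in form is a
piecewise-linear multiplicative boost above a threshold coverage h:

    c_eff = min(1, c · (1 + max_boost · max(0, c − h)/(1 − h))),

continuous, nondecreasing, zero boost at the threshold, capped at full
coverage. The boost shape is a package choice; no standard closed form
exists for the indirect protection of vaccines and bed nets at this level
of aggregation.

## Scenarios

* **evaluate(t0, t1)** — the engine run as described.
* **missed_opportunity(base_year, threshold=90, horizon=5)** — eligibility
  is strict (coverage < threshold; an intervention exactly at the
  threshold is excluded). Each eligible intervention is stepped to the
  threshold at base_year+1 with every other coverage and prevalence held
  flat at base-year values, and deaths averted accrue over `horizon` years
  (minimum five — shorter windows give unstable impact estimates in this
  class of model). Rows are sorted by total (both bands) descending, ties
  broken by intervention id: deterministic, where published rankings often
  state no rule. The threshold is exposed because observed rankings
  sometimes include rows at nominal coverage ≥ 90, presumably measured on
  a different coverage definition.
* **universal_scaleup(t0, t1, target=100)** — every endline anchor is
  replaced by the target (which must not sit below any baseline coverage),
  coverage interpolates from the t0 values, and the reported increase per
  intervention is target − c(t0) in percentage points. Counterfactual
  NMR/U5MR per year are the scenario's projected band deaths divided by
  births × 1000.

## Parameters and units

| parameter | units | default | notes |
|---|---|---|---|
| coverage anchors | percent [0,100] | — | stored as printed in survey tables; converted to proportions once at the engine boundary |
| effectiveness E | proportion [0,1] | — | per intervention |
| affected fraction AF | proportion [0,1] | — | per intervention × cause, sparse |
| NMR₀, U5MR₀ | deaths per 1,000 live births | 31.2 / 75.3 (synthetic) | baseline rates |
| relative risk RR | ≥ 1 | drawn in [1.5, 4] (synthetic) | per risk factor × cause |
| MOT threshold | percent | 90 | national target coverage convention |
| MOT horizon | years | 5 | minimum allowed |
| scale-up target | percent | 100 | |

## Synthetic data

The generator emulates the *structure* of a national intervention
database: ~20 interventions across six delivery periods
(pregnancy/childbirth/breastfeeding/preventive/vaccine/curative) with
period-specific plausible coverage ranges, sparse affected fractions (each
intervention touches 1–2 of 6 causes), Dirichlet cause-of-death fractions
per band, two coverage anchors per intervention mimicking a
baseline/endline survey pair (with a 20% chance a channel slips
backwards), and stunting/wasting risk factors with the observed 27.5→18.8
and 8.6→4.7 percent prevalence declines. Defaults: 800,000 annual live
births and baseline rates 31.2/75.3 per 1,000 — a high-burden West African
setting. A single `numpy` generator is seeded per call; no global state,
so fixtures are bitwise reproducible.

What the synthetic profiles do *not* emulate: empirically estimated
effectiveness and affected-fraction values (synthetic values are labelled
synthetic and drawn from ranges), correlated coverage trends across
interventions, measurement error in survey anchors, and secular trends in
the cause-of-death structure. Tests passing on synthetic profiles
demonstrate the engine's accounting (signs, conservation, closed forms,
oracle agreement) — not that any particular real-world attribution is
correct, which depends entirely on the input effectiveness database.

## Numerical choices

* Residual terms are floored at 1e-300 inside logarithms; a cause fully
  averted at baseline (residual 0 at t0) raises a degenerate-input error
  naming the cause rather than producing infinities.
* Attribution tolerances: allocations sum to the joint figure to 1e-9
  relative (tested); the zero-total/zero-weight branch returns exact
  zeros.
* Rounding for display: integers for lives saved, one decimal for shares
  and rates, ties away from zero (matches printed tables; Python's
  built-in banker's rounding does not). Shares are computed from unrounded
  values against the unrounded total, then rounded.
* Profile I/O writes floats with `%.17g` and reads with pandas
  `float_precision="round_trip"`, so write-then-load is exact field-for-
  field.
* Coverage queries outside the anchored span clamp to the nearest anchor;
  out-of-span birth years clamp to the nearest year.

## Packaged reference tables

Three published Ghana evaluation tables (2008→2014 coverage anchors and
lives saved per intervention under two modes; the 90% missed-opportunity
ranking; the 100% scale-up) ship as tab-separated fixtures. NA cells mark
channels disabled in a mode and are kept as explicit missing values, never
zero. The transcription keeps the printed "coverage change" column as
`change_printed` because a handful of its cells do not equal
endline − baseline arithmetic (e.g. a printed 10.8 where the anchors give
10.0); recomputed changes come from `coverage_change()`. The fixtures'
column totals (34,477; 48,084; 108,390) and every printed parenthetical
share are reproduced by `aggregate_fixture()` and `shares()` and are
asserted in the test suite. The per-intervention lives-saved magnitudes in
those tables depend on the source tool's unpublished effectiveness /
affected-fraction / cause-of-death database and are *not* reproduction
targets for the engine.

## Known limitations

* Two age bands only; no finer age structure, no cohort survival between
  years, no population projection feedback.
* Constant effectiveness over time and coverage (no quality or access
  gradients).
* The intervention-mode prevalence-response form is a stated convention,
  not an estimate.
* No uncertainty intervals: the model is deterministic and the inputs
  carry no sampling variances here.
* Baseline NMR must be strictly below U5MR; degenerate full-aversion
  baselines are rejected rather than approximated.
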