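"""The deterministic impact engine.

Projected deaths for cause k in age band a at year t are

    D(a, k, t) = D0(a, k, t) * prod_ch [ term_ch(t) / term_ch(t0) ]

where D0 is the baseline expectation (births x baseline rate x cause
fraction) and each *channel* ch contributes a multiplicative term:

* an intervention i active on (a, k) contributes the residual
  ``1 - c_eff_i(t) * E_i * AF_ik`` — the fraction of the cause's deaths it
  does NOT avert at effective coverage ``c_eff``;
* a risk-factor channel contributes the population mean relative risk
  ``rho(P, RR) = P*RR + (1 - P)`` at the prevalence the channel implies.

Combining interventions multiplicatively within a cause is the standard
convention for joint portfolios: it keeps total aversion below 100% however
many interventions act on the cause. Normalising by the year-t0 terms makes
"no change in coverage" produce exactly zero lives saved, and recomputing
the held-at-baseline counterfactual every year prevents the same coverage
delta from re-saving the same children in later years.

Lives saved in year t are ``D0 - D(t)`` summed over causes, attributed to
channels by signed log-residual shares: channel ch receives weight
``ln term_ch(t0) - ln term_ch(t)``. The weights are order-independent, give
an unchanged channel exactly zero, go negative when coverage falls, and
sum-normalise so per-cause allocations add up to the joint figure exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .demography import baseline_cause_deaths
from .errors import ConsistencyError, DegenerateInputError
from .profile import CountryProfile, CoverageSeries, HerdSpec, InterventionSpec

_LOG_FLOOR = 1e-300


def interpolate_coverage(series: CoverageSeries, year: float) -> float:
    """Coverage as a PROPORTION at ``year``: linear between percent anchors,
    clamped outside the anchored span."""
    return series.value_at(year) / 100.0


def effective_coverage(c: float, herd: Optional[HerdSpec] = None) -> float:
    """Coverage after the optional herd-effect boost.

    With no herd spec this is the identity. With one, coverage above the
    threshold earns a piecewise-linear multiplicative boost reaching
    ``1 + max_boost`` at 100% coverage, capped at 1. Continuous and
    nondecreasing in ``c``; the boost is exactly zero at the threshold.
    """
    if herd is None or herd.threshold >= 1.0:
        return c
    boost = herd.max_boost * max(0.0, c - herd.threshold) / (1.0 - herd.threshold)
    return min(1.0, c * (1.0 + boost))


def residual_factor(
    interventions: Iterable[InterventionSpec],
    coverages: Mapping[str, float],
    cause: str,
    age_band: str,
) -> float:
    """Fraction of the cause's deaths NOT averted by the portfolio.

    Product over interventions active on (cause, band) of
    ``1 - c_eff * E * AF``; the empty product is 1.
    """
    value = 1.0
    for iv in interventions:
        af = iv.affected_fractions.get(cause, 0.0)
        if af > 0.0 and age_band in iv.age_bands:
            c_eff = effective_coverage(coverages[iv.id], iv.herd)
            value *= 1.0 - c_eff * iv.effectiveness * af
    return value


def risk_scaler(P: float, RR: float) -> float:
    """Population mean relative risk at prevalence ``P`` (proportion):
    ``P*RR + (1-P)``. Equals 1 at zero prevalence; increasing in both
    arguments."""
    return P * RR + (1.0 - P)


# ---------------------------------------------------------------------------
# Channel terms
# ---------------------------------------------------------------------------

def _channel_terms(
    profile: CountryProfile,
    cov: Mapping[str, float],
    prev: Mapping[str, float],
    base_cov: Mapping[str, float],
    base_prev: Mapping[str, float],
    band: str,
    cause: str,
) -> dict[str, float]:
    """Multiplicative term per channel for one (band, cause) cell.

    Intervention channels are keyed by intervention id. Risk channels are
    keyed by the risk-factor name in direct-entry mode, and by
    ``"<intervention_id>:<risk>"`` in intervention-only mode, where each
    linked intervention moves prevalence by its own factor
    ``max(0, 1 - efficacy * (c - c0))``.
    """
    terms: dict[str, float] = {}
    for iv in profile.interventions:
        af = iv.affected_fractions.get(cause, 0.0)
        if af > 0.0 and band in iv.age_bands:
            c_eff = effective_coverage(cov[iv.id], iv.herd)
            terms[iv.id] = 1.0 - c_eff * iv.effectiveness * af
    for rf in profile.risk_factors:
        rr = rf.relative_risks.get(cause)
        if rr is None:
            continue
        if profile.mode == "direct_entry":
            terms[rf.name] = risk_scaler(prev[rf.name], rr)
        else:  # intervention_only: linked interventions drive prevalence
            p0 = base_prev[rf.name]
            for iid, eff in rf.linked_interventions:
                f = max(0.0, 1.0 - eff * (cov[iid] - base_cov[iid]))
                terms[f"{iid}:{rf.name}"] = risk_scaler(min(1.0, p0 * f), rr)
    return terms


def cause_deaths_under_scenario(
    profile: CountryProfile,
    coverages_at_t: Mapping[str, float],
    prevalences_at_t: Mapping[str, float],
    year: int,
    base_coverages: Optional[Mapping[str, float]] = None,
    base_prevalences: Optional[Mapping[str, float]] = None,
) -> dict[tuple[str, str], float]:
    """Projected deaths per (band, cause) at ``year`` under the given
    coverage/prevalence proportions, normalised so that year-t0 inputs
    reproduce the baseline deaths exactly."""
    t0 = profile.demography.years[0]
    if base_coverages is None:
        base_coverages = {cs.intervention_id: interpolate_coverage(cs, t0) for cs in profile.coverages}
    if base_prevalences is None:
        base_prevalences = {rf.name: rf.prevalence_at(t0) / 100.0 for rf in profile.risk_factors}

    d0 = baseline_cause_deaths(profile, year)
    out: dict[tuple[str, str], float] = {}
    for (band, cause), deaths0 in d0.deaths.items():
        terms0 = _channel_terms(profile, base_coverages, base_prevalences, base_coverages, base_prevalences, band, cause)
        terms1 = _channel_terms(profile, coverages_at_t, prevalences_at_t, base_coverages, base_prevalences, band, cause)
        ratio = 1.0
        for ch, f0 in terms0.items():
            if f0 <= 0.0:
                raise DegenerateInputError(
                    f"cause {cause!r} ({band}) is fully averted at baseline; counterfactual ratio undefined"
                )
            ratio *= terms1[ch] / f0
        out[(band, cause)] = deaths0 * ratio
    return out


def attribute_lives_saved(
    baseline_deaths: float,
    factors_t0: Mapping[str, float],
    factors_t1: Mapping[str, float],
) -> dict[str, float]:
    """Allocate the joint deaths-averted figure across channels.

    Total averted is ``D0 * (1 - prod f1/f0)``. Channel ch receives the
    share ``w_ch / sum w`` with ``w_ch = ln f0 - ln f1``: exactly zero for
    unchanged channels, negative where coverage fell, and exact-summing to
    the total. With a single changed channel this reduces to the closed
    form (the channel takes 100%).
    """
    ratio = 1.0
    weights: dict[str, float] = {}
    for ch, f0 in factors_t0.items():
        f1 = factors_t1[ch]
        ratio *= f1 / max(f0, _LOG_FLOOR)
        if f1 == f0:
            weights[ch] = 0.0
        else:
            weights[ch] = math.log(max(f0, _LOG_FLOOR)) - math.log(max(f1, _LOG_FLOOR))
    total = baseline_deaths * (1.0 - ratio)
    sw = sum(weights.values())
    if sw == 0.0:
        if abs(total) <= 1e-9 * max(1.0, abs(baseline_deaths)):
            return {ch: 0.0 for ch in factors_t0}
        raise ConsistencyError("zero net log-change with nonzero deaths averted")
    return {ch: total * (w / sw) for ch, w in weights.items()}


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class LivesSavedResult:
    """Per-channel, per-year, per-band deaths-averted ledger.

    ``ledger`` maps (channel, year, band) to real-valued deaths averted
    (negative where coverage fell). ``deaths_by_band_year`` carries the
    scenario's projected deaths, from which counterfactual mortality rates
    are derived.
    """

    mode: str
    span: tuple[int, int]
    ledger: dict[tuple[str, int, str], float]
    deaths_by_band_year: dict[tuple[int, str], float]
    baseline_by_band_year: dict[tuple[int, str], float]

    @property
    def totals(self) -> dict[str, float]:
        """Deaths averted per channel, summed over years and bands."""
        out: dict[str, float] = {}
        for (ch, _, _), v in self.ledger.items():
            out[ch] = out.get(ch, 0.0) + v
        return out

    @property
    def grand_total(self) -> float:
        return sum(self.ledger.values())

    @property
    def shares(self) -> dict[str, float]:
        """Percent of the grand total per channel (unrounded)."""
        g = self.grand_total
        if g == 0.0:
            return {ch: 0.0 for ch in self.totals}
        return {ch: 100.0 * v / g for ch, v in self.totals.items()}

    def band_total(self, band: str) -> float:
        return sum(v for (_, _, b), v in self.ledger.items() if b == band)

    def to_frame(self) -> pd.DataFrame:
        """Ledger as a tidy DataFrame (channel, year, age_band, lives_saved),
        sorted for deterministic output."""
        rows = [
            {"channel": ch, "year": y, "age_band": b, "lives_saved": v}
            for (ch, y, b), v in self.ledger.items()
        ]
        df = pd.DataFrame(rows, columns=["channel", "year", "age_band", "lives_saved"])
        return df.sort_values(["channel", "year", "age_band"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# The main run
# ---------------------------------------------------------------------------

def lives_saved(profile: CountryProfile, t0: int, t1: int) -> LivesSavedResult:
    """Run the engine over (t0, t1].

    For each year the coverages (and, in direct-entry mode, prevalences)
    are linearly interpolated; deaths under the scenario and under
    everything-held-at-t0 are compared, and the difference attributed per
    channel. In intervention-only mode risk-factor prevalence paths are
    driven by linked interventions; in direct-entry mode prevalence anchors
    drive the risk channels and linked-intervention effects are disabled.
    """
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got {t0} >= {t1}")
    profile.validate()

    base_cov = {cs.intervention_id: interpolate_coverage(cs, t0) for cs in profile.coverages}
    base_prev = {rf.name: rf.prevalence_at(t0) / 100.0 for rf in profile.risk_factors}

    ledger: dict[tuple[str, int, str], float] = {}
    deaths_by_band_year: dict[tuple[int, str], float] = {}
    baseline_by_band_year: dict[tuple[int, str], float] = {}

    for t in range(t0 + 1, t1 + 1):
        cov_t = {cs.intervention_id: interpolate_coverage(cs, t) for cs in profile.coverages}
        if profile.mode == "direct_entry":
            prev_t = {rf.name: rf.prevalence_at(t) / 100.0 for rf in profile.risk_factors}
        else:
            prev_t = dict(base_prev)  # anchors beyond baseline ignored

        d0 = baseline_cause_deaths(profile, t)
        for (band, cause), deaths0 in d0.deaths.items():
            baseline_by_band_year[(t, band)] = baseline_by_band_year.get((t, band), 0.0) + deaths0
            terms0 = _channel_terms(profile, base_cov, base_prev, base_cov, base_prev, band, cause)
            if any(f <= 0.0 for f in terms0.values()):
                raise DegenerateInputError(
                    f"cause {cause!r} ({band}) is fully averted at baseline; counterfactual ratio undefined"
                )
            terms_t = _channel_terms(profile, cov_t, prev_t, base_cov, base_prev, band, cause)
            alloc = attribute_lives_saved(deaths0, terms0, terms_t)
            averted = sum(alloc.values())
            deaths_by_band_year[(t, band)] = deaths_by_band_year.get((t, band), 0.0) + (deaths0 - averted)
            for ch, v in alloc.items():
                key = (ch, t, band)
                ledger[key] = ledger.get(key, 0.0) + v

    return LivesSavedResult(
        mode=profile.mode,
        span=(t0, t1),
        ledger=ledger,
        deaths_by_band_year=deaths_by_band_year,
        baseline_by_band_year=baseline_by_band_year,
    )
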