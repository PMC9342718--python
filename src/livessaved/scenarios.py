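"""The three study scenarios, orchestrated over the impact engine.

* ``evaluate`` — lives saved between a baseline and endline year under
  linearly interpolated coverage change (the retrospective evaluation).
* ``missed_opportunity`` — each intervention below a coverage threshold is
  individually stepped up to the threshold one year after the base year and
  held; interventions at or above the threshold are excluded. Rows are
  ranked by total deaths averted over the horizon.
* ``universal_scaleup`` — every endline coverage anchor is replaced by a
  common target (default 100%), and counterfactual neonatal / under-five
  mortality rates are reported alongside the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .engine import LivesSavedResult, lives_saved
from .profile import NEONATAL, POSTNEONATAL, CountryProfile, CoverageSeries, RiskFactorSpec

SCENARIO_KINDS = ("evaluate", "missed_opportunity", "universal_scaleup")


@dataclass(frozen=True)
class ScenarioSpec:
    """Which analysis to run and its parameters.

    ``threshold`` (percent) is the missed-opportunity eligibility/step
    level; ``target`` (percent) the universal scale-up endpoint;
    ``horizon`` the number of years the missed-opportunity projection
    accrues impact (a minimum of five years is required to estimate
    impact).
    """

    kind: str
    t0: int
    t1: Optional[int] = None
    threshold: float = 90.0
    target: float = 100.0
    horizon: int = 5

    def validate(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind in ("evaluate", "universal_scaleup"):
            if self.t1 is None or not self.t0 < self.t1:
                raise ValueError(f"need t0 < t1, got {self.t0}, {self.t1}")
        if not 0.0 < self.threshold <= 100.0:
            raise ValueError(f"threshold must be in (0,100], got {self.threshold}")
        if not 0.0 < self.target <= 100.0:
            raise ValueError(f"target must be in (0,100], got {self.target}")
        if self.horizon < 5:
            raise ValueError(f"horizon must be >= 5 years, got {self.horizon}")


@dataclass(frozen=True)
class MissedOpportunityRow:
    """One ranked intervention from the missed-opportunity analysis."""

    intervention_id: str
    baseline_coverage: float  # percent at the base year
    deaths_averted_neonatal: float
    deaths_averted_1to59m: float

    @property
    def total(self) -> float:
        return self.deaths_averted_neonatal + self.deaths_averted_1to59m


def evaluate(profile: CountryProfile, t0: int, t1: int, mode: Optional[str] = None) -> LivesSavedResult:
    """Retrospective evaluation: lives saved over (t0, t1] under the
    profile's interpolated coverage (and, in direct-entry mode, prevalence)
    trajectories."""
    if mode is not None:
        profile = replace(profile, mode=mode)
    return lives_saved(profile, t0, t1)


def counterfactual_rates(
    profile: CountryProfile, deaths_by_band_year: dict[tuple[int, str], float]
) -> dict[int, tuple[float, float]]:
    """Mortality rates implied by a deaths ledger: per year,
    ``NMR = neonatal deaths / births x 1000`` and
    ``U5MR = (neonatal + 1-59m deaths) / births x 1000``."""
    years = sorted({y for (y, _) in deaths_by_band_year})
    out: dict[int, tuple[float, float]] = {}
    for y in years:
        births = profile.demography.births(y)
        neo = deaths_by_band_year.get((y, NEONATAL), 0.0)
        post = deaths_by_band_year.get((y, POSTNEONATAL), 0.0)
        out[y] = (1000.0 * neo / births, 1000.0 * (neo + post) / births)
    return out


def _flat_risk_factors(profile: CountryProfile, base_year: int) -> tuple[RiskFactorSpec, ...]:
    """Risk factors with prevalence held at base-year values."""
    return tuple(
        replace(rf, prevalence_anchors={base_year: rf.prevalence_at(base_year)})
        for rf in profile.risk_factors
    )


def missed_opportunity(
    profile: CountryProfile,
    base_year: int,
    threshold: float = 90.0,
    horizon: int = 5,
) -> list[MissedOpportunityRow]:
    """One-at-a-time scale-up to ``threshold`` percent, ranked by impact.

    Interventions with base-year coverage at or above the threshold are
    excluded (strict ``<`` eligibility). For each eligible intervention a
    scenario holds every other channel at its base-year value and steps the
    chosen coverage to the threshold at ``base_year + 1``, accruing deaths
    averted over ``horizon`` years. Output is sorted by total deaths
    averted descending, ties broken by intervention id.
    """
    ScenarioSpec(kind="missed_opportunity", t0=base_year, threshold=threshold, horizon=horizon).validate()
    frozen_rf = _flat_risk_factors(profile, base_year)
    rows: list[MissedOpportunityRow] = []
    for iv in profile.interventions:
        c_base = profile.coverage_series(iv.id).value_at(base_year)
        if c_base >= threshold:
            continue
        coverages = []
        for cs in profile.coverages:
            c0 = cs.value_at(base_year)
            if cs.intervention_id == iv.id:
                anchors = {base_year: c0, base_year + 1: threshold}
            else:
                anchors = {base_year: c0}
            coverages.append(CoverageSeries(cs.intervention_id, anchors))
        variant = replace(profile, coverages=tuple(coverages), risk_factors=frozen_rf)
        result = lives_saved(variant, base_year, base_year + horizon)
        rows.append(
            MissedOpportunityRow(
                intervention_id=iv.id,
                baseline_coverage=c_base,
                deaths_averted_neonatal=result.band_total(NEONATAL),
                deaths_averted_1to59m=result.band_total(POSTNEONATAL),
            )
        )
    rows.sort(key=lambda r: (-r.total, r.intervention_id))
    return rows


@dataclass(frozen=True)
class ScaleupResult:
    """Universal scale-up output: the lives-saved ledger, the percentage-
    point coverage increase per intervention (target minus baseline-year
    coverage), and counterfactual NMR/U5MR by year."""

    result: LivesSavedResult
    coverage_increase: dict[str, float]
    rates: dict[int, tuple[float, float]]


def universal_scaleup(
    profile: CountryProfile, t0: int, t1: int, target: float = 100.0
) -> ScaleupResult:
    """Scale every intervention to ``target`` percent coverage at ``t1``.

    Endline anchors are replaced by the target, coverage interpolates
    linearly from the t0 values, and counterfactual mortality rates are
    reported from the scenario's projected deaths.
    """
    ScenarioSpec(kind="universal_scaleup", t0=t0, t1=t1, target=target).validate()
    coverages = []
    increase: dict[str, float] = {}
    for cs in profile.coverages:
        c0 = cs.value_at(t0)
        if target < c0:
            raise ValueError(
                f"target {target} below baseline coverage {c0} for {cs.intervention_id!r}"
            )
        coverages.append(CoverageSeries(cs.intervention_id, {t0: c0, t1: target}))
        increase[cs.intervention_id] = target - c0
    variant = replace(profile, coverages=tuple(coverages))
    result = lives_saved(variant, t0, t1)
    rates = counterfactual_rates(profile, result.deaths_by_band_year)
    return ScaleupResult(result=result, coverage_increase=increase, rates=rates)
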