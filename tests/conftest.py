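"""Shared fixtures: small hand-built profiles and an independent oracle.

The oracle (`brute_force_averted`) re-derives joint deaths averted from the
raw profile tables with nothing but explicit loops and arithmetic — no
engine helpers — so engine results can be checked against an independent
path on small profiles.
"""

from __future__ import annotations

import pytest

from livessaved.profile import (
    AGE_BANDS,
    NEONATAL,
    POSTNEONATAL,
    CauseOfDeathProfile,
    CountryProfile,
    CoverageSeries,
    Demography,
    InterventionSpec,
)


def make_profile(
    interventions,
    coverages,
    *,
    causes=("cause_a",),
    cause_fractions=None,
    births=100_000.0,
    nmr0=20.0,
    u5mr0=40.0,
    years=(2008, 2014),
    risk_factors=(),
    mode="intervention_only",
    name="test",
) -> CountryProfile:
    """Small hand-specified profile; cause fractions default to uniform."""
    span = tuple(range(years[0], years[-1] + 1))
    demography = Demography(
        years=span, live_births={y: births for y in span}, nmr0=nmr0, u5mr0=u5mr0
    )
    if cause_fractions is None:
        cause_fractions = {c: 1.0 / len(causes) for c in causes}
        # exact unit sum
        first = causes[0]
        cause_fractions[first] += 1.0 - sum(cause_fractions.values())
    cod = {b: CauseOfDeathProfile(age_band=b, fractions=dict(cause_fractions)) for b in AGE_BANDS}
    return CountryProfile(
        name=name,
        demography=demography,
        cod=cod,
        interventions=tuple(interventions),
        coverages=tuple(coverages),
        risk_factors=tuple(risk_factors),
        mode=mode,
    )


def iv(id, E, afs, bands=(NEONATAL, POSTNEONATAL), period="curative", herd=None):
    return InterventionSpec(
        id=id, name=id, period=period, age_bands=bands,
        effectiveness=E, affected_fractions=dict(afs), herd=herd,
    )


def brute_force_averted(profile: CountryProfile, t0: int, t1: int) -> float:
    """Joint deaths averted over (t0, t1] by direct multiplication of both
    scenarios' residual products (independent of the engine)."""
    assert not profile.risk_factors, "oracle covers intervention channels only"
    total = 0.0
    for t in range(t0 + 1, t1 + 1):
        births = profile.demography.births(t)
        band_deaths = {
            NEONATAL: births * profile.demography.nmr0 / 1000.0,
            POSTNEONATAL: births * (profile.demography.u5mr0 - profile.demography.nmr0) / 1000.0,
        }
        for band in AGE_BANDS:
            for cause, frac in profile.cod[band].fractions.items():
                d0 = band_deaths[band] * frac
                r_base, r_t = 1.0, 1.0
                for spec in profile.interventions:
                    af = spec.affected_fractions.get(cause, 0.0)
                    if af <= 0.0 or band not in spec.age_bands:
                        continue
                    series = profile.coverage_series(spec.id)
                    c_base = series.value_at(t0) / 100.0
                    c_t = series.value_at(t) / 100.0
                    r_base *= 1.0 - c_base * spec.effectiveness * af
                    r_t *= 1.0 - c_t * spec.effectiveness * af
                total += d0 * (1.0 - r_t / r_base)
    return total


@pytest.fixture
def single_intervention_profile():
    """One cause, one intervention, coverage 0% -> 60% over one year:
    closed-form lives saved = D0 * 0.6 * 0.5 * 1.0 = 300 per 1,000 deaths."""
    spec = iv("iv_a", 0.5, {"cause_a": 1.0}, bands=(POSTNEONATAL,))
    cov = CoverageSeries("iv_a", {2008: 0.0, 2009: 60.0})
    # births chosen so the post-neonatal band has exactly 1,000 deaths/year
    return make_profile([spec], [cov], births=50_000.0, years=(2008, 2009))


@pytest.fixture
def three_intervention_profile():
    """Two causes, three interventions with overlapping targets."""
    specs = [
        iv("iv_a", 0.5, {"cause_a": 0.8}),
        iv("iv_b", 0.7, {"cause_a": 0.3, "cause_b": 0.6}, bands=(POSTNEONATAL,)),
        iv("iv_c", 0.4, {"cause_b": 1.0}, bands=(NEONATAL,)),
    ]
    covs = [
        CoverageSeries("iv_a", {2008: 30.0, 2014: 75.0}),
        CoverageSeries("iv_b", {2008: 50.0, 2014: 20.0}),
        CoverageSeries("iv_c", {2008: 0.0, 2014: 90.0}),
    ]
    return make_profile(specs, covs, causes=("cause_a", "cause_b"))
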