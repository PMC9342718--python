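"""Seeded generator of country profiles with known ground truth.

Emulates the structure of a national child-health database: a portfolio of
a few dozen interventions grouped by delivery period with sparse per-cause
affected fractions, two coverage anchors per intervention mimicking a
baseline/endline survey pair, a cause-of-death split per age band, and
optional stunting/wasting risk factors. Default demographic anchors are a
high-burden West African setting: 800,000 annual live births, baseline
neonatal mortality 31.2 and under-five mortality 75.3 per 1,000 live
births, stunting prevalence falling 27.5% -> 18.8% and wasting
8.6% -> 4.7% over the span.

All randomness flows from a single ``numpy`` generator seeded per call, so
a fixed seed reproduces a profile bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ProfileValidationError
from .profile import (
    AGE_BANDS,
    NEONATAL,
    PERIODS,
    POSTNEONATAL,
    CauseOfDeathProfile,
    CountryProfile,
    CoverageSeries,
    Demography,
    InterventionSpec,
    RiskFactorSpec,
)

#: plausible percent coverage range by delivery period
DEFAULT_COVERAGE_RANGES: dict[str, tuple[float, float]] = {
    "pregnancy": (10.0, 90.0),
    "childbirth": (15.0, 80.0),
    "breastfeeding": (40.0, 70.0),
    "preventive": (0.0, 80.0),
    "vaccine": (60.0, 99.0),
    "curative": (5.0, 75.0),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the generator; defaults mirror the study setting."""

    seed: int = 0
    n_interventions: int = 20
    n_causes: int = 6
    birth_count: float = 800_000.0
    t0: int = 2008
    t1: int = 2014
    nmr0: float = 31.2
    u5mr0: float = 75.3
    effectiveness_range: tuple[float, float] = (0.2, 0.9)
    affected_fraction_range: tuple[float, float] = (0.1, 0.8)
    coverage_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVERAGE_RANGES)
    )
    include_risk_factors: bool = True
    rr_range: tuple[float, float] = (1.5, 4.0)
    mode: str = "direct_entry"

    def validate(self) -> None:
        if self.n_interventions < 1:
            raise ProfileValidationError("synth.n_interventions", "need at least one intervention")
        if self.n_causes < 1:
            raise ProfileValidationError("synth.n_causes", "need at least one cause")
        if not self.t0 < self.t1:
            raise ProfileValidationError("synth.years", f"need t0 < t1, got {self.t0}, {self.t1}")
        for name, (lo, hi) in (
            ("effectiveness_range", self.effectiveness_range),
            ("affected_fraction_range", self.affected_fraction_range),
        ):
            if not 0.0 <= lo <= hi <= 1.0:
                raise ProfileValidationError(f"synth.{name}", f"range {lo}..{hi} outside [0,1]")
        for period, (lo, hi) in self.coverage_ranges.items():
            if not 0.0 <= lo <= hi <= 100.0:
                raise ProfileValidationError("synth.coverage_ranges", f"range {lo}..{hi} outside [0,100]", row=period)
        if not 1.0 <= self.rr_range[0] <= self.rr_range[1]:
            raise ProfileValidationError("synth.rr_range", f"relative risks must be >= 1, got {self.rr_range}")


def gen_profile(config: SynthConfig | None = None, **overrides) -> CountryProfile:
    """Generate a validated synthetic country profile.

    Deterministic for a fixed seed. Each intervention touches one or two
    causes (sparse affected fractions), has effectiveness drawn from the
    configured range, and carries two coverage anchors (t0, t1) drawn from
    its period's plausible range. With risk factors enabled, stunting and
    wasting get relative risks on up to three post-neonatal causes and one
    linked nutrition intervention each.
    """
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SynthConfig or keyword overrides, not both")
    config.validate()
    rng = np.random.default_rng(config.seed)

    years = tuple(range(config.t0, config.t1 + 1))
    demography = Demography(
        years=years,
        live_births={y: float(config.birth_count) for y in years},
        nmr0=config.nmr0,
        u5mr0=config.u5mr0,
    )

    causes = [f"cause_{i:02d}" for i in range(config.n_causes)]
    cod = {}
    for band in AGE_BANDS:
        fractions = rng.dirichlet(np.ones(config.n_causes))
        # exact unit sum despite float noise: renormalise onto the last cause
        fracs = {c: float(f) for c, f in zip(causes, fractions)}
        fracs[causes[-1]] += 1.0 - sum(fracs.values())
        cod[band] = CauseOfDeathProfile(age_band=band, fractions=fracs)

    band_choices = [(NEONATAL,), (POSTNEONATAL,), (NEONATAL, POSTNEONATAL)]
    interventions = []
    coverages = []
    for i in range(config.n_interventions):
        period = str(rng.choice(PERIODS))
        n_touched = int(rng.integers(1, 3))  # sparse: 1-2 causes
        touched = rng.choice(config.n_causes, size=min(n_touched, config.n_causes), replace=False)
        lo, hi = config.affected_fraction_range
        afs = {causes[j]: float(rng.uniform(lo, hi)) for j in touched}
        elo, ehi = config.effectiveness_range
        bands = band_choices[int(rng.integers(0, 3))]
        iv = InterventionSpec(
            id=f"iv{i:02d}",
            name=f"Synthetic intervention {i:02d} ({period})",
            period=period,
            age_bands=bands,
            effectiveness=float(rng.uniform(elo, ehi)),
            affected_fractions=afs,
        )
        interventions.append(iv)
        clo, chi = config.coverage_ranges.get(period, (0.0, 100.0))
        c0, c1 = sorted(float(rng.uniform(clo, chi)) for _ in range(2))
        # most portfolios improve over time, but some channels slip back
        if rng.random() < 0.2:
            c0, c1 = c1, c0
        coverages.append(CoverageSeries(iv.id, {config.t0: round(c0, 1), config.t1: round(c1, 1)}))

    risk_factors = []
    if config.include_risk_factors and config.n_causes >= 2:
        rlo, rhi = config.rr_range
        prevalences = {"stunting": (27.5, 18.8), "wasting": (8.6, 4.7)}
        for name, (p0, p1) in prevalences.items():
            n_rr = int(min(3, config.n_causes))
            rr_causes = rng.choice(config.n_causes, size=n_rr, replace=False)
            linked = str(rng.choice([iv.id for iv in interventions]))
            risk_factors.append(
                RiskFactorSpec(
                    name=name,
                    prevalence_anchors={config.t0: p0, config.t1: p1},
                    relative_risks={causes[j]: float(rng.uniform(rlo, rhi)) for j in rr_causes},
                    linked_interventions=((linked, float(rng.uniform(0.1, 0.5))),),
                )
            )

    profile = CountryProfile(
        name=f"synthetic-{config.seed}",
        demography=demography,
        cod=cod,
        interventions=tuple(interventions),
        coverages=tuple(coverages),
        risk_factors=tuple(risk_factors),
        mode=config.mode,
    )
    profile.validate()
    return profile


def gen_closed_form_case(
    c0: float, c1: float, E: float, AF: float, deaths: float
) -> tuple[CountryProfile, float]:
    """Single-cause, single-intervention profile with a known answer.

    The profile has ``deaths`` annual baseline deaths from one cause in the
    1-59 month band and one intervention whose coverage moves from ``c0``
    to ``c1`` (proportions) over a single year. The exact lives saved are

        deaths * (c1 - c0) * E * AF / (1 - c0 * E * AF)

    Raises a degenerate-input error when ``c0 * E * AF == 1`` (the cause is
    fully averted at baseline, so the counterfactual is undefined).
    """
    for name, v in (("c0", c0), ("c1", c1), ("E", E), ("AF", AF)):
        if not 0.0 <= v <= 1.0:
            raise ProfileValidationError(f"closed_form.{name}", f"must be in [0,1], got {v}")
    if deaths <= 0:
        raise ProfileValidationError("closed_form.deaths", f"must be > 0, got {deaths}")
    if c0 * E * AF >= 1.0:
        raise DegenerateInputError("c0*E*AF = 1: cause fully averted at baseline")

    t0, t1 = 2000, 2001
    births = deaths * 1000.0  # post-neonatal rate gap of 1 per 1,000 yields `deaths`
    demography = Demography(
        years=(t0, t1), live_births={t0: births, t1: births}, nmr0=1.0, u5mr0=2.0
    )
    cod = {
        band: CauseOfDeathProfile(age_band=band, fractions={"target": 1.0})
        for band in AGE_BANDS
    }
    iv = InterventionSpec(
        id="iv00",
        name="Closed-form intervention",
        period="curative",
        age_bands=(POSTNEONATAL,),
        effectiveness=E,
        affected_fractions={"target": AF},
    )
    profile = CountryProfile(
        name="closed-form",
        demography=demography,
        cod=cod,
        interventions=(iv,),
        coverages=(CoverageSeries("iv00", {t0: 100.0 * c0, t1: 100.0 * c1}),),
        mode="intervention_only",
    )
    profile.validate()
    expected = deaths * (c1 - c0) * E * AF / (1.0 - c0 * E * AF)
    return profile, expected
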