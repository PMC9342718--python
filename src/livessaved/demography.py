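"""Expected baseline deaths by year, age band, and cause.

Rates are converted to deaths with the simple cohort-synthetic
approximation ``deaths = births x rate/1000`` per band, using
``u5mr0 - nmr0`` for the 1-59 month band. Full life-table machinery (as in
cohort-component projection tools) is deliberately out of scope: only the
two headline rates are inputs here, and births are exogenous. Deaths are
real-valued throughout; rounding happens only in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ProfileValidationError
from .profile import AGE_BANDS, NEONATAL, POSTNEONATAL, CountryProfile, Demography


@dataclass(frozen=True)
class BaselineDeaths:
    """Expected deaths in one year, keyed by (age band, cause)."""

    year: int
    deaths: dict[tuple[str, str], float]

    def band_total(self, band: str) -> float:
        return sum(v for (b, _), v in self.deaths.items() if b == band)

    def total(self) -> float:
        return sum(self.deaths.values())


def band_deaths(demography: Demography, year: int) -> dict[str, float]:
    """Expected deaths per age band in ``year`` at the baseline rates.

    Neonatal deaths are ``births x nmr0/1000``; deaths at 1-59 months are
    ``births x (u5mr0 - nmr0)/1000``. Years outside the span clamp to the
    nearest year's births.
    """
    if demography.u5mr0 <= demography.nmr0:
        raise ProfileValidationError("demography.u5mr0", "must exceed nmr0")
    births = demography.births(year)
    return {
        NEONATAL: births * demography.nmr0 / 1000.0,
        POSTNEONATAL: births * (demography.u5mr0 - demography.nmr0) / 1000.0,
    }


def baseline_cause_deaths(profile: CountryProfile, year: int) -> BaselineDeaths:
    """Split each band's baseline deaths across causes by the cause-of-death
    fractions. Conservation holds by construction: the per-cause entries of
    a band sum to the band total."""
    totals = band_deaths(profile.demography, year)
    deaths: dict[tuple[str, str], float] = {}
    for band in AGE_BANDS:
        fractions = profile.cod[band].fractions
        s = sum(fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ProfileValidationError("cod.fractions", f"band {band!r} fractions sum to {s}, expected 1")
        for cause, frac in fractions.items():
            deaths[(band, cause)] = totals[band] * frac
    return BaselineDeaths(year=year, deaths=deaths)
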