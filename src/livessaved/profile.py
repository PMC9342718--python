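"""Country profiles: the full set of model inputs.

A profile bundles everything the deterministic engine needs: an annual
live-births series with baseline neonatal and under-five mortality rates,
a cause-of-death fraction table per age band, the intervention portfolio
(effectiveness and per-cause affected fractions), percent coverage anchors
per intervention, and optional nutrition risk factors (stunting, wasting)
with prevalence anchors and per-cause relative risks.

Coverages and prevalences are stored as PERCENT, exactly as they appear in
published coverage tables; conversion to proportions happens once at the
engine boundary (`livessaved.engine`).

Profiles round-trip through a directory of UTF-8 tab-separated tables plus
a small YAML config (see :func:`write_profile` / :func:`load_profile`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .errors import ProfileValidationError

NEONATAL = "neonatal"
POSTNEONATAL = "1-59m"
AGE_BANDS = (NEONATAL, POSTNEONATAL)

PERIODS = ("pregnancy", "childbirth", "breastfeeding", "preventive", "vaccine", "curative")
MODES = ("intervention_only", "direct_entry")
RISK_FACTOR_NAMES = ("stunting", "wasting")

NA_MARKER = "NA"


@dataclass(frozen=True)
class Demography:
    """Annual live births plus baseline mortality rates.

    Rates are deaths per 1,000 live births: ``nmr0`` for the first month of
    life, ``u5mr0`` for birth to exactly five years.
    """

    years: tuple[int, ...]
    live_births: dict[int, float]
    nmr0: float
    u5mr0: float

    def validate(self) -> None:
        if not self.years:
            raise ProfileValidationError("demography.years", "empty year span")
        if list(self.years) != sorted(set(self.years)):
            raise ProfileValidationError("demography.years", "years must be strictly increasing")
        for y in self.years:
            b = self.live_births.get(y)
            if b is None or not b > 0:
                raise ProfileValidationError("demography.live_births", "live births must be > 0", row=y)
        if not 0 < self.nmr0:
            raise ProfileValidationError("demography.nmr0", f"must be > 0, got {self.nmr0}")
        if not self.nmr0 < self.u5mr0:
            raise ProfileValidationError(
                "demography.u5mr0", f"must exceed nmr0 ({self.nmr0}), got {self.u5mr0}"
            )

    def births(self, year: int) -> float:
        """Live births in ``year``, clamped to the span."""
        y = min(max(year, self.years[0]), self.years[-1])
        return self.live_births[y]


@dataclass(frozen=True)
class CauseOfDeathProfile:
    """Fraction of an age band's deaths attributed to each cause."""

    age_band: str
    fractions: dict[str, float]

    def validate(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise ProfileValidationError("cod.age_band", f"unknown band {self.age_band!r}")
        for cause, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ProfileValidationError("cod.fraction", f"must be in [0,1], got {f}", row=cause)
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ProfileValidationError(
                "cod.fractions", f"band {self.age_band!r} fractions sum to {total}, expected 1"
            )


@dataclass(frozen=True)
class HerdSpec:
    """Indirect-protection boost for vaccines and bed nets.

    Above ``threshold`` coverage (proportion), effective coverage is
    multiplied by up to ``1 + max_boost`` at full coverage, capped at 1.
    """

    threshold: float
    max_boost: float

    def validate(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ProfileValidationError("herd.threshold", f"must be in [0,1], got {self.threshold}")
        if self.max_boost < 0:
            raise ProfileValidationError("herd.max_boost", f"must be >= 0, got {self.max_boost}")


@dataclass(frozen=True)
class InterventionSpec:
    """One intervention: effectiveness E and per-cause affected fractions AF.

    ``effectiveness`` is the proportion of amenable cause-specific deaths
    prevented in a covered child; ``affected_fractions[cause]`` is the
    fraction of that cause's mortality amenable to this intervention.
    """

    id: str
    name: str
    period: str
    age_bands: tuple[str, ...]
    effectiveness: float
    affected_fractions: dict[str, float]
    herd: Optional[HerdSpec] = None

    def validate(self) -> None:
        if not self.id:
            raise ProfileValidationError("intervention.id", "empty id")
        if self.period not in PERIODS:
            raise ProfileValidationError("intervention.period", f"unknown period {self.period!r}", row=self.id)
        if not self.age_bands or any(b not in AGE_BANDS for b in self.age_bands):
            raise ProfileValidationError("intervention.age_bands", f"invalid bands {self.age_bands}", row=self.id)
        if not 0.0 <= self.effectiveness <= 1.0:
            raise ProfileValidationError(
                "intervention.effectiveness", f"must be in [0,1], got {self.effectiveness}", row=self.id
            )
        for cause, af in self.affected_fractions.items():
            if not 0.0 <= af <= 1.0:
                raise ProfileValidationError(
                    "intervention.affected_fraction", f"must be in [0,1], got {af}", row=(self.id, cause)
                )
        if not any(af > 0 for af in self.affected_fractions.values()):
            raise ProfileValidationError(
                "intervention.affected_fractions", "at least one nonzero affected fraction required", row=self.id
            )
        if self.herd is not None:
            self.herd.validate()


@dataclass(frozen=True)
class CoverageSeries:
    """Percent coverage anchors per intervention, linearly interpolated.

    Queries outside the anchor span clamp to the nearest anchor.
    """

    intervention_id: str
    anchors: dict[int, float]

    def validate(self) -> None:
        if not self.anchors:
            raise ProfileValidationError("coverage.anchors", "at least one anchor required", row=self.intervention_id)
        for y, c in self.anchors.items():
            if not 0.0 <= c <= 100.0:
                raise ProfileValidationError(
                    "coverage.anchor", f"must be in [0,100], got {c}", row=(self.intervention_id, y)
                )

    def value_at(self, year: float) -> float:
        """Coverage percent at ``year``: linear between anchors, clamped outside."""
        yrs = sorted(self.anchors)
        if year <= yrs[0]:
            return self.anchors[yrs[0]]
        if year >= yrs[-1]:
            return self.anchors[yrs[-1]]
        for y0, y1 in zip(yrs, yrs[1:]):
            if y0 <= year <= y1:
                c0, c1 = self.anchors[y0], self.anchors[y1]
                return c0 + (c1 - c0) * (year - y0) / (y1 - y0)
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class RiskFactorSpec:
    """A nutrition risk factor (stunting or wasting).

    Falling prevalence lowers the mean relative risk of the infection causes
    named in ``relative_risks``. ``linked_interventions`` lists
    (intervention id, prevalence-reduction efficacy) pairs used when the
    profile runs in intervention-only mode.
    """

    name: str
    prevalence_anchors: dict[int, float]
    relative_risks: dict[str, float]
    linked_interventions: tuple[tuple[str, float], ...] = ()

    def validate(self) -> None:
        if self.name not in RISK_FACTOR_NAMES:
            raise ProfileValidationError("risk_factor.name", f"unknown risk factor {self.name!r}")
        if not self.prevalence_anchors:
            raise ProfileValidationError("risk_factor.prevalence", "at least one anchor required", row=self.name)
        for y, p in self.prevalence_anchors.items():
            if not 0.0 <= p <= 100.0:
                raise ProfileValidationError(
                    "risk_factor.prevalence", f"must be in [0,100], got {p}", row=(self.name, y)
                )
        for cause, rr in self.relative_risks.items():
            if rr < 1.0:
                raise ProfileValidationError(
                    "risk_factor.relative_risk", f"must be >= 1, got {rr}", row=(self.name, cause)
                )
        for iid, eff in self.linked_interventions:
            if not 0.0 <= eff <= 1.0:
                raise ProfileValidationError(
                    "risk_factor.link_efficacy", f"must be in [0,1], got {eff}", row=(self.name, iid)
                )

    def prevalence_at(self, year: float) -> float:
        """Prevalence percent at ``year`` (linear, clamped)."""
        series = CoverageSeries(self.name, self.prevalence_anchors)
        return series.value_at(year)


@dataclass(frozen=True)
class CountryProfile:
    """All inputs for one country analysis.

    ``mode`` selects how stunting/wasting enter the model:

    * ``direct_entry`` — measured prevalence anchors drive the risk
      channels; linked-intervention prevalence effects are disabled.
    * ``intervention_only`` — prevalence is moved by linked interventions;
      prevalence anchors beyond the baseline year are ignored.

    The two modes are mutually exclusive to prevent double counting.
    """

    name: str
    demography: Demography
    cod: dict[str, CauseOfDeathProfile]
    interventions: tuple[InterventionSpec, ...]
    coverages: tuple[CoverageSeries, ...]
    risk_factors: tuple[RiskFactorSpec, ...] = ()
    mode: str = "direct_entry"

    def validate(self) -> None:
        self.demography.validate()
        if set(self.cod) != set(AGE_BANDS):
            raise ProfileValidationError("cod", f"need one cause profile per band {AGE_BANDS}, got {sorted(self.cod)}")
        for band, codp in self.cod.items():
            if codp.age_band != band:
                raise ProfileValidationError("cod", f"band key {band!r} != profile band {codp.age_band!r}")
            codp.validate()
        if self.mode not in MODES:
            raise ProfileValidationError("mode", f"unknown mode {self.mode!r}")
        ids = [iv.id for iv in self.interventions]
        if len(set(ids)) != len(ids):
            raise ProfileValidationError("interventions", "duplicate intervention ids")
        known = set(ids)
        causes = self.causes()
        for iv in self.interventions:
            iv.validate()
            for cause in iv.affected_fractions:
                if cause not in causes:
                    raise ProfileValidationError(
                        "intervention.affected_fraction", f"unknown cause {cause!r}", row=iv.id
                    )
        cov_ids = [cs.intervention_id for cs in self.coverages]
        if len(set(cov_ids)) != len(cov_ids):
            raise ProfileValidationError("coverage", "duplicate coverage series")
        for cs in self.coverages:
            cs.validate()
            if cs.intervention_id not in known:
                raise ProfileValidationError(
                    "coverage.intervention_id", f"unknown intervention id {cs.intervention_id!r}"
                )
        if set(cov_ids) != known:
            missing = known - set(cov_ids)
            raise ProfileValidationError("coverage", f"interventions without a coverage series: {sorted(missing)}")
        for rf in self.risk_factors:
            rf.validate()
            for cause in rf.relative_risks:
                if cause not in causes:
                    raise ProfileValidationError("risk_factor.relative_risk", f"unknown cause {cause!r}", row=rf.name)
            for iid, _ in rf.linked_interventions:
                if iid not in known:
                    raise ProfileValidationError(
                        "risk_factor.linked_intervention", f"unknown intervention id {iid!r}", row=rf.name
                    )

    # -- convenience lookups -------------------------------------------------

    def causes(self) -> set[str]:
        return set().union(*(set(c.fractions) for c in self.cod.values()))

    def intervention(self, iid: str) -> InterventionSpec:
        for iv in self.interventions:
            if iv.id == iid:
                return iv
        raise KeyError(iid)

    def coverage_series(self, iid: str) -> CoverageSeries:
        for cs in self.coverages:
            if cs.intervention_id == iid:
                return cs
        raise KeyError(iid)

    def with_coverages(self, coverages) -> "CountryProfile":
        """Copy of the profile with the coverage series replaced."""
        return replace(self, coverages=tuple(coverages))


# ---------------------------------------------------------------------------
# Directory round-trip
# ---------------------------------------------------------------------------

_FILES = {
    "config": "config.yaml",
    "demography": "demography.tsv",
    "causes": "causes.tsv",
    "interventions": "interventions.tsv",
    "affected_fractions": "affected_fractions.tsv",
    "coverage": "coverage.tsv",
    "risk_relative_risks": "risk_relative_risks.tsv",
    "risk_prevalence": "risk_prevalence.tsv",
    "risk_links": "risk_links.tsv",
}


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[NA_MARKER], keep_default_na=False, float_precision="round_trip"
    )


def write_profile(profile: CountryProfile, path) -> None:
    """Write ``profile`` to a directory of tab-separated tables + config.yaml.

    The layout is diff-able and spreadsheet-editable; ``load_profile`` on the
    written directory reproduces the profile exactly.
    """
    profile.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    config = {
        "name": profile.name,
        "mode": profile.mode,
        "nmr0": profile.demography.nmr0,
        "u5mr0": profile.demography.u5mr0,
    }
    (path / _FILES["config"]).write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")

    def _write(df: pd.DataFrame, key: str) -> None:
        # %.17g round-trips IEEE doubles exactly through the text tables
        df.to_csv(path / _FILES[key], sep="\t", index=False, na_rep=NA_MARKER, float_format="%.17g")

    _write(
        pd.DataFrame(
            {"year": list(profile.demography.years),
             "live_births": [profile.demography.live_births[y] for y in profile.demography.years]}
        ),
        "demography",
    )
    _write(
        pd.DataFrame(
            [(band, cause, frac) for band in AGE_BANDS for cause, frac in sorted(profile.cod[band].fractions.items())],
            columns=["age_band", "cause", "fraction"],
        ),
        "causes",
    )
    _write(
        pd.DataFrame(
            [
                {
                    "id": iv.id,
                    "name": iv.name,
                    "period": iv.period,
                    "age_bands": ",".join(iv.age_bands),
                    "effectiveness": iv.effectiveness,
                    "herd_threshold": iv.herd.threshold if iv.herd else None,
                    "herd_max_boost": iv.herd.max_boost if iv.herd else None,
                }
                for iv in profile.interventions
            ]
        ),
        "interventions",
    )
    _write(
        pd.DataFrame(
            [
                (iv.id, cause, af)
                for iv in profile.interventions
                for cause, af in sorted(iv.affected_fractions.items())
            ],
            columns=["intervention_id", "cause", "affected_fraction"],
        ),
        "affected_fractions",
    )
    _write(
        pd.DataFrame(
            [(cs.intervention_id, y, c) for cs in profile.coverages for y, c in sorted(cs.anchors.items())],
            columns=["intervention_id", "year", "coverage"],
        ),
        "coverage",
    )
    if profile.risk_factors:
        _write(
            pd.DataFrame(
                [(rf.name, cause, rr) for rf in profile.risk_factors for cause, rr in sorted(rf.relative_risks.items())],
                columns=["name", "cause", "relative_risk"],
            ),
            "risk_relative_risks",
        )
        _write(
            pd.DataFrame(
                [(rf.name, y, p) for rf in profile.risk_factors for y, p in sorted(rf.prevalence_anchors.items())],
                columns=["name", "year", "prevalence"],
            ),
            "risk_prevalence",
        )
        _write(
            pd.DataFrame(
                [(rf.name, iid, eff) for rf in profile.risk_factors for iid, eff in rf.linked_interventions],
                columns=["name", "intervention_id", "efficacy"],
            ),
            "risk_links",
        )


def load_profile(path) -> CountryProfile:
    """Load and validate a profile directory written by :func:`write_profile`."""
    path = Path(path)
    cfg_path = path / _FILES["config"]
    if not cfg_path.exists():
        raise FileNotFoundError(f"profile config not found: {cfg_path}")
    config = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))

    demo_df = _read_tsv(path / _FILES["demography"])
    demography = Demography(
        years=tuple(int(y) for y in demo_df["year"]),
        live_births={int(r.year): float(r.live_births) for r in demo_df.itertuples()},
        nmr0=float(config["nmr0"]),
        u5mr0=float(config["u5mr0"]),
    )

    causes_df = _read_tsv(path / _FILES["causes"])
    cod = {
        band: CauseOfDeathProfile(
            age_band=band,
            fractions={r.cause: float(r.fraction) for r in causes_df.itertuples() if r.age_band == band},
        )
        for band in AGE_BANDS
    }

    iv_df = _read_tsv(path / _FILES["interventions"])
    af_df = _read_tsv(path / _FILES["affected_fractions"])
    interventions = []
    for r in iv_df.itertuples():
        herd = None
        if not (pd.isna(r.herd_threshold) or pd.isna(r.herd_max_boost)):
            herd = HerdSpec(threshold=float(r.herd_threshold), max_boost=float(r.herd_max_boost))
        afs = {
            a.cause: float(a.affected_fraction)
            for a in af_df.itertuples()
            if a.intervention_id == r.id
        }
        interventions.append(
            InterventionSpec(
                id=str(r.id),
                name=str(r.name),
                period=str(r.period),
                age_bands=tuple(str(r.age_bands).split(",")),
                effectiveness=float(r.effectiveness),
                affected_fractions=afs,
                herd=herd,
            )
        )

    cov_df = _read_tsv(path / _FILES["coverage"])
    coverages = []
    for iid, grp in cov_df.groupby("intervention_id", sort=False):
        coverages.append(
            CoverageSeries(
                intervention_id=str(iid),
                anchors={int(r.year): float(r.coverage) for r in grp.itertuples()},
            )
        )

    risk_factors = []
    rr_path = path / _FILES["risk_relative_risks"]
    if rr_path.exists():
        rr_df = _read_tsv(rr_path)
        prev_df = _read_tsv(path / _FILES["risk_prevalence"])
        links_path = path / _FILES["risk_links"]
        links_df = _read_tsv(links_path) if links_path.exists() else pd.DataFrame(columns=["name", "intervention_id", "efficacy"])
        for name in rr_df["name"].unique():
            risk_factors.append(
                RiskFactorSpec(
                    name=str(name),
                    prevalence_anchors={
                        int(r.year): float(r.prevalence) for r in prev_df.itertuples() if r.name == name
                    },
                    relative_risks={
                        r.cause: float(r.relative_risk) for r in rr_df.itertuples() if r.name == name
                    },
                    linked_interventions=tuple(
                        (str(r.intervention_id), float(r.efficacy))
                        for r in links_df.itertuples()
                        if r.name == name
                    ),
                )
            )

    profile = CountryProfile(
        name=str(config["name"]),
        demography=demography,
        cod=cod,
        interventions=tuple(interventions),
        coverages=tuple(coverages),
        risk_factors=tuple(risk_factors),
        mode=str(config["mode"]),
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Packaged fixtures (published Ghana coverage / lives-saved tables)
# ---------------------------------------------------------------------------

FIXTURE_TABLES = ("table1", "table2", "table3")


def load_fixture(table: str) -> pd.DataFrame:
    """Load one of the packaged published tables as a DataFrame.

    ``table1`` — 2008→2014 evaluation: coverage anchors, printed coverage
    change, and lives saved under intervention-based modelling and under
    direct entry of stunting/wasting (with printed percentage shares).
    ``table2`` — missed-opportunity ranking at the 90% threshold, lives
    saved split by age band. ``table3`` — universal scale-up to 100%.

    NA cells mark channels disabled in a mode, never zero.
    """
    if table not in FIXTURE_TABLES:
        raise ValueError(f"unknown fixture table {table!r}; expected one of {FIXTURE_TABLES}")
    ref = importlib.resources.files("livessaved") / "data" / "fixtures" / f"{table}.tsv"
    with importlib.resources.as_file(ref) as p:
        return _read_tsv(p)
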