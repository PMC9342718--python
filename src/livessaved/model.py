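"""Model / Results interface over the scenario engine.

``LivesSavedModel`` is constructed from a :class:`~livessaved.profile.CountryProfile`
(or a profile directory, or the synthetic generator) together with a
:class:`~livessaved.scenarios.ScenarioSpec`; ``fit()`` runs the deterministic
projection and returns a results object carrying the per-channel ledger,
totals, percentage shares, counterfactual mortality rates, and a
``summary()`` table. The projection is deterministic, so the results carry
point outputs and accounting diagnostics rather than sampling uncertainty.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .engine import LivesSavedResult
from .profile import CountryProfile, load_profile
from .reporting import ShareTable, render, round_half_away, shares
from .scenarios import (
    MissedOpportunityRow,
    ScaleupResult,
    ScenarioSpec,
    counterfactual_rates,
    evaluate,
    missed_opportunity,
    universal_scaleup,
)


class LivesSavedModel:
    """Deterministic lives-saved projection for one country profile.

    Parameters
    ----------
    profile
        Validated model inputs (demography, cause structure, interventions,
        coverages, risk factors, analysis mode).
    scenario
        What to run. Defaults to a retrospective evaluation over the
        profile's full year span.
    """

    def __init__(self, profile: CountryProfile, scenario: Optional[ScenarioSpec] = None):
        profile.validate()
        if scenario is None:
            years = profile.demography.years
            scenario = ScenarioSpec(kind="evaluate", t0=years[0], t1=years[-1])
        scenario.validate()
        self.profile = profile
        self.scenario = scenario

    @classmethod
    def from_profile_dir(cls, path, scenario: Optional[ScenarioSpec] = None) -> "LivesSavedModel":
        """Build from a profile directory (see :func:`livessaved.profile.load_profile`)."""
        return cls(load_profile(path), scenario)

    @classmethod
    def from_synthetic(cls, seed: int = 0, scenario: Optional[ScenarioSpec] = None, **config) -> "LivesSavedModel":
        """Build from the seeded synthetic generator."""
        from .synthetic import gen_profile

        return cls(gen_profile(seed=seed, **config), scenario)

    def fit(self) -> "LivesSavedResults | MissedOpportunityResults":
        """Run the scenario and return a results object."""
        s = self.scenario
        if s.kind == "evaluate":
            raw = evaluate(self.profile, s.t0, s.t1)
            rates = counterfactual_rates(self.profile, raw.deaths_by_band_year)
            return LivesSavedResults(self, raw, rates)
        if s.kind == "universal_scaleup":
            scale: ScaleupResult = universal_scaleup(self.profile, s.t0, s.t1, s.target)
            return LivesSavedResults(self, scale.result, scale.rates, coverage_increase=scale.coverage_increase)
        if s.kind == "missed_opportunity":
            rows = missed_opportunity(self.profile, s.t0, s.threshold, s.horizon)
            return MissedOpportunityResults(self, rows)
        raise ValueError(f"unknown scenario kind {s.kind!r}")


class LivesSavedResults:
    """Results of an evaluation or universal scale-up run."""

    def __init__(
        self,
        model: LivesSavedModel,
        raw: LivesSavedResult,
        rates: dict[int, tuple[float, float]],
        coverage_increase: Optional[dict[str, float]] = None,
    ):
        self.model = model
        self.raw = raw
        self.rates = rates
        self.coverage_increase = coverage_increase
        self.ledger = raw.to_frame()
        self.totals_ = pd.Series(raw.totals, name="lives_saved").sort_index()
        self.grand_total_ = raw.grand_total

    def share_table(self) -> ShareTable:
        """Percentage shares of the grand total per channel."""
        return shares(self.raw.totals)

    def mortality_rates(self) -> pd.DataFrame:
        """Counterfactual NMR/U5MR per year (deaths per 1,000 live births)."""
        return pd.DataFrame(
            [{"year": y, "nmr": n, "u5mr": u} for y, (n, u) in sorted(self.rates.items())],
            columns=["year", "nmr", "u5mr"],
        )

    def summary(self) -> str:
        """Human-readable run summary with the top channels and endline rates."""
        s = self.model.scenario
        p = self.model.profile
        lines = [
            "Lives-saved projection",
            "=" * 54,
            f"profile:      {p.name}",
            f"scenario:     {s.kind}  span ({s.t0}, {s.t1}]",
            f"mode:         {p.mode}",
            f"grand total:  {round_half_away(self.grand_total_):,.0f} lives saved",
        ]
        if self.rates:
            y = max(self.rates)
            nmr, u5mr = self.rates[y]
            lines.append(
                f"rates {y}:   NMR {round_half_away(nmr, 1):.1f}, U5MR {round_half_away(u5mr, 1):.1f} per 1,000 live births"
            )
        lines.append("-" * 54)
        lines.append(f"{'channel':<28}{'lives saved':>14}{'share %':>10}")
        if self.grand_total_ != 0.0:
            table = self.share_table()
            for ch, v, sh in sorted(table.rows, key=lambda r: (-r[1], r[0])):
                lines.append(f"{ch:<28}{v:>14,}{sh:>10.1f}")
            lines.append(f"{'Total':<28}{table.total:>14,}{100.0:>10.1f}")
        else:
            lines.append("(no coverage change: zero lives saved on every channel)")
        return "\n".join(lines) + "\n"

    def plot_shares(self, ax=None):
        """Bar chart of per-channel shares (optional diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        table = self.share_table()
        channels = [r[0] for r in table.rows]
        values = [r[2] for r in table.rows]
        ax.barh(channels, values)
        ax.set_xlabel("share of lives saved (%)")
        ax.invert_yaxis()
        return ax

    def render(self, format: str = "csv", path=None) -> str:
        return render(self.raw, format=format, path=path)


class MissedOpportunityResults:
    """Ranked one-at-a-time scale-up results."""

    def __init__(self, model: LivesSavedModel, rows: Sequence[MissedOpportunityRow]):
        self.model = model
        self.rows = list(rows)

    def to_frame(self) -> pd.DataFrame:
        from .reporting import _mot_frame

        return _mot_frame(self.rows)

    def summary(self) -> str:
        s = self.model.scenario
        lines = [
            "Missed-opportunity ranking",
            "=" * 66,
            f"profile:    {self.model.profile.name}",
            f"base year:  {s.t0}   threshold: {s.threshold:.0f}%   horizon: {s.horizon} years",
            "-" * 66,
            f"{'intervention':<22}{'coverage %':>12}{'neonatal':>10}{'1-59m':>10}{'total':>10}",
        ]
        for r in self.rows:
            lines.append(
                f"{r.intervention_id:<22}{r.baseline_coverage:>12.1f}"
                f"{round_half_away(r.deaths_averted_neonatal):>10,.0f}"
                f"{round_half_away(r.deaths_averted_1to59m):>10,.0f}"
                f"{round_half_away(r.total):>10,.0f}"
            )
        if not self.rows:
            lines.append("(every intervention is at or above the threshold)")
        return "\n".join(lines) + "\n"

    def render(self, format: str = "csv", path=None) -> str:
        return render(self.rows, format=format, path=path)
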