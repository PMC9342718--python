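"""Impact engine: interpolation, residuals, attribution, lives saved.

Includes the independent brute-force oracle comparison and the
single-channel closed form, plus hypothesis property tests for the sign,
conservation, and monotonicity invariants.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from livessaved import (
    ConsistencyError,
    CoverageSeries,
    DegenerateInputError,
    HerdSpec,
    NEONATAL,
    POSTNEONATAL,
    attribute_lives_saved,
    cause_deaths_under_scenario,
    effective_coverage,
    interpolate_coverage,
    lives_saved,
    residual_factor,
    risk_scaler,
)
from conftest import brute_force_averted, iv, make_profile


class TestInterpolation:
    series = CoverageSeries("itn", {2008: 41.7, 2014: 70.9})

    def test_endline_anchor(self):
        assert interpolate_coverage(self.series, 2014) == pytest.approx(0.709)

    def test_midpoint_is_linear(self):
        assert interpolate_coverage(self.series, 2011) == pytest.approx(0.563)

    def test_clamps_before_span(self):
        assert interpolate_coverage(self.series, 2005) == pytest.approx(0.417)

    def test_clamps_after_span(self):
        assert interpolate_coverage(self.series, 2030) == pytest.approx(0.709)


class TestEffectiveCoverage:
    def test_identity_without_herd(self):
        assert effective_coverage(0.5, None) == 0.5

    def test_boost_is_zero_at_threshold(self):
        herd = HerdSpec(threshold=0.7, max_boost=0.2)
        assert effective_coverage(0.7, herd) == pytest.approx(0.7)

    def test_capped_at_one(self):
        herd = HerdSpec(threshold=0.0, max_boost=0.1)
        assert effective_coverage(1.0, herd) == 1.0

    def test_continuous_and_nondecreasing(self):
        herd = HerdSpec(threshold=0.6, max_boost=0.3)
        grid = [effective_coverage(c / 100.0, herd) for c in range(101)]
        assert all(b >= a for a, b in zip(grid, grid[1:]))
        # continuity across the threshold
        assert effective_coverage(0.6 + 1e-9, herd) == pytest.approx(effective_coverage(0.6, herd), abs=1e-8)


class TestResidualFactor:
    def test_empty_product_is_one(self):
        assert residual_factor([], {}, "any", NEONATAL) == 1.0

    def test_full_aversion(self):
        spec = iv("a", 1.0, {"c": 1.0})
        assert residual_factor([spec], {"a": 1.0}, "c", NEONATAL) == 0.0

    def test_two_interventions_multiply(self):
        specs = [iv("a", 0.6, {"c": 0.5}), iv("b", 0.6, {"c": 0.5})]
        got = residual_factor(specs, {"a": 0.5, "b": 0.5}, "c", NEONATAL)
        assert got == pytest.approx(0.7225, rel=1e-12)

    def test_band_mismatch_excluded(self):
        spec = iv("a", 1.0, {"c": 1.0}, bands=(POSTNEONATAL,))
        assert residual_factor([spec], {"a": 1.0}, "c", NEONATAL) == 1.0


class TestRiskScaler:
    @pytest.mark.parametrize(
        "P, RR, expected",
        [(0.0, 5.0, 1.0), (0.5, 3.0, 2.0), (0.086, 2.0, 1.086)],
    )
    def test_mean_relative_risk(self, P, RR, expected):
        assert risk_scaler(P, RR) == pytest.approx(expected)

    def test_increasing_in_both_arguments(self):
        assert risk_scaler(0.3, 2.0) < risk_scaler(0.4, 2.0) < risk_scaler(0.4, 2.5)


def one_cause_profile(c0_pct, c1_pct, E=0.5, AF=1.0):
    spec = iv("a", E, {"cause_a": AF}, bands=(POSTNEONATAL,))
    cov = CoverageSeries("a", {2008: c0_pct, 2009: c1_pct})
    # 1,000 post-neonatal deaths per year
    return make_profile([spec], [cov], births=50_000.0, years=(2008, 2009))


class TestScenarioDeaths:
    def test_baseline_inputs_reproduce_baseline_deaths(self):
        p = one_cause_profile(30.0, 60.0)
        deaths = cause_deaths_under_scenario(p, {"a": 0.3}, {}, 2008)
        assert deaths[(POSTNEONATAL, "cause_a")] == pytest.approx(1000.0, rel=1e-12)

    def test_coverage_rise_reduces_deaths(self):
        p = one_cause_profile(0.0, 60.0)
        deaths = cause_deaths_under_scenario(p, {"a": 0.6}, {}, 2009)
        assert deaths[(POSTNEONATAL, "cause_a")] == pytest.approx(700.0, rel=1e-12)

    def test_coverage_fall_raises_deaths(self):
        p = one_cause_profile(60.0, 30.0)
        deaths = cause_deaths_under_scenario(p, {"a": 0.3}, {}, 2009)
        assert deaths[(POSTNEONATAL, "cause_a")] == pytest.approx(1000.0 * 0.85 / 0.7, rel=1e-12)

    def test_fully_averted_baseline_is_degenerate(self):
        p = one_cause_profile(100.0, 100.0, E=1.0, AF=1.0)
        with pytest.raises(DegenerateInputError, match="cause_a"):
            cause_deaths_under_scenario(p, {"a": 1.0}, {}, 2009)


class TestAttribution:
    def test_single_changed_channel_takes_all(self):
        alloc = attribute_lives_saved(1000.0, {"a": 0.7, "b": 0.9}, {"a": 0.5, "b": 0.9})
        assert alloc["b"] == 0.0
        assert alloc["a"] == pytest.approx(1000.0 * (1.0 - 0.5 / 0.7), rel=1e-12)

    def test_symmetric_channels_split_evenly(self):
        alloc = attribute_lives_saved(1000.0, {"a": 0.8, "b": 0.8}, {"a": 0.6, "b": 0.6})
        assert alloc["a"] == pytest.approx(alloc["b"], rel=1e-12)
        total = 1000.0 * (1.0 - (0.6 / 0.8) ** 2)
        assert alloc["a"] + alloc["b"] == pytest.approx(total, rel=1e-12)

    def test_opposing_channels_carry_signed_allocations(self):
        # c1: 0 -> 0.6 and c2: 0.6 -> 0.3, both E=0.5, AF=1
        f0 = {"up": 1.0, "down": 0.7}
        f1 = {"up": 0.7, "down": 0.85}
        alloc = attribute_lives_saved(1000.0, f0, f1)
        total = 1000.0 * (1.0 - (0.7 / 1.0) * (0.85 / 0.7))
        assert alloc["up"] > 0 > alloc["down"]
        assert sum(alloc.values()) == pytest.approx(total, rel=1e-12)

    def test_unchanged_channels_get_exact_zero(self):
        alloc = attribute_lives_saved(500.0, {"a": 0.8, "b": 0.5}, {"a": 0.4, "b": 0.5})
        assert alloc["b"] == 0.0

    def test_exactly_offsetting_channels_return_zeros(self):
        # log-weights cancel exactly <=> the residual products cancel too,
        # so the zero-weight branch must return an all-zero allocation
        alloc = attribute_lives_saved(1000.0, {"a": 0.5, "b": 0.8}, {"a": 0.8, "b": 0.5})
        assert alloc == {"a": 0.0, "b": 0.0}

    @given(
        st.dictionaries(
            st.sampled_from(list("abcde")),
            st.tuples(st.floats(0.05, 1.0), st.floats(0.05, 1.0)),
            min_size=1,
            max_size=5,
        ),
        st.floats(10.0, 10_000.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_allocations_sum_to_joint_total(self, terms, d0):
        f0 = {ch: a for ch, (a, _) in terms.items()}
        f1 = {ch: b for ch, (_, b) in terms.items()}
        ratio = math.prod(f1[ch] / f0[ch] for ch in f0)
        total = d0 * (1.0 - ratio)
        try:
            alloc = attribute_lives_saved(d0, f0, f1)
        except ConsistencyError:
            return  # hypothesis found exactly-cancelling logs; guarded path
        assert sum(alloc.values()) == pytest.approx(total, rel=1e-9, abs=1e-9)


class TestLivesSaved:
    def test_flat_coverage_saves_exactly_zero(self, three_intervention_profile):
        p = three_intervention_profile
        flat = p.with_coverages(
            CoverageSeries(cs.intervention_id, {2008: cs.value_at(2008)}) for cs in p.coverages
        )
        result = lives_saved(flat, 2008, 2014)
        assert result.grand_total == 0.0
        assert all(v == 0.0 for v in result.ledger.values())

    def test_single_step_closed_form(self, single_intervention_profile):
        result = lives_saved(single_intervention_profile, 2008, 2009)
        assert result.grand_total == pytest.approx(300.0, rel=1e-9)

    def test_falling_coverage_yields_negative_ledger(self):
        p = one_cause_profile(60.6, 50.0)
        result = lives_saved(p, 2008, 2009)
        entries = [v for (ch, _, _), v in result.ledger.items() if ch == "a"]
        assert entries and all(v < 0 for v in entries)

    def test_matches_brute_force_oracle(self, three_intervention_profile):
        result = lives_saved(three_intervention_profile, 2008, 2014)
        oracle = brute_force_averted(three_intervention_profile, 2008, 2014)
        assert result.grand_total == pytest.approx(oracle, rel=1e-9)

    def test_per_cell_attribution_conserves(self, three_intervention_profile):
        # allocations summed over channels equal the joint per-(year, band)
        # deaths-averted figure derived from the scenario deaths
        result = lives_saved(three_intervention_profile, 2008, 2014)
        for (year, band), deaths in result.deaths_by_band_year.items():
            joint = result.baseline_by_band_year[(year, band)] - deaths
            alloc = sum(v for (ch, y, b), v in result.ledger.items() if y == year and b == band)
            assert alloc == pytest.approx(joint, rel=1e-9, abs=1e-9)

    def test_averted_never_exceeds_baseline(self, three_intervention_profile):
        result = lives_saved(three_intervention_profile, 2008, 2014)
        for (year, band), deaths in result.deaths_by_band_year.items():
            averted = result.baseline_by_band_year[(year, band)] - deaths
            assert averted <= result.baseline_by_band_year[(year, band)] + 1e-9

    @given(c1=st.floats(0.0, 100.0), c1_alt=st.floats(0.0, 100.0))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_endline_anchor(self, c1, c1_alt):
        lo, hi = sorted((c1, c1_alt))
        total_lo = lives_saved(one_cause_profile(30.0, lo), 2008, 2009).grand_total
        total_hi = lives_saved(one_cause_profile(30.0, hi), 2008, 2009).grand_total
        assert total_hi >= total_lo - 1e-9

    @given(c0=st.floats(0.0, 99.0), delta=st.floats(-50.0, 50.0))
    @settings(max_examples=60, derandomize=True)
    def test_sign_follows_coverage_change(self, c0, delta):
        c1 = min(100.0, max(0.0, c0 + delta))
        total = lives_saved(one_cause_profile(c0, c1, E=0.5, AF=0.9), 2008, 2009).grand_total
        if c1 > c0 + 1e-9:
            assert total > 0
        elif c1 < c0 - 1e-9:
            assert total < 0
        elif c1 == c0:
            assert total == 0.0
        # sub-epsilon coverage changes may vanish in float residuals

    def test_direct_entry_vs_intervention_only_populate_disjoint_risk_rows(self):
        from livessaved import RiskFactorSpec
        from dataclasses import replace

        spec = iv("cf", 0.5, {"cause_a": 0.2}, bands=(POSTNEONATAL,))
        cov = CoverageSeries("cf", {2008: 40.0, 2014: 60.0})
        rf = RiskFactorSpec(
            name="wasting",
            prevalence_anchors={2008: 8.6, 2014: 4.7},
            relative_risks={"cause_a": 2.0},
            linked_interventions=(("cf", 0.4),),
        )
        p = make_profile([spec], [cov], risk_factors=[rf], mode="direct_entry")
        direct = lives_saved(p, 2008, 2014)
        interv = lives_saved(replace(p, mode="intervention_only"), 2008, 2014)
        assert "wasting" in direct.totals and "cf:wasting" not in direct.totals
        assert "cf:wasting" in interv.totals and "wasting" not in interv.totals
        assert direct.totals["wasting"] > 0  # falling prevalence saves lives
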