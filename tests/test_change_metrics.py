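"""Percent-change arithmetic, burst detection, per-gene summaries, correlation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import run_pipeline
from panelvar.change_metrics import (
    correlate,
    detect_bursts,
    format_percent,
    monthly_deltas,
    per_gene_change_summary,
    percentage_increase,
    round_half_away,
)
from panelvar.months import MonthKey, month_range
from panelvar.synthetic_fixtures import Event, FixtureSpec, correlated_series, generate


def months_for(values, start=MonthKey(2020, 1)):
    return month_range(start, start.plus(len(values) - 1))


class TestPercentageIncrease:
    def test_identity_is_zero(self):
        assert percentage_increase(42, 42) == 0.0

    def test_zero_start_is_undefined_not_an_error(self):
        assert percentage_increase(0, 10) is None

    @pytest.mark.parametrize("start,end,pct", [
        (7477, 36930, 394),    # +29,453
        (1081, 2001, 85),      # +920
        (208, 521, 150),       # +313
        (462, 667, 44),        # +205
    ])
    def test_reported_integer_percent_after_rounding(self, start, end, pct):
        raw = percentage_increase(start, end)
        assert round_half_away(raw) == pct

    @given(st.integers(1, 10**6), st.integers(0, 10**6))
    @settings(max_examples=200, derandomize=True)
    def test_sign_matches_direction(self, start, end):
        pct = percentage_increase(start, end)
        assert np.sign(pct) == np.sign(end - start)

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.4) == 2

    def test_format_percent_modes(self):
        assert format_percent(466.55) == "467%"
        assert format_percent(466.55, "truncate") == "466%"
        assert format_percent(None) == "NA"


class TestMonthlyDeltas:
    def test_constant_series_is_all_zeros(self):
        values = [50] * 6
        summary = monthly_deltas(months_for(values), values)
        assert summary.monthly_percent_changes == [0.0] * 5
        assert summary.mean == 0.0

    def test_closed_form_geometric_series(self):
        values = [100, 110, 121]
        summary = monthly_deltas(months_for(values), values)
        assert summary.monthly_percent_changes == pytest.approx([10.0, 10.0])
        assert summary.mean == pytest.approx(10.0)

    def test_zero_intermediate_is_undefined_and_excluded(self):
        values = [10, 0, 5]
        summary = monthly_deltas(months_for(values), values)
        assert summary.monthly_percent_changes[0] == -100.0
        assert summary.monthly_percent_changes[1] is None
        assert summary.n_undefined == 1
        assert summary.mean == pytest.approx(-100.0)

    def test_compounding_reconstructs_the_series(self):
        rng = np.random.default_rng(1)
        values = list(np.cumsum(rng.integers(1, 50, size=12)) + 100)
        summary = monthly_deltas(months_for(values), values)
        value = float(values[0])
        rebuilt = [value]
        for pct in summary.monthly_percent_changes:
            value *= 1 + pct / 100.0
            rebuilt.append(value)
        assert rebuilt == pytest.approx([float(v) for v in values])

    def test_endpoint_summary(self):
        values = [100, 150, 300]
        summary = monthly_deltas(months_for(values), values)
        assert summary.absolute_increase == 200
        assert summary.percent_increase == pytest.approx(200.0)

    def test_fewer_than_two_months_is_an_error(self):
        with pytest.raises(ValueError):
            monthly_deltas([MonthKey(2020, 1)], [5])


class TestDetectBursts:
    def test_single_burst_flagged(self):
        changes = [1.0, 2.0, 12.0, 0.0]
        months = months_for([0] * 5)
        report = detect_bursts(months, changes, threshold=5.0)
        assert report.month_keys() == [months[3]]
        assert report.burst_months[0][1] == 12.0

    def test_threshold_is_strict(self):
        months = months_for([0] * 2)
        assert detect_bursts(months, [5.0], threshold=5.0).burst_months == []

    def test_two_sided_catches_declines(self):
        months = months_for([0] * 3)
        report = detect_bursts(months, [-9.0, 1.0], threshold=5.0, two_sided=True)
        assert report.month_keys() == [months[1]]

    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=20),
           st.floats(0, 20), st.floats(0, 20))
    @settings(max_examples=150, derandomize=True)
    def test_monotone_in_threshold(self, changes, t1, t2):
        lo, hi = sorted([t1, t2])
        months = months_for([0] * (len(changes) + 1))
        at_hi = set(detect_bursts(months, changes, threshold=hi).month_keys())
        at_lo = set(detect_bursts(months, changes, threshold=lo).month_keys())
        assert at_hi <= at_lo

    def test_injected_step_is_the_only_burst(self, tmp_path):
        """With baseline growth capped below threshold, only the injected
        P/LP step month is flagged in the diagnostic P/LP series."""
        launch = MonthKey(2019, 1)
        step_month = launch.plus(8)
        spec = FixtureSpec(n_genes=40, n_months=18, launch_month=launch, seed=21,
                           events=[Event(step_month, "plp_step", magnitude=2000)])
        run = run_pipeline(generate(spec, tmp_path / "burst"))
        months, plp = run.joined.plp_series()
        report = detect_bursts(months, monthly_deltas(months, plp), threshold=5.0)
        assert report.month_keys() == [step_month]


class TestPerGeneChangeSummary:
    def test_toy_cohort_statistics(self, tmp_path):
        launch = MonthKey(2022, 1)
        spec = FixtureSpec(n_genes=3, n_months=4, launch_month=launch, seed=2,
                           monthly_growth=0.0, growth_sd=0.0,
                           include_str_entry=False, n_extra_clinvar_genes=0,
                           frac_diagnostic=1.1,  # all diagnostic
                           events=[
                               Event(launch.plus(1), "plp_step",
                                     gene="GENE0000", magnitude=5),
                               Event(launch.plus(2), "plp_decline",
                                     gene="GENE0002", magnitude=2),
                           ])
        run = run_pipeline(generate(spec, tmp_path / "toy"))
        summary = per_gene_change_summary(run.static)
        changes = dict(zip(summary.per_gene["symbol"], summary.per_gene["change"]))
        assert changes == {"GENE0000": 5, "GENE0001": 0, "GENE0002": -2}
        assert summary.mean == pytest.approx(1.0)
        assert summary.median == pytest.approx(0.0)
        assert (summary.min, summary.max) == (-2, 5)
        assert summary.n_zero_change == 1
        assert summary.n_negative_change == 1

    def test_decline_event_recovered_exactly(self, tmp_path):
        launch = MonthKey(2022, 1)
        spec = FixtureSpec(n_genes=5, n_months=6, launch_month=launch, seed=4,
                           monthly_growth=0.0, growth_sd=0.0,
                           frac_diagnostic=1.1,
                           events=[Event(launch.plus(3), "plp_decline",
                                         gene="GENE0001", magnitude=10)])
        run = run_pipeline(generate(spec, tmp_path / "decline"))
        summary = per_gene_change_summary(run.static)
        per = summary.per_gene.set_index("symbol")
        assert per.loc["GENE0001", "change"] == -10

    def test_rankings_match_brute_force_sort(self, standard_run):
        summary = per_gene_change_summary(standard_run.static, top_k=3)
        frame = standard_run.static.frame
        for month, ranked in summary.top_by_month.items():
            sub = frame[(frame["month"] == str(month)) & ~frame["missing"]]
            expected = sorted(
                ((str(r.symbol), int(r.plp_alleles))
                 for r in sub.itertuples(index=False)),
                key=lambda t: (-t[1], t[0]),
            )[:3]
            assert ranked == expected

    def test_dominant_gene_tops_every_month(self, tmp_path):
        """A gene given a huge early step stays top-ranked all window."""
        launch = MonthKey(2020, 1)
        spec = FixtureSpec(n_genes=15, n_months=10, launch_month=launch, seed=6,
                           frac_diagnostic=1.1,
                           events=[Event(launch.plus(1), "plp_step",
                                         gene="GENE0007", magnitude=100000)])
        run = run_pipeline(generate(spec, tmp_path / "dominant"))
        summary = per_gene_change_summary(
            run.static, start=launch.plus(1), end=launch.plus(9))
        assert summary.top_gene_every_month() == "GENE0007"


class TestCorrelate:
    def test_series_with_itself_is_one(self):
        a = [1.0, 3.0, 2.0, 5.0, 4.0]
        assert correlate(a, a) == pytest.approx(1.0)

    def test_anti_linear_is_minus_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [9.0, 7.0, 5.0, 3.0]
        assert correlate(a, b) == pytest.approx(-1.0)

    def test_constant_series_is_undefined(self):
        assert correlate([1, 1, 1], [1, 2, 3]) is None

    def test_symmetric_and_affine_invariant(self):
        a, b = correlated_series(40, 0.5, seed=8)
        r = correlate(a, b)
        assert correlate(b, a) == pytest.approx(r)
        assert correlate(3.0 * a + 7.0, b) == pytest.approx(r)

    def test_planted_correlation_recovered(self):
        a, b = correlated_series(60, 0.9, seed=13)
        assert correlate(a, b) == pytest.approx(0.9, abs=0.08)
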