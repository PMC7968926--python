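"""Ca2+ flux scoring: normalization, event detection, window
proportions, percentile bracketing, and the Wilcoxon tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoquant.errors import DegenerateTraceError, ParameterError
from cytoquant.flux import (
    DepositWindowSet,
    FluxCellSummary,
    detect_flux_events,
    exclude_no_flux_cells,
    flux_pipeline,
    flux_rate,
    normalize_trace,
    percentile_bracket,
    rank_sum_test,
    signed_rank_test,
    total_flux_time,
    validate_threshold,
    window_proportions,
)
from cytoquant.simulate import CalciumSimParams, gen_calcium_traces

from oracles import (
    detect_events_bruteforce,
    rank_sum_exact_p,
    signed_rank_exact_p,
    total_flux_time_bruteforce,
)

DT = 1.7


def make_trace(values, dt=DT, cell_id="c"):
    values = np.asarray(values, dtype=float)
    return normalize_trace(np.arange(len(values)) * dt, values, cell_id)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([10, 20, 30], [0, 50, 100]),
            ([5, 7, 9, 6], [0, 50, 100, 25]),
        ],
    )
    def test_affine_rescale(self, raw, expected):
        nt = make_trace(raw)
        np.testing.assert_allclose(nt.value, expected)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            make_trace([4, 4, 4])

    def test_idempotent(self, rng):
        raw = rng.normal(100, 20, size=60)
        once = make_trace(raw)
        twice = normalize_trace(once.time, once.value)
        np.testing.assert_allclose(once.value, twice.value, atol=1e-12)

    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-1000, max_value=1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_event_count_invariant_under_affine_transform(self, a, b):
        raw = np.array([0, 10, 80, 85, 12, 5, 90, 11, 0, 3.0])
        n0 = len(detect_flux_events(make_trace(raw)))
        n1 = len(detect_flux_events(make_trace(a * raw + b)))
        assert n0 == n1


class TestDetectEvents:
    def test_subthreshold_trace_has_no_events(self):
        # normalization pins the max at 100, so sub-threshold semantics
        # are probed on an already-normalized series
        from cytoquant.flux import NormalizedTrace

        t = np.arange(5) * DT
        trace = NormalizedTrace("c", t, np.array([0.0, 10, 49, 30, 0]))
        assert detect_flux_events(trace) == []

    def test_sustained_plateau_is_single_event(self):
        # a 40 s plateau above threshold counts once, not per-sample;
        # the 100 spike at the start anchors the normalization scale and
        # sits > merge_window away from the plateau
        n_plateau = int(40 / DT)
        values = [100.0] + [0.0] * 15 + [60.0] * n_plateau + [0.0] * 5
        events = detect_flux_events(make_trace(values))
        assert len(events) == 2  # the anchor spike + the plateau
        plateau = events[1]
        assert plateau.t_end - plateau.t_start == pytest.approx((n_plateau - 1) * DT)

    def test_gap_merge_rule(self):
        def pulses(gap_s):
            n_gap = int(round(gap_s / DT))
            vals = (
                [100.0] + [0.0] * 15 + [80.0] * 3 + [0.0] * n_gap
                + [80.0] * 3 + [0.0] * 3
            )
            return make_trace(vals)

        assert len(detect_flux_events(pulses(30))) == 3  # anchor + 2 pulses
        assert len(detect_flux_events(pulses(10))) == 2  # anchor + merged pair

    def test_invalid_threshold_rejected(self):
        nt = make_trace([0, 60, 100])
        with pytest.raises(ParameterError):
            detect_flux_events(nt, threshold=0)
        with pytest.raises(ParameterError):
            detect_flux_events(nt, threshold=101)

    @given(
        values=st.lists(
            st.sampled_from([0.0, 49.0, 50.0, 51.0, 100.0]),
            min_size=2,
            max_size=50,
        ),
        merge_n=st.integers(min_value=1, max_value=20),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_bruteforce_oracle(self, values, merge_n):
        from cytoquant.flux import NormalizedTrace

        t = np.arange(len(values)) * DT
        trace = NormalizedTrace("c", t, np.array(values))
        merge_window = merge_n * DT
        events = detect_flux_events(trace, 50.0, merge_window)
        expected = detect_events_bruteforce(t, values, 50.0, merge_window)
        assert len(events) == len(expected)
        for ev, (i, j) in zip(events, expected):
            assert ev.t_start == pytest.approx(t[i])
            assert ev.t_end == pytest.approx(t[j])
            assert ev.peak_value >= 50.0


class TestRatesAndTimes:
    @pytest.mark.parametrize(
        "n, duration, expected",
        [(0, 900, 0.0), (6, 900, 0.4), (3, 600, 0.3)],
    )
    def test_flux_rate_arithmetic(self, n, duration, expected):
        assert flux_rate(n, duration) == pytest.approx(expected)

    def test_flux_rate_needs_positive_duration(self):
        with pytest.raises(ParameterError):
            flux_rate(3, 0)

    def test_total_flux_time_counts_supra_samples(self):
        from cytoquant.flux import NormalizedTrace

        vals = np.array([0.0] * 5 + [60.0] * 10 + [0.0] * 5)
        trace = NormalizedTrace("c", np.arange(20) * DT, vals)
        assert total_flux_time(trace, 50.0) == pytest.approx(17.0)

    def test_flat_zero_trace_has_zero_flux_time(self):
        from cytoquant.flux import NormalizedTrace

        trace = NormalizedTrace("c", np.arange(10) * DT, np.zeros(10))
        assert total_flux_time(trace, 50.0) == 0.0

    def test_total_flux_time_matches_per_sample_oracle(self, rng):
        from cytoquant.flux import NormalizedTrace

        for _ in range(50):
            vals = rng.uniform(0, 100, size=rng.integers(2, 80))
            trace = NormalizedTrace("c", np.arange(len(vals)) * DT, vals)
            assert total_flux_time(trace, 50.0) == pytest.approx(
                total_flux_time_bruteforce(vals, 50.0, DT)
            )
            assert total_flux_time(trace, 50.0) <= trace.duration


class TestWindowProportions:
    def test_flux_only_inside_windows(self):
        from cytoquant.flux import NormalizedTrace

        t = np.arange(100) * 1.0
        vals = np.zeros(100)
        vals[30:35] = 80.0  # inside [25, 45]
        trace = NormalizedTrace("c", t, vals)
        props = window_proportions(trace, DepositWindowSet((25.0,), 20.0))
        assert props.prop_in > 0
        assert props.prop_out == 0
        assert props.in_defined and props.out_defined

    def test_no_deposits_leaves_prop_in_undefined(self):
        from cytoquant.flux import NormalizedTrace

        t = np.arange(50) * 1.0
        vals = np.zeros(50)
        vals[10:15] = 80.0
        trace = NormalizedTrace("c", t, vals)
        props = window_proportions(trace, DepositWindowSet((), 20.0))
        assert not props.in_defined
        assert np.isnan(props.prop_in)
        assert props.prop_out == pytest.approx(5 / 50)

    def test_coupled_cells_spend_more_window_time_in_flux(self):
        # deposits with guaranteed coupling: the in-window proportion
        # should exceed the out-of-window proportion for nearly all cells
        params = CalciumSimParams(
            n_cells=100, deposits_per_cell=3, coupling_prob=1.0
        )
        table, gt = gen_calcium_traces(params, seed=11)
        wins = 0
        total = 0
        for cell_id, _cond, t, v in table.iter_cells():
            trace = normalize_trace(t, v, cell_id)
            windows = DepositWindowSet(tuple(gt.deposit_times[cell_id]), 20.0)
            props = window_proportions(trace, windows)
            total += 1
            if props.prop_in > props.prop_out:
                wins += 1
        assert wins / total >= 0.9


class TestPercentileBracket:
    def test_linear_interpolation_of_1_to_100(self):
        p_lo, p_hi = percentile_bracket(np.arange(1.0, 101.0), 90, 95)
        assert p_lo == pytest.approx(90.1)
        assert p_hi == pytest.approx(95.05)

    def test_constant_sample_brackets_itself(self):
        p_lo, p_hi = percentile_bracket(np.full(20, 7.0), 90, 95)
        assert (p_lo, p_hi) == (7.0, 7.0)
        assert validate_threshold(7.0, p_lo, p_hi)

    def test_threshold_below_bracket_fails_validation(self):
        p_lo, p_hi = percentile_bracket(np.arange(1.0, 101.0), 90, 95)
        assert not validate_threshold(80.0, p_lo, p_hi)

    def test_matches_bruteforce_sort(self, rng):
        vals = rng.uniform(0, 100, size=500)
        p_lo, p_hi = percentile_bracket(vals, 90, 95)
        s = np.sort(vals)
        # linear interpolation between order statistics, h = (n-1)q
        for q, p in ((0.90, p_lo), (0.95, p_hi)):
            h = (len(s) - 1) * q
            lo = int(np.floor(h))
            expected = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
            assert p == pytest.approx(expected)


class TestExclusion:
    def _summary(self, cid, n_events):
        return FluxCellSummary(
            cell_id=cid, condition="SHH", n_events=n_events,
            flux_rate=n_events / 15, total_flux_time=0.0, duration=900.0,
            prop_flux=0.0, prop_in_windows=float("nan"),
            prop_out_windows=float("nan"), has_deposits=False,
        )

    def test_all_fluxing_cells_retained(self):
        summaries = [self._summary(f"c{i}", 2) for i in range(5)]
        kept, excluded = exclude_no_flux_cells(summaries)
        assert len(kept) == 5 and excluded == []

    def test_silent_cell_reported(self):
        summaries = [self._summary(f"c{i}", i) for i in range(5)]
        kept, excluded = exclude_no_flux_cells(summaries)
        assert len(kept) == 4
        assert excluded == ["c0"]

    def test_empty_input(self):
        assert exclude_no_flux_cells([]) == ([], [])


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_small_samples(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)
        assert res.pvalue == pytest.approx(rank_sum_exact_p([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration(self, rng):
        for _ in range(30):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            res = rank_sum_test(x, y)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(rank_sum_exact_p(x, y), abs=1e-12)

    def test_large_sample_approximation_close_to_exact(self, rng):
        x = rng.normal(0, 1, size=13)
        y = rng.normal(0.5, 1, size=13)
        approx = rank_sum_test(x, y)  # combined n = 26 > 25
        assert approx.method == "approximate"
        assert approx.pvalue == pytest.approx(rank_sum_exact_p(x, y), abs=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            rank_sum_test([], [1.0])


class TestSignedRank:
    def test_all_equal_pairs_degenerate(self):
        res = signed_rank_test([(0.2, 0.2)] * 6)
        assert res.pvalue == 1.0
        assert res.degenerate

    def test_five_positive_pairs(self):
        res = signed_rank_test([(i + 1.0, 0.0) for i in range(5)])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(2 / 32)

    def test_fifteen_positive_pairs_reach_headline_p(self):
        res = signed_rank_test([(i + 1.0, 0.0) for i in range(15)])
        assert res.pvalue == pytest.approx(2 / 2**15)
        assert res.pvalue < 1e-4

    def test_exact_matches_enumeration(self, rng):
        for _ in range(30):
            d = rng.normal(size=rng.integers(1, 10))
            res = signed_rank_test([(float(v), 0.0) for v in d])
            assert res.pvalue == pytest.approx(signed_rank_exact_p(d), abs=1e-12)


class TestFluxPipeline:
    def test_rate_uses_duration_in_minutes(self):
        params = CalciumSimParams(n_cells=4, duration=900.0)
        table, _ = gen_calcium_traces(params, seed=3)
        res = flux_pipeline(table, None)
        for _, row in res.summaries.iterrows():
            assert row["duration"] == pytest.approx(900.0, abs=2.0)
            assert row["flux_rate"] == pytest.approx(
                row["n_events"] / (row["duration"] / 60.0)
            )

    def test_coupled_dataset_yields_small_signed_rank_p(self):
        from cytoquant.simulate import simulate_flux_study

        hits = 0
        for s in range(10):
            table, deposits, _ = simulate_flux_study(seed=500 + s)
            res = flux_pipeline(table, deposits)
            if res.deposit_test.pvalue < 0.01:
                hits += 1
        assert hits >= 9

    def test_percentile_bracket_and_provenance_in_output(self):
        from cytoquant.simulate import simulate_flux_study

        table, deposits, _ = simulate_flux_study(seed=42)
        res = flux_pipeline(table, deposits)
        d = res.tests_dict()
        assert d["config"]["flux_threshold"] == 50.0
        assert "control_percentile_bracket" in d
        assert "rank_sum_condition_contrast" in d
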