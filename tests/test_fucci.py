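import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hypoxiq import fucci
from hypoxiq.config import SimulationConfig
from hypoxiq.synthetic import generate_fucci_traces

GATES = fucci.CellCycleGates(red_high=50.0, green_high=50.0)


def _trace(states_h, frame_h=0.5, mitosis_at_end=False, cell_id=0):
    """Build a trace from (state, hours) segments using canonical levels."""
    levels = {"earlyG1": (10, 10), "G1": (100, 10), "S": (100, 100),
              "G2": (10, 100)}
    red, green = [], []
    for state, hours in states_h:
        n = int(round(hours / frame_h))
        red.extend([levels[state][0]] * n)
        green.extend([levels[state][1]] * n)
    n = len(red)
    mitosis = np.zeros(n, dtype=bool)
    if mitosis_at_end:
        mitosis[-1] = True
    return fucci.FucciTrace(
        cell_id=cell_id,
        time_h=np.arange(n) * frame_h,
        red=np.array(red, float),
        green=np.array(green, float),
        mitosis=mitosis,
        frame_interval_h=frame_h,
    )


class TestClassifyState:
    def test_paper_gating(self):
        assert fucci.classify_state(100, 10, GATES) is fucci.Phase.G1
        assert fucci.classify_state(10, 100, GATES) is fucci.Phase.G2
        assert fucci.classify_state(100, 100, GATES) is fucci.Phase.S
        assert fucci.classify_state(10, 10, GATES) is fucci.Phase.EARLY_G1

    def test_threshold_boundary_is_low(self):
        assert fucci.classify_state(50.0, 50.0, GATES) is fucci.Phase.EARLY_G1

    @given(red=st.floats(0, 1e6), green=st.floats(0, 1e6))
    def test_partitions_intensity_plane(self, red, green):
        state = fucci.classify_state(red, green, GATES)
        assert state in list(fucci.Phase)


class TestCalibrateGates:
    def test_bimodal_mixture_threshold_between_modes(self):
        # oracle: threshold must separate the two log-normal modes with <5%
        # misclassification
        rng = np.random.default_rng(0)
        lo = rng.lognormal(math.log(10), 0.25, 500)
        hi = rng.lognormal(math.log(100), 0.25, 500)
        values = np.concatenate([lo, hi])
        gates = fucci.calibrate_gates(values, values)
        thr = gates.red_high
        mis = (lo > thr).mean() + (hi <= thr).mean()
        assert 10 < thr < 100 and mis < 0.05

    def test_all_zero_channel_fallback(self):
        rng = np.random.default_rng(1)
        good = rng.lognormal(3, 1, 200)
        with pytest.warns(UserWarning, match="not bimodal"):
            gates = fucci.calibrate_gates(np.zeros(200), good)
        assert gates.red_high > 0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        red = np.concatenate(
            [rng.lognormal(2, 0.2, 300), rng.lognormal(5, 0.2, 300)]
        )
        green = np.concatenate(
            [rng.lognormal(1, 0.2, 300), rng.lognormal(4, 0.2, 300)]
        )
        g1 = fucci.calibrate_gates(red, green)
        g2 = fucci.calibrate_gates(red * 10, green * 10)
        assert g2.red_high == pytest.approx(10 * g1.red_high, rel=0.05)
        assert g2.green_high == pytest.approx(10 * g1.green_high, rel=0.05)

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError, match="100"):
            fucci.calibrate_gates(np.ones(50), np.ones(50))


class TestTraceDurations:
    def test_stall_rule_30h_red(self):
        trace = _trace([("G1", 30.0)])
        result = fucci.trace_durations(trace, GATES)
        assert result.status is fucci.CyclingStatus.NONCYCLING_STALL

    def test_slip_rule_green_to_red_without_mitosis(self):
        trace = _trace([("S", 4.0), ("G2", 4.0), ("G1", 6.0)])
        result = fucci.trace_durations(trace, GATES)
        assert result.status is fucci.CyclingStatus.NONCYCLING_SLIP

    def test_green_to_red_with_mitosis_is_cycling(self):
        trace = _trace(
            [("earlyG1", 2), ("G1", 8), ("S", 7), ("G2", 3)],
            mitosis_at_end=True,
        )
        result = fucci.trace_durations(trace, GATES)
        assert result.status is fucci.CyclingStatus.CYCLING
        assert result.total_h == pytest.approx(20.0, abs=0.5)
        assert result.durations_h["G1"] == pytest.approx(8.0, abs=0.5)

    def test_short_incomplete_trace_censored(self):
        trace = _trace([("earlyG1", 2), ("G1", 8)])
        result = fucci.trace_durations(trace, GATES)
        assert result.status is fucci.CyclingStatus.CENSORED

    def test_strict_movie_end_stalls_incomplete(self):
        trace = _trace([("earlyG1", 2), ("G1", 8)])
        result = fucci.trace_durations(trace, GATES, strict_movie_end=True)
        assert result.status is fucci.CyclingStatus.NONCYCLING_STALL

    def test_majority_filter_suppresses_flicker(self):
        trace = _trace(
            [("earlyG1", 2), ("G1", 8), ("S", 7), ("G2", 3)],
            mitosis_at_end=True,
        )
        # inject a single-frame artifact inside G1
        trace.red[8] = 10.0
        result = fucci.trace_durations(trace, GATES)
        assert result.status is fucci.CyclingStatus.CYCLING
        assert result.durations_h["G1"] == pytest.approx(8.0, abs=0.5)

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            fucci.FucciTrace(
                0, [0, 1, 1], [1, 1, 1], [1, 1, 1], [0, 0, 0], 0.5
            )

    def test_closed_loop_label_agreement(self, trace_dataset):
        traces_df, truth, cfg = trace_dataset
        gates = fucci.calibrate_gates(
            traces_df["red"].to_numpy(), traces_df["green"].to_numpy()
        )
        results = {
            t.cell_id: fucci.trace_durations(t, gates)
            for t in fucci.traces_from_frame(traces_df, cfg.frame_interval_h)
        }
        agree = np.mean(
            [
                (results[r.cell_id].status is fucci.CyclingStatus.CYCLING)
                == (r.status == "cycling")
                for r in truth.itertuples()
            ]
        )
        assert agree >= 0.99

    def test_closed_loop_duration_within_one_frame(self, trace_dataset):
        traces_df, truth, cfg = trace_dataset
        gates = fucci.calibrate_gates(
            traces_df["red"].to_numpy(), traces_df["green"].to_numpy()
        )
        results = {
            t.cell_id: fucci.trace_durations(t, gates)
            for t in fucci.traces_from_frame(traces_df, cfg.frame_interval_h)
        }
        for row in truth.itertuples():
            r = results[row.cell_id]
            if row.status == "cycling" and r.status is fucci.CyclingStatus.CYCLING:
                assert abs(r.total_h - row.total_h) <= cfg.frame_interval_h

    def test_closed_loop_slip_cells_all_flagged(self, trace_dataset):
        traces_df, truth, cfg = trace_dataset
        gates = fucci.calibrate_gates(
            traces_df["red"].to_numpy(), traces_df["green"].to_numpy()
        )
        results = {
            t.cell_id: fucci.trace_durations(t, gates)
            for t in fucci.traces_from_frame(traces_df, cfg.frame_interval_h)
        }
        slips = truth[truth.status == "noncycling_slip"]
        assert len(slips) > 0
        assert all(
            results[r.cell_id].status is fucci.CyclingStatus.NONCYCLING_SLIP
            for r in slips.itertuples()
        )


class TestCompareDurations:
    def test_identical_groups_h_zero(self):
        h, p = fucci.compare_durations({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert h == 0.0 and p == 1.0

    def test_hand_rank_sum_oracle(self):
        # {1,2,3} vs {4,5,6}: H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 3.857
        h, _ = fucci.compare_durations({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_relabeling_invariance(self):
        g = {"a": [1.0, 3, 5], "b": [2.0, 4, 9], "c": [1.5, 2.5, 8]}
        h1, _ = fucci.compare_durations(g)
        h2, _ = fucci.compare_durations(
            {"x": g["b"], "y": g["c"], "z": g["a"]}
        )
        assert h1 == pytest.approx(h2)

    def test_matches_scipy_kruskal(self):
        rng = np.random.default_rng(3)
        g = {"a": rng.normal(0, 1, 25), "b": rng.normal(1, 1, 25)}
        h, p = fucci.compare_durations(g)
        expected = stats.kruskal(g["a"], g["b"])
        assert h == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)


def _fisher_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p via full table enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    observed = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        prob = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if prob <= observed:
            total += prob
    return total


class TestCyclingAssociation:
    def test_no_association(self):
        odds, p = fucci.cycling_association((5, 5), (5, 5))
        assert p == 1.0 and odds == 1.0

    def test_perfect_association(self):
        _, p = fucci.cycling_association((10, 0), (0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_row_swap_inverts_odds_keeps_p(self):
        o1, p1 = fucci.cycling_association((12, 4), (3, 9))
        o2, p2 = fucci.cycling_association((3, 9), (12, 4))
        assert p1 == pytest.approx(p2)
        assert o1 == pytest.approx(1 / o2)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fucci.cycling_association((0, 0), (3, 4))

    def test_matches_enumeration_oracle_small_tables(self):
        # exhaustive check on all tables with N <= 14 (full sweep of N <= 40
        # lives in the acceptance suite)
        for n in range(2, 15):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        _, p = fucci.cycling_association((a, b), (c, d))
                        oracle = _fisher_oracle(a, b, c, d)
                        assert p == pytest.approx(float(oracle), rel=1e-12)

    def test_matches_scipy_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p = fucci.cycling_association((a, b), (c, d))
            assert p == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-9
            )
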