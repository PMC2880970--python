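import math

import numpy as np
import pytest

from stochtrace import analyze as an
from stochtrace.simulate import TraceSet

from . import _bruteforce as bf
from .conftest import fuzz_traceset, make_trace

ALL_STATS = list(an.STAT_NAMES)


class TestConditionGrammar:
    def test_threshold_comparison(self):
        c = an.parse_condition("S_TF > 600")
        assert c.evaluate({"S_TF": 601}) and not c.evaluate({"S_TF": 600})

    def test_two_species_comparison(self):
        c = an.parse_condition("S_CP < S_TF")
        assert c.evaluate({"S_CP": 1, "S_TF": 2})
        assert not c.evaluate({"S_CP": 2, "S_TF": 2})

    def test_boolean_combinators_and_precedence(self):
        c = an.parse_condition("A > 1 AND B < 2 OR NOT (A = 0)")
        # (A>1 AND B<2) OR NOT(A==0)
        assert c.evaluate({"A": 0, "B": 5}) is False
        assert c.evaluate({"A": 3, "B": 5}) is True

    @pytest.mark.parametrize("bad", ["S_TF >", "> 3", "A AND", "A > (", "A ? 3"])
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(an.ConditionSyntaxError, match="position"):
            an.parse_condition(bad)

    def test_unknown_species_deferred_to_evaluation(self):
        c = an.parse_condition("GHOST > 1")
        with pytest.raises(KeyError):
            c.evaluate({"A": 1})


class TestComputeStat:
    @pytest.mark.parametrize(
        "values, stat, expected",
        [
            ([1, 2, 3, 4], "mean", 2.5),
            ([1, 4], "geometric_mean", 2.0),
            ([3, 4], "rms", math.sqrt(25 / 2)),
            ([1, 2, 3], "skew", 0.0),
            ([1, 2, 3, 4], "variance", 5 / 3),
            ([1, 2, 3, 4], "stddev", math.sqrt(5 / 3)),
            ([1, 2, 3, 4], "stderr", math.sqrt(5 / 3) / 2),
            ([1, 2, 4], "harmonic_mean", 3 / (1 + 0.5 + 0.25)),
        ],
    )
    def test_reference_values(self, values, stat, expected):
        assert an.compute_stat(values, stat) == pytest.approx(expected)

    def test_domain_errors_name_the_statistic(self):
        with pytest.raises(an.StatDomainError, match="harmonic_mean"):
            an.compute_stat([1, 0, 2], "harmonic_mean")
        with pytest.raises(an.StatDomainError, match="variance"):
            an.compute_stat([1], "variance")

    def test_mean_translation_equivariant_rms_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            xs = rng.normal(size=10)
            assert an.compute_stat(xs + 5, "mean") == pytest.approx(
                an.compute_stat(xs, "mean") + 5
            )
            assert an.compute_stat(xs, "rms") >= abs(an.compute_stat(xs, "mean")) - 1e-12
        assert an.compute_stat([3, 3], "rms") == pytest.approx(3.0)

    def test_agrees_with_oracle_on_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            xs = list(rng.integers(1, 50, size=8).astype(float))
            for stat in ALL_STATS:
                if bf.bf_stat_ok(xs, stat):
                    assert an.compute_stat(xs, stat) == pytest.approx(
                        bf.bf_stat(xs, stat), rel=1e-12
                    )


class TestFronts:
    def test_definition_scan(self):
        tr = make_trace([0, 1, 2, 3], {"X": [0, 1, 1, 0]})
        fronts = an.detect_fronts(tr, an.parse_condition("X > 0"))
        assert [(f.t, f.direction) for f in fronts] == [
            (1.0, "ascending"),
            (3.0, "descending"),
        ]

    def test_always_true_yields_no_fronts(self):
        tr = make_trace([0, 1, 2], {"X": [1, 1, 1]})
        assert an.detect_fronts(tr, an.parse_condition("X > 0")) == []

    def test_never_true_yields_no_fronts(self):
        tr = make_trace([0, 1], {"X": [0, 0]})
        assert an.detect_fronts(tr, an.parse_condition("X > 5")) == []

    def test_initial_front_option(self):
        tr = make_trace([0, 1], {"X": [1, 1]})
        fronts = an.detect_fronts(tr, an.parse_condition("X > 0"), initial_front=True)
        assert [(f.t, f.direction) for f in fronts] == [(0.0, "ascending")]

    def test_fronts_alternate(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tr = fuzz_traceset(rng, n_species=1, n_replicas=1).traces[0]
            fronts = an.detect_fronts(tr, an.parse_condition("S0 > 3"))
            for a, b in zip(fronts[:-1], fronts[1:]):
                assert a.direction != b.direction


class TestSeriesAnalyzers:
    def test_constant_replicas_mean_and_variance(self):
        a = make_trace([0, 1, 2], {"S": [2, 2, 2]})
        b = make_trace([0, 0.5, 2.5], {"S": [4, 4, 4]})
        out = an.analyze_series(TraceSet([a, b]), ["S"], ["mean", "variance"])
        mean = next(s for s in out if s.stat == "mean")
        var = next(s for s in out if s.stat == "variance")
        assert (mean.values == 3.0).all()
        assert (var.values == 2.0).all()
        # grid is the union of both time vectors
        assert list(mean.times) == [0.0, 0.5, 1.0, 2.0, 2.5]

    def test_identical_replicas_zero_spread(self):
        tr = make_trace([0, 1, 2], {"S": [1, 5, 2]})
        tr2 = make_trace([0, 1, 2], {"S": [1, 5, 2]})
        out = an.analyze_series(TraceSet([tr, tr2]), ["S"], ["variance", "stddev", "stderr"])
        for s in out:
            assert (s.values == 0.0).all()

    def test_single_replica_mean_is_identity(self):
        tr = make_trace([0, 1, 3], {"S": [2, 7, 1]})
        out = an.analyze_series(TraceSet([tr]), ["S"], ["mean"])[0]
        assert list(out.times) == [0, 1, 3]
        assert list(out.values) == [2, 7, 1]

    def test_pointwise_grid_includes_endpoints(self):
        tr = make_trace([0, 1, 2], {"S": [1, 1, 1]})
        out = an.analyze_pointwise(TraceSet([tr]), ["S"], ["mean"], interval=5.0)[0]
        assert list(out.times) == [0.0, 2.0]

    def test_pointwise_matches_series_where_grids_coincide(self):
        rng = np.random.default_rng(3)
        ts = fuzz_traceset(rng, n_species=1, n_replicas=3)
        series = an.analyze_series(ts, ["S0"], ["mean"])[0]
        pw = an.analyze_pointwise(ts, ["S0"], ["mean"], interval=0.25)[0]
        common = set(series.times) & set(pw.times)
        s_map = dict(zip(series.times, series.values))
        p_map = dict(zip(pw.times, pw.values))
        assert common
        for t in common:
            assert s_map[t] == pytest.approx(p_map[t], rel=1e-12)


class TestFirstHitting:
    def test_mean_at_mean_hit_time(self):
        a = make_trace([0, 1], {"S": [0, 10]})
        b = make_trace([0, 3], {"S": [0, 12]})
        res = an.analyze_first_hitting(
            TraceSet([a, b]), ["S"], ["mean"], an.parse_condition("S > 5")
        )[0]
        assert res.stats["mean"] == pytest.approx(11.0)
        assert res.plotted_at == pytest.approx(2.0)
        assert res.hit_times == [1.0, 3.0]

    def test_condition_true_at_start(self):
        a = make_trace([0, 1], {"S": [9, 1]})
        res = an.analyze_first_hitting(
            TraceSet([a]), ["S"], ["mean"], an.parse_condition("S > 5")
        )[0]
        assert res.hit_times == [0.0]

    def test_never_hitting_runs_counted_not_errored(self):
        a = make_trace([0, 1], {"S": [0, 1]})
        res = an.analyze_first_hitting(
            TraceSet([a]), ["S"], ["mean"], an.parse_condition("S > 99")
        )[0]
        assert res.n_runs_used == 0 and res.n_runs_excluded == 1
        assert res.hit_times == [] and res.plotted_at is None


class TestSteadyState:
    def test_constant_after_transient_any_seed(self):
        tr = make_trace([0, 1, 2, 3, 4], {"S": [9, 5, 5, 5, 5]})
        ts = TraceSet([tr, tr])
        for seed in (0, 1, 2):
            out = an.analyze_steady_state(ts, ["S"], ["mean"], transient=0.5, seed=seed)
            assert out["S"]["mean"] == 5.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        ts = fuzz_traceset(rng, n_species=1, n_replicas=4)
        a = an.analyze_steady_state(ts, ["S0"], ["mean"], transient=1.0, seed=9)
        b = an.analyze_steady_state(ts, ["S0"], ["mean"], transient=1.0, seed=9)
        assert a == b

    def test_short_run_excluded_with_warning(self):
        long = make_trace([0, 1, 5], {"S": [1, 2, 3]})
        short = make_trace([0, 0.5], {"S": [7, 7]})
        with pytest.warns(UserWarning, match="transient"):
            out = an.analyze_steady_state(
                TraceSet([long, short]), ["S"], ["mean"], transient=2.0, seed=0
            )
        assert out["S"]["mean"] == 3.0

    def test_sampled_indices_uniform_chi_square(self):
        # one run with 8 post-transient timestamps; sampling across seeds
        # should hit each index uniformly
        from scipy.stats import chisquare

        tr = make_trace(np.arange(9, dtype=float), {"S": np.arange(9.0)})
        ts = TraceSet([tr])
        counts = np.zeros(8)
        n = 10**4
        for seed in range(n):
            out = an.analyze_steady_state(ts, ["S"], ["mean"], transient=0.5, seed=seed)
            counts[int(out["S"]["mean"]) - 1] += 1
        res = chisquare(counts)
        assert res.pvalue > 0.01


class TestCumulative:
    def test_hand_integral(self):
        # ZOH trace: 2 on [0,1), 4 on [1,3); condition always true
        tr = make_trace([0, 1, 3], {"S": [2, 4, 4]})
        res = an.analyze_cumulative(TraceSet([tr]), ["S"], an.parse_condition("S > 0"))[0]
        assert res.overall_mean == pytest.approx(10 / 3)
        assert res.overall_max == 4 and res.overall_min == 2

    def test_condition_never_true_empty(self):
        tr = make_trace([0, 1], {"S": [1, 1]})
        res = an.analyze_cumulative(TraceSet([tr]), ["S"], an.parse_condition("S > 5"))[0]
        assert res.intervals == [] and res.overall_mean is None


class TestTimeAnalyzer:
    @staticmethod
    def square_wave(period=10.0, high=5.0, span=50.0):
        times, vals, t, level = [], [], 0.0, 1.0
        while t <= span:
            times.append(t)
            vals.append(level)
            level = 0.0 if level == 1.0 else 1.0
            t += high
        return make_trace(times, {"X": vals})

    def test_square_wave_periods_and_durations_exact(self):
        ts = TraceSet([self.square_wave()])
        cond = an.parse_condition("X > 0")
        periods = an.analyze_time(ts, cond, "between_ascending")[0].durations
        assert periods and all(p == 10.0 for p in periods)
        trues = an.analyze_time(ts, cond, "true_intervals")[0].durations
        assert trues and all(d == 5.0 for d in trues)

    def test_always_true_time_sum_is_span(self):
        tr = make_trace([0, 4, 10], {"X": [1, 2, 3]})
        out = an.analyze_time(TraceSet([tr]), an.parse_condition("X > 0"), "time_sum")
        assert out[0].durations == [10.0]

    def test_no_fronts_empty(self):
        tr = make_trace([0, 1], {"X": [0, 0]})
        out = an.analyze_time(TraceSet([tr]), an.parse_condition("X > 0"))
        assert out[0].durations == []

    def test_durations_within_span(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ts = fuzz_traceset(rng, n_species=1)
            for r in an.analyze_time(ts, an.parse_condition("S0 > 3")):
                span = ts.traces[r.replica].t_last - ts.traces[r.replica].t_first
                assert sum(r.durations) <= span + 1e-9


class TestRaw:
    def test_passthrough_bit_identical(self):
        rng = np.random.default_rng(6)
        ts = fuzz_traceset(rng, n_species=2, n_replicas=3)
        out = an.analyze_raw(ts, ["S0", "S1"])
        assert len(out) == 6
        for s in out:
            ri = int(s.label.split()[-1])
            tr = ts.traces[ri]
            assert np.array_equal(s.times, tr.times)
            assert np.array_equal(s.values, tr.column(s.species))


def _assert_close(a, b, what):
    if a is None or b is None:
        assert a == b, what
        return
    assert a == pytest.approx(b, rel=1e-12, abs=1e-12), what


class TestOracleEquivalence:
    """All seven analyzers against plain-loop reimplementations from the
    definitions, on fuzzed replica sets."""

    def test_all_analyzers_match_bruteforce(self):
        rng = np.random.default_rng(7)
        cond = an.parse_condition("S0 > 3 OR S1 = 0")
        stats = ["mean", "rms", "variance", "stddev", "stderr", "skew", "kurtosis"]
        for trial in range(15):
            ts = fuzz_traceset(rng, n_species=2, n_replicas=int(rng.integers(2, 5)))

            grid = bf.bf_series_grid(ts)
            expected = bf.bf_stats_on_grid(ts, "S0", stats, grid)
            got = an.analyze_series(ts, ["S0"], stats)
            for s in got:
                exp = expected[s.stat]
                assert len(s.points) == len(exp)
                for (t, v, _), (te, ve) in zip(s.points, exp):
                    _assert_close(t, te, f"series {s.stat} time")
                    _assert_close(v, ve, f"series {s.stat} value")

            pw_grid = bf.bf_pointwise_grid(ts, 0.7)
            expected = bf.bf_stats_on_grid(ts, "S0", ["mean"], pw_grid)["mean"]
            got_pw = an.analyze_pointwise(ts, ["S0"], ["mean"], 0.7)[0]
            assert len(got_pw.points) == len(expected)
            for (t, v, _), (te, ve) in zip(got_pw.points, expected):
                _assert_close(v, ve, "pointwise value")

            exp_fh = bf.bf_first_hitting(ts, ["S0"], ["mean"], cond)["S0"]
            got_fh = an.analyze_first_hitting(ts, ["S0"], ["mean"], cond)[0]
            assert got_fh.hit_times == exp_fh["times"]
            assert got_fh.n_runs_used == exp_fh["n_used"]
            _assert_close(got_fh.plotted_at, exp_fh["plotted_at"], "fh plotted_at")
            for k, v in exp_fh["stats"].items():
                _assert_close(got_fh.stats[k], v, f"fh stat {k}")

            exp_ss = bf.bf_steady_state(ts, ["S0"], ["mean"], 1.0, seed=trial)
            got_ss = an.analyze_steady_state(ts, ["S0"], ["mean"], 1.0, seed=trial)
            for k, v in exp_ss["S0"].items():
                _assert_close(got_ss["S0"][k], v, f"ss stat {k}")

            exp_cum = bf.bf_cumulative(ts, ["S0"], cond)
            got_cum = an.analyze_cumulative(ts, ["S0"], cond)
            assert len(exp_cum) == len(got_cum)
            for e, g in zip(exp_cum, got_cum):
                _assert_close(g.overall_mean, e["overall_mean"], "cum mean")
                _assert_close(g.overall_max, e["overall_max"], "cum max")
                _assert_close(g.overall_min, e["overall_min"], "cum min")
                assert len(g.intervals) == len(e["intervals"])
                for gi, ei in zip(g.intervals, e["intervals"]):
                    _assert_close(gi.v_mean, ei["mean"], "interval mean")

            for mode in ("between_ascending", "true_intervals", "time_sum"):
                exp_t = bf.bf_time(ts, cond, mode)
                got_t = an.analyze_time(ts, cond, mode)
                for e, g in zip(exp_t, got_t):
                    assert len(e) == len(g.durations)
                    for ev, gv in zip(e, g.durations):
                        _assert_close(gv, ev, f"time {mode}")

            got_raw = an.analyze_raw(ts, ["S0"])
            for ri, s in enumerate(got_raw):
                assert np.array_equal(s.times, ts.traces[ri].times)
                assert np.array_equal(s.values, ts.traces[ri].column("S0"))
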