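"""Engine-level determinism, summaries, comparisons, and the grid."""

import numpy as np
import pytest

from opioidsim import (DiversionLedger, ModelParams, RunConfig, RunResult,
                       ScenarioConfig, SensitivityConfig, compare_scenarios,
                       cumulative_curves, run_experiment_grid, run_simulation,
                       scenario_by_name, summarize_runs)
from opioidsim.engine import MetricSummary, SummaryStats


def fake_result(run_id, fatal_total, od_total=None, n_days=10):
    """Synthetic RunResult with the given cumulative counts."""
    od_total = fatal_total if od_total is None else od_total
    daily_f = np.zeros(n_days, dtype=np.int32)
    daily_o = np.zeros(n_days, dtype=np.int32)
    daily_f[0] = fatal_total
    daily_o[0] = od_total
    return RunResult(run_id=run_id, n_agents=10_000, years=5,
                     daily_overdoses=daily_o, daily_fatal=daily_f,
                     ever_diverted_users=0, sharer_degrees=[],
                     ledger=DiversionLedger(), stock_total=0)


class TestDeterminism:
    def test_identical_seeds_identical_results(self):
        cfg = RunConfig(n_runs=1, n_agents=2_000, years=1, base_seed=33)
        a = run_simulation(scenario_by_name("status_quo"),
                           SensitivityConfig("none"), cfg, 0)
        b = run_simulation(scenario_by_name("status_quo"),
                           SensitivityConfig("none"), cfg, 0)
        assert np.array_equal(a.daily_overdoses, b.daily_overdoses)
        assert np.array_equal(a.daily_fatal, b.daily_fatal)
        assert a.ledger == b.ledger
        assert a.sharer_degrees == b.sharer_degrees
        assert a.ever_diverted_users == b.ever_diverted_users

    def test_zero_years_empty_series(self):
        cfg = RunConfig(n_runs=1, n_agents=500, years=0, base_seed=1)
        r = run_simulation(scenario_by_name("status_quo"),
                           SensitivityConfig("none"), cfg)
        assert len(r.daily_overdoses) == 0
        assert r.total_overdoses == 0 and r.fatal_overdoses == 0

    def test_controlled_only_equals_zeroed_status_quo(self):
        # forcing both diversion knobs of the status-quo scenario to zero
        # must reproduce the controlled-only run bit for bit
        cfg = RunConfig(n_runs=1, n_agents=2_000, years=1, base_seed=8)
        zeroed = ScenarioConfig(name="status_quo", p_divert_given_rx=0.0,
                                p_use_diverted_given_oud=0.0)
        a = run_simulation(scenario_by_name("controlled_only"),
                           SensitivityConfig("none"), cfg, 0)
        b = run_simulation(zeroed, SensitivityConfig("none"), cfg, 0)
        assert np.array_equal(a.daily_overdoses, b.daily_overdoses)
        assert np.array_equal(a.daily_fatal, b.daily_fatal)
        assert a.ledger == b.ledger


class TestSummaries:
    def test_degenerate_spread(self):
        results = [fake_result(i, 10) for i in range(100)]
        s = summarize_runs(results, scale_factor=1_050.0)
        assert s.fatal_overdoses.mean == 10_500.0
        assert s.fatal_overdoses.ci_lo == 10_500.0
        assert s.fatal_overdoses.ci_hi == 10_500.0

    def test_percentiles_against_brute_force(self):
        # runs with fatal counts 1..100 at scale 1; oracle = manual linear
        # interpolation between order statistics
        results = [fake_result(i, i + 1) for i in range(100)]
        s = summarize_runs(results, scale_factor=1.0)
        vals = np.arange(1, 101, dtype=float)

        def manual_quantile(q):
            h = (len(vals) - 1) * q
            lo, frac = int(np.floor(h)), h - np.floor(h)
            hi = min(lo + 1, len(vals) - 1)
            return vals[lo] * (1 - frac) + vals[hi] * frac

        assert s.fatal_overdoses.mean == pytest.approx(50.5)
        assert s.fatal_overdoses.ci_lo == pytest.approx(manual_quantile(0.05))
        assert s.fatal_overdoses.ci_hi == pytest.approx(manual_quantile(0.95))

    def test_scaling_linearity(self):
        results = [fake_result(i, f) for i, f in enumerate((3, 7, 11, 2))]
        unscaled = summarize_runs(results, scale_factor=1.0)
        scaled = summarize_runs(results, scale_factor=1_050.0)
        for name in ("total_overdoses", "fatal_overdoses"):
            assert getattr(unscaled, name).mean * 1_050 == pytest.approx(
                getattr(scaled, name).mean)
            assert getattr(unscaled, name).ci_hi * 1_050 == pytest.approx(
                getattr(scaled, name).ci_hi)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            summarize_runs([], 1.0)


class TestComparisons:
    def _summary(self, fatal_mean):
        m = MetricSummary(fatal_mean, fatal_mean, fatal_mean)
        return SummaryStats(n_runs=100, scale_factor=1_050.0,
                            total_overdoses=m, fatal_overdoses=m,
                            ever_diverted_users=m)

    def test_averted_fatal_overdoses(self):
        cmp_ = compare_scenarios(self._summary(10_658), self._summary(10_301))
        assert cmp_.averted_count == pytest.approx(357.0)
        assert cmp_.averted_pct == pytest.approx(3.35, abs=0.01)

    def test_additional_fatal_overdoses_negative_sign(self):
        cmp_ = compare_scenarios(self._summary(10_658), self._summary(10_741))
        assert cmp_.averted_count == pytest.approx(-83.0)
        assert cmp_.averted_pct == pytest.approx(-0.78, abs=0.01)

    def test_identical_scenarios(self):
        cmp_ = compare_scenarios(self._summary(5.0), self._summary(5.0))
        assert cmp_.averted_count == 0.0
        assert cmp_.averted_pct == 0.0

    def test_zero_baseline_undefined_percentage(self):
        cmp_ = compare_scenarios(self._summary(0.0), self._summary(1.0))
        assert cmp_.averted_pct is None


class TestCurves:
    def test_zero_overdose_curve_flat(self):
        curve = cumulative_curves([fake_result(0, 0)], 1_050.0)
        assert np.all(curve == 0.0)

    def test_final_point_matches_summary_mean(self):
        results = [fake_result(i, f) for i, f in enumerate((2, 5, 9))]
        curve = cumulative_curves(results, 1_050.0)
        s = summarize_runs(results, 1_050.0)
        assert curve[-1] == pytest.approx(s.fatal_overdoses.mean)
        assert np.all(np.diff(curve) >= 0)


class TestEventLogs:
    def test_logs_consistent_with_counts(self):
        from opioidsim.engine import Simulation
        cfg = RunConfig(n_runs=1, n_agents=5_000, years=2, base_seed=19)
        sim = Simulation(ModelParams(), cfg, run_id=0, log_events=True)
        result = sim.run()
        od = sim.overdose_log()
        ep = sim.episode_log()
        naive = result.ledger.naive_fatal
        assert len(od) + naive == result.total_overdoses
        assert od.fatal.sum() + naive == result.fatal_overdoses
        # reversed implies naloxone available and non-fatal
        assert not ((od["reversed"]) & ~od.naloxone_available).any()
        assert not ((od["reversed"]) & od.fatal).any()
        assert set(ep.modality) <= {"methadone", "buprenorphine",
                                    "naltrexone", "non_pharmacologic"}
        closed = ep[ep.end_day >= 0]
        assert (closed.end_day >= closed.start_day).all()


class TestGrid:
    def test_minimal_grid_one_row(self):
        cfg = RunConfig(n_runs=2, n_agents=400, years=1, base_seed=2)
        table, results = run_experiment_grid(cfg, scenarios=("status_quo",),
                                             sensitivities=("none",))
        assert len(table) == 1
        assert ("none", "status_quo") in results

    def test_full_grid_shape_and_controlled_row_sharing(self):
        cfg = RunConfig(n_runs=2, n_agents=600, years=1, base_seed=2)
        table, results = run_experiment_grid(cfg)
        assert len(table) == 15  # 3 scenarios x (main + 4 sensitivities)
        b_rows = table[table.scenario == "controlled_only"]
        assert b_rows.fatal_mean.nunique() == 1  # byte-identical B rows
        assert b_rows.total_mean.nunique() == 1
        # comparisons only within block, vs that block's status quo
        sq = table[(table.sensitivity == "s3")
                   & (table.scenario == "status_quo")].iloc[0]
        c = table[(table.sensitivity == "s3")
                  & (table.scenario == "increased_diversion")].iloc[0]
        assert c.averted_fatal_vs_status_quo == pytest.approx(
            sq.fatal_mean - c.fatal_mean)
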