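"""Adjusted tables, error factors and the Monte Carlo simulation."""

import numpy as np
import pytest

import ltfbias as lb
from ltfbias.distributions import TruncatedNegBinSpec
from ltfbias.scenarios import Scenario, TrialDraw

from conftest import HIGH


def _draw(ad, id_total, id_never, id_high):
    id_ever = id_total - id_never
    return TrialDraw(ad, id_total, id_never, id_ever, id_high, id_ever - id_high)


class TestAdjustCounts:
    def test_worked_example(self, table):
        # 15 decedents move to the reference cases, 3 to the highest stratum's
        a, b, c, d = lb.adjust_counts(table, _draw(104, 21, 15, 3), HIGH)
        assert (a, b, c, d) == (17, 145, 29, 436)

    def test_all_zero_draw_reproduces_observed_table(self, table):
        assert lb.adjust_counts(table, _draw(0, 0, 0, 0), HIGH) == (14, 148, 14, 451)

    def test_cap_boundary_leaves_only_other_cause_deaths(self, table):
        # moving all 112 living non-cases leaves the 36 deceased-other
        a, b, c, d = lb.adjust_counts(table, _draw(112, 112, 0, 112), HIGH)
        assert b == 36
        assert a == 14 + 112

    def test_row_totals_conserved(self, table):
        draw = _draw(104, 21, 15, 3)
        a, b, c, d = lb.adjust_counts(table, draw, HIGH)
        s = table.stratum(HIGH)
        r = table.reference
        assert a + b == s.cases + s.noncases
        assert c + d == r.cases + r.noncases

    def test_move_exceeding_living_noncases_rejected(self, table):
        with pytest.raises(ValueError, match="living non-cases"):
            lb.adjust_counts(table, _draw(150, 150, 0, 113), HIGH)


class TestErrorFactor:
    def test_no_bias_identity(self):
        assert lb.error_factor(3.05, 3.05) == pytest.approx(1.0)

    def test_worked_example(self, table):
        # direct arithmetic oracle from the adjusted table (17,145,29,436)
        or_obs = lb.crude_odds_ratio(table, HIGH)
        or_adj = (17 / 145) / (29 / 436)
        assert or_adj == pytest.approx(1.7627, abs=1e-4)
        assert lb.error_factor(or_obs, or_adj) == pytest.approx(1.7288, abs=1e-4)

    def test_adjustment_above_observed_gives_factor_below_one(self):
        assert lb.error_factor(3.0, 4.0) < 1.0

    def test_domain(self):
        with pytest.raises(ValueError):
            lb.error_factor(0.0, 1.0)
        with pytest.raises(ValueError):
            lb.error_factor(1.0, -2.0)


class TestRunSimulation:
    def test_reproducible_given_seed(self, table, scenarios):
        r1 = lb.run_simulation(scenarios["1"], table, n_trials=2000, seed=42)
        r2 = lb.run_simulation(scenarios["1"], table, n_trials=2000, seed=42)
        for key in r1.draws:
            assert np.array_equal(r1.draws[key], r2.draws[key])
        assert np.array_equal(r1.or_adjusted, r2.or_adjusted)
        r3 = lb.run_simulation(scenarios["1"], table, n_trials=2000, seed=43)
        assert not np.array_equal(r1.or_adjusted, r3.or_adjusted)

    def test_epsilon_decomposition_identity(self, table, scenarios):
        res = lb.run_simulation(scenarios["1"], table, n_trials=20_000, seed=3)
        np.testing.assert_allclose(
            res.epsilon * res.or_adjusted, res.or_observed, rtol=1e-10
        )

    def test_directional_effect_of_one_sided_moves(self, table, scenarios):
        res = lb.run_simulation(scenarios["1"], table, n_trials=50_000, seed=9)
        d = res.draws
        only_never = (d["id_never"] > 0) & (d["id_high"] == 0)
        assert only_never.any()
        assert np.all(res.or_adjusted[only_never] < res.or_observed)
        only_high = (d["id_high"] > 0) & (d["id_never"] == 0)
        assert only_high.any()
        assert np.all(res.or_adjusted[only_high] > res.or_observed)

    def test_degenerate_scenario_is_exact_no_bias(self, table):
        spec = TruncatedNegBinSpec(0.5, 1, 0, 0)
        scen = Scenario("null", spec, 0.204, 0.75, 0.5, 112, n_trials=500)
        res = lb.run_simulation(scen, table, seed=0)
        assert np.all(res.epsilon == 1.0)
        assert np.all(res.or_adjusted == res.or_observed)

    def test_no_flagged_trials_on_fixture(self, table, scenarios):
        res = lb.run_simulation(scenarios["2"], table, n_trials=50_000, seed=11)
        assert res.n_flagged == 0
        # adjusted cells can never hit zero: cases >= 14 and the highest
        # stratum keeps at least its other-cause deaths
        assert res.adj_cells["noncases_high"].min() >= 36

    def test_differential_b_exceeds_a_twin(self, table, scenarios):
        gm = {}
        for name in ("1", "2"):
            res = lb.run_simulation(scenarios[name], table, n_trials=20_000, seed=5)
            gm[name] = lb.geometric_mean(res.or_adjusted)
        assert gm["2"] > gm["1"]

    def test_records_and_frame_agree(self, table, scenarios):
        res = lb.run_simulation(scenarios["1"], table, n_trials=50, seed=1)
        recs = res.records
        frame = res.to_frame()
        assert len(recs) == len(frame) == 50
        assert recs[7].or_adjusted == pytest.approx(frame["or_adjusted"].iloc[7])
        assert recs[7].draw.id_never == frame["id_never"].iloc[7]

    def test_audit_round_trip(self, table, scenarios, tmp_path):
        res = lb.run_simulation(scenarios["1"], table, n_trials=100, seed=1)
        path = tmp_path / "audit.tsv"
        res.write_audit(path)
        lines = path.read_text().splitlines()
        assert len(lines) == 101  # header + one row per trial
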