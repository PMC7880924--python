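"""Cohort engine: discounting, transition structure, accrual and invariants."""

import numpy as np
import pytest

from stentcea import ModelOptions, ParameterSet, discount_factor, run_cohort, transition_matrix


class TestDiscounting:
    @pytest.mark.parametrize(
        "t,rate,expected",
        [(0, 0.03, 1.0), (1, 0.03, 1 / 1.03), (5, 0.0, 1.0), (2, 0.05, 1.05**-2)],
    )
    def test_values(self, t, rate, expected):
        assert discount_factor(t, rate) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.03)
        with pytest.raises(ValueError):
            discount_factor(1, -0.03)


class TestTransitionMatrix:
    def test_dead_row_absorbing(self, base_params, default_options):
        m = transition_matrix(65, base_params, default_options)
        assert m[2].tolist() == [0.0, 0.0, 1.0]

    def test_additive_rule_well_row(self, base_params):
        opts = ModelOptions(risk_rule="additive")
        m = transition_matrix(65, base_params, opts)
        assert m[0] == pytest.approx([0.9378, 0.0264, 0.0358])

    def test_additive_overflow_names_multiplicative(self):
        p = ParameterSet(p_death_no_stenosis=0.6, p_death_other=0.5)
        with pytest.raises(ValueError, match="multiplicative"):
            transition_matrix(65, p, ModelOptions(risk_rule="additive"))

    @pytest.mark.parametrize("risk_rule", ["multiplicative", "additive"])
    @pytest.mark.parametrize("resolution", ["tunnel", "persistent"])
    @pytest.mark.parametrize("mortality", ["constant", "age-specific"])
    def test_rows_sum_to_one(self, base_params, risk_rule, resolution, mortality):
        opts = ModelOptions(
            risk_rule=risk_rule, stenosis_resolution=resolution, mortality=mortality
        )
        for age in (65, 75, 95):
            m = transition_matrix(age, base_params, opts)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()

    def test_tunnel_returns_survivors_to_well(self, base_params):
        m = transition_matrix(65, base_params, ModelOptions(stenosis_resolution="tunnel"))
        assert m[1, 1] == 0.0
        m = transition_matrix(
            65, base_params, ModelOptions(stenosis_resolution="persistent")
        )
        assert m[1, 0] == 0.0

    def test_age_out_of_range_rejected(self, base_params, default_options):
        with pytest.raises(ValueError):
            transition_matrix(40, base_params, default_options)


class TestRunCohort:
    def test_zero_horizon_accrues_nothing(self, default_options):
        p = ParameterSet(horizon_cycles=0)
        tr = run_cohort([1, 0, 0], p, default_options)
        assert tr.total_cost == 0.0 and tr.total_qalys == 0.0

    def test_all_dead_cohort_accrues_nothing(self, base_params, default_options):
        tr = run_cohort([0, 0, 1], base_params, default_options)
        assert tr.total_cost == 0.0 and tr.total_qalys == 0.0
        assert np.allclose(tr.occupancy[:, 2], 1.0)

    def test_invalid_initial_rejected(self, base_params, default_options):
        with pytest.raises(ValueError):
            run_cohort([0.5, 0.4, 0.2], base_params, default_options)

    def test_degenerate_model_matches_geometric_series(self):
        # no transitions out of the well state, end-of-cycle accrual
        p = ParameterSet(
            p_new_stenosis=0.0,
            p_death_no_stenosis=0.0,
            p_death_other=0.0,
            horizon_cycles=25,
        )
        tr = run_cohort([1, 0, 0], p, ModelOptions(accrual="end"))
        r, u, n = p.discount_rate, p.utility_no_stenosis, p.horizon_cycles
        closed_form = u * sum((1 + r) ** (-t) for t in range(1, n + 1))
        assert tr.total_qalys == pytest.approx(closed_form, abs=1e-10)

    def test_matrix_power_identity(self, base_params, default_options):
        m = transition_matrix(65, base_params, default_options)
        init = np.array([0.7, 0.3, 0.0])
        tr = run_cohort(init, base_params, default_options)
        for k in (1, 5, 10):
            assert np.allclose(tr.occupancy[k], init @ np.linalg.matrix_power(m, k))

    @pytest.mark.parametrize("resolution", ["tunnel", "persistent"])
    def test_survival_strictly_decreasing_with_positive_death_rates(
        self, base_params, resolution
    ):
        opts = ModelOptions(stenosis_resolution=resolution)
        tr = run_cohort([0.8, 0.2, 0.0], base_params, opts)
        survival = 1.0 - tr.occupancy[:, 2]
        assert np.all(np.diff(survival) < 0)
        assert np.all(np.diff(tr.occupancy[:, 2]) >= 0)

    def test_discounted_totals_below_undiscounted(self, base_params, default_options):
        disc = run_cohort([1, 0, 0], base_params, default_options)
        undisc = run_cohort([1, 0, 0], base_params.with_values(discount_rate=0.0), default_options)
        assert disc.total_cost < undisc.total_cost
        assert disc.total_qalys < undisc.total_qalys
        assert undisc.total_qalys <= base_params.horizon_cycles * 0.75

    def test_raising_utility_or_cost_raises_totals(self, base_params, default_options):
        base = run_cohort([0.9, 0.1, 0.0], base_params, default_options)
        for bump in (
            {"utility_no_stenosis": 0.80},
            {"utility_stenosis": 0.74},
        ):
            up = run_cohort([0.9, 0.1, 0.0], base_params.with_values(**bump), default_options)
            assert up.total_qalys >= base.total_qalys
        for bump in ({"yearly_cost_no_stenosis": 6500.0}, {"cost_ptca": 5200.0}):
            up = run_cohort([0.9, 0.1, 0.0], base_params.with_values(**bump), default_options)
            assert up.total_cost >= base.total_cost

    def test_cumulative_totals_nondecreasing(self, base_params, default_options):
        tr = run_cohort([0.9, 0.1, 0.0], base_params, default_options)
        assert np.all(np.diff(tr.cumulative_cost) >= 0)
        assert np.all(np.diff(tr.cumulative_qalys) >= 0)
        assert np.allclose(tr.occupancy.sum(axis=1), 1.0)

    def test_half_cycle_accrual_between_start_and_end(self, base_params):
        init = [0.5, 0.5, 0.0]
        res = {
            accrual: run_cohort(init, base_params, ModelOptions(accrual=accrual)).total_qalys
            for accrual in ("start", "half", "end")
        }
        # later discounting and mortality-averaged occupancy both shrink accrual
        assert res["end"] < res["start"]
        assert res["half"] < res["start"]
        assert res["half"] == pytest.approx(res["end"], rel=0.02)

    def test_trace_frame_columns(self, base_params, default_options):
        frame = run_cohort([1, 0, 0], base_params, default_options).to_frame()
        assert list(frame.columns) == [
            "cycle",
            "age",
            "occ_no_stenosis",
            "occ_stenosis",
            "occ_dead",
            "disc_cost_increment",
            "disc_qaly_increment",
            "cumulative_cost",
            "cumulative_qalys",
        ]
        assert len(frame) == base_params.horizon_cycles + 1
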