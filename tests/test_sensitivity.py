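"""One-way DSA, tornado ordering and probabilistic sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from stentcea import (
    DsaRange,
    ModelOptions,
    ParameterSet,
    default_distributions,
    default_dsa_ranges,
    inmb_ctp_vs_cta,
    one_way_dsa,
    psa,
    tornado,
)
from stentcea.parameters import DistributionSpec, fixed_distributions


class TestOneWayDsa:
    def test_inmb_slope_in_ctp_cost_is_minus_one(self, base_params):
        res = one_way_dsa(DsaRange("cost_ctp", 370.0, 570.0), base_params)
        slopes = np.diff(res.inmb) / np.diff(res.values)
        assert np.allclose(slopes, -1.0, atol=1e-9)

    def test_zero_width_range_is_flat(self, base_params):
        base = base_params.cost_ica
        res = one_way_dsa(DsaRange("cost_ica", base, base), base_params)
        assert np.all(res.inmb == res.inmb[0])

    def test_base_value_reproduces_base_inmb_exactly(self, base_params):
        base = base_params.cost_ctp
        res = one_way_dsa(DsaRange("cost_ctp", base, base, n_points=2), base_params)
        base_inmb = inmb_ctp_vs_cta(base_params).inmb
        assert res.inmb[0] == base_inmb and res.inmb[1] == base_inmb

    def test_unknown_parameter_rejected(self, base_params):
        with pytest.raises(KeyError):
            one_way_dsa(DsaRange("cost_of_coffee", 0.0, 1.0), base_params)

    def test_non_bracketing_range_rejected_unless_flagged(self, base_params):
        with pytest.raises(ValueError, match="bracket"):
            one_way_dsa(DsaRange("cost_ctp", 100.0, 200.0), base_params)
        res = one_way_dsa(
            DsaRange("cost_ctp", 100.0, 200.0, must_bracket=False), base_params
        )
        assert len(res.inmb) == 11

    def test_linked_partner_moves_with_source(self, base_params):
        # cost_ptca drags cost_ptca_delayed at 1.3x while the link is on,
        # so the INMB response differs once the link is cut
        linked = one_way_dsa(DsaRange("cost_ptca", 3678.0, 5678.0, n_points=3), base_params)
        unlinked_params = base_params.with_values(linked_cost_assumption=False)
        unlinked = one_way_dsa(
            DsaRange("cost_ptca", 3678.0, 5678.0, n_points=3), unlinked_params
        )
        assert not np.allclose(linked.inmb, unlinked.inmb)


class TestTornado:
    def test_single_range_single_row(self, base_params):
        t = tornado([DsaRange("cost_ctp", 370.0, 570.0)], base_params)
        assert len(t) == 1
        assert t.loc[0, "span"] == pytest.approx(200.0)

    def test_zero_span_row_sorts_last(self, base_params):
        t = tornado(
            [
                DsaRange("cost_ica", base_params.cost_ica, base_params.cost_ica),
                DsaRange("cost_ctp", 370.0, 570.0),
            ],
            base_params,
        )
        assert t.iloc[-1]["parameter"] == "cost_ica"
        assert t.iloc[-1]["span"] == 0.0

    def test_published_ranges_all_positive(self, base_params):
        t = tornado(default_dsa_ranges(base_params), base_params)
        assert (t["inmb_low"] > 0).all() and (t["inmb_high"] > 0).all()

    def test_deterministic_ordering_with_name_tiebreak(self, base_params):
        t = tornado(default_dsa_ranges(base_params), base_params)
        spans = list(zip(-t["span"], t["parameter"]))
        assert spans == sorted(spans)

    def test_empty_ranges_rejected(self, base_params):
        with pytest.raises(ValueError):
            tornado([], base_params)


class TestPsa:
    def test_zero_variance_reproduces_base_case_bit_exactly(self, base_params):
        from stentcea.pipeline import evaluate_strategies

        base = evaluate_strategies(base_params)
        res = psa(5, seed=3, params=base_params, dists=fixed_distributions(base_params))
        for _, row in res.samples.iterrows():
            assert row["cost_cta"] == base["CTA"].cost
            assert row["qalys_cta"] == base["CTA"].qalys
            assert row["cost_ctp"] == base["CTP"].cost
            assert row["qalys_ctp"] == base["CTP"].qalys

    def test_identical_seed_bit_identical_samples(self, base_params):
        dists = default_distributions(base_params)
        a = psa(50, seed=11, params=base_params, dists=dists)
        b = psa(50, seed=11, params=base_params, dists=dists)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        c = psa(50, seed=12, params=base_params, dists=dists)
        assert not a.samples["inmb"].equals(c.samples["inmb"])

    def test_ceac_at_wtp_zero_is_cost_saving_fraction(self, base_params):
        dists = default_distributions(base_params)
        res = psa(200, seed=5, params=base_params, dists=dists, wtp_grid=[0.0])
        expected = float((res.samples["delta_cost"] < 0).mean())
        assert res.ceac.loc[0, "probability_cost_effective"] == pytest.approx(expected)

    def test_ceac_at_huge_wtp_converges_to_qaly_gain_fraction(self, base_params):
        dists = default_distributions(base_params)
        res = psa(200, seed=5, params=base_params, dists=dists, wtp_grid=[1e12])
        expected = float((res.samples["delta_qalys"] > 0).mean())
        assert res.ceac.loc[0, "probability_cost_effective"] == pytest.approx(expected)

    def test_drawn_values_respect_domains(self, base_params):
        dists = default_distributions(base_params)
        res = psa(100, seed=7, params=base_params, dists=dists)
        s = res.samples
        assert (s[["cost_cta", "cost_ctp", "cost_cta_ctp"]] > 0).all().all()
        assert (s[["qalys_cta", "qalys_ctp", "qalys_cta_ctp"]] >= 0).all().all()
        np.testing.assert_allclose(
            s["inmb"], res.wtp * s["delta_qalys"] - s["delta_cost"]
        )

    def test_invalid_spec_rejected_before_sampling(self, base_params):
        with pytest.raises(KeyError):
            psa(
                5,
                seed=0,
                params=base_params,
                dists={"nonexistent": DistributionSpec("fixed", {"value": 1.0})},
            )
        with pytest.raises(ValueError):
            psa(0, seed=0, params=base_params, dists={})

    def test_undistributed_parameters_held_at_base(self, base_params):
        # only the CTP scan cost varies; every iteration's CTA arm is the base case
        from stentcea.pipeline import evaluate_strategies

        base = evaluate_strategies(base_params)
        dists = {"cost_ctp": DistributionSpec("gamma", {"shape": 25.0, "scale": 470.31 / 25})}
        res = psa(20, seed=2, params=base_params, dists=dists)
        assert (res.samples["cost_cta"] == base["CTA"].cost).all()
        assert res.samples["cost_ctp"].nunique() == 20
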