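"""Consumed-donor / product-formation arithmetic against independent oracles."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nkscreen import (
    ControlSet,
    SimulationConfig,
    build_spectrum,
    consumed_donor,
    join_layout,
    product_formation,
    quantify_plate,
    simulate_plate,
    stoichiometric_ratio,
)
from nkscreen.quantification import QuantificationError, ReactionResult


def oracle_consumed(R, B, S, N):
    """Independent plain-Python evaluation of the consumed-donor formula."""
    raw = 100 - 100 * (R + B + S) / (N + S)
    return min(100.0, max(0.0, raw))


class TestConsumedDonor:
    def test_no_consumption_identity(self):
        assert consumed_donor(60000, ControlSet(N=60000, basal=None, S=0)) == 0.0

    def test_full_depletion_limit(self):
        assert consumed_donor(0, ControlSet(N=60000, basal=None, S=0)) == 100.0

    def test_hand_computed_mixed_case(self):
        # 100 - 100 * 46500 / 60500
        controls = ControlSet(N=60000, basal=59000, S=500)
        assert controls.B == 1000.0
        assert consumed_donor(45000, controls) == pytest.approx(
            100 - 100 * 46500 / 60500
        )
        assert consumed_donor(45000, controls) == pytest.approx(23.14, abs=0.005)

    def test_reaction_brighter_than_negative_clamps_to_zero(self):
        assert consumed_donor(65000, ControlSet(N=60000, basal=None, S=0)) == 0.0

    def test_uninterpretable_plate_is_hard_error(self):
        with pytest.raises(QuantificationError, match="N \\+ S"):
            consumed_donor(0, ControlSet(N=0, basal=None, S=0))

    @settings(derandomize=True, max_examples=200)
    @given(
        R=st.floats(0, 1e6), basal=st.floats(0, 1e6),
        S=st.floats(0, 1e5), N=st.floats(1, 1e6),
    )
    def test_matches_independent_oracle(self, R, basal, S, N):
        controls = ControlSet(N=N, basal=basal, S=S)
        expected = oracle_consumed(R, max(0.0, N - basal), S, N)
        assert consumed_donor(R, controls) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        r1=st.floats(0, 5e5), r2=st.floats(0, 5e5), N=st.floats(1e3, 1e6),
    )
    def test_strictly_decreasing_in_R_on_unclamped_domain(self, r1, r2, N):
        controls = ControlSet(N=N, basal=None, S=0.0)
        lo, hi = sorted((r1, r2))
        # stay below both clamps and beyond float resolution of the quotient
        if hi <= N and hi - lo > N * 1e-9:
            assert consumed_donor(lo, controls) > consumed_donor(hi, controls)


class TestProductFormation:
    @pytest.mark.parametrize(
        "consumed,expected", [(50.0, 60.0), (90.0, 100.0), (0.0, 0.0)]
    )
    def test_scaling_and_clamp(self, consumed, expected):
        assert product_formation(consumed) == expected

    def test_nonpositive_ratio_is_hard_error(self):
        with pytest.raises(QuantificationError):
            product_formation(50.0, donor_substrate_ratio=0.0)

    def test_nondecreasing_in_consumed(self):
        grid = np.linspace(0, 100, 201)
        vals = [product_formation(c) for c in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestStoichiometricRatio:
    def test_standard_setup_rounds_to_1_2(self):
        assert stoichiometric_ratio(400.0, 330.0) == 1.2
        assert stoichiometric_ratio(400.0, 333.0) == 1.2

    def test_two_significant_figures(self):
        assert stoichiometric_ratio(500.0, 333.0) == 1.5
        assert stoichiometric_ratio(100.0, 400.0) == 0.25


class TestQuantifyPlate:
    def test_noiseless_conversion_recovered_in_closed_form(self):
        """80% substrate conversion at 400/333 uM: 66.6% donor consumed,
        79.92% product after the 1.2x multiplier."""
        config = SimulationConfig(
            seed=0, noise_cv=0.0, basal_consumption=0.0, atp_degradation=0.0,
            true_conversion={("E", "dCyd"): 0.8},
        )
        layout, reading, _ = simulate_plate(config, [("E", "dCyd", "ATP")])
        (result,) = quantify_plate(join_layout(reading, layout))
        assert result.consumed_donor_pct == pytest.approx(100 * 0.8 * 333 / 400, abs=1e-9)
        assert result.product_pct == pytest.approx(66.6 * 1.2, abs=1e-9)
        assert result.sd_pct == pytest.approx(0.0, abs=1e-9)

    def test_low_positive_conversion_sets_verify_flag(self):
        config = SimulationConfig(
            seed=0, noise_cv=0.0, true_conversion={("E", "Thd"): 0.07}
        )
        layout, reading, _ = simulate_plate(config, [("E", "Thd", "ATP")])
        (result,) = quantify_plate(join_layout(reading, layout))
        assert 0 < result.product_pct < 10
        assert result.flag_verify

    def test_zero_conversion_is_not_flagged(self):
        config = SimulationConfig(
            seed=0, noise_cv=0.0, basal_consumption=0.0,
            true_conversion={("E", "Urd"): 0.0},
        )
        layout, reading, _ = simulate_plate(config, [("E", "Urd", "ATP")])
        (result,) = quantify_plate(join_layout(reading, layout))
        assert result.product_pct == 0.0
        assert not result.flag_verify

    def test_missing_negative_control_names_group(self, default_plate):
        _, annotated, _ = default_plate
        broken = annotated[annotated.role != "negative_control"]
        with pytest.raises(QuantificationError, match=r"HsdCK.*negative"):
            quantify_plate(broken)

    def test_missing_basal_control_warns_and_zeroes_B(self, default_plate, caplog):
        _, annotated, _ = default_plate
        no_basal = annotated[annotated.role != "basal_control"]
        with caplog.at_level(logging.WARNING, logger="nkscreen"):
            results = quantify_plate(no_basal)
        assert any("basal" in rec.getMessage() for rec in caplog.records)
        # without the B correction the apparent consumption can only grow
        with_basal = {r.substrate: r for r in quantify_plate(annotated)}
        for r in results:
            assert r.consumed_donor_pct >= with_basal[r.substrate].consumed_donor_pct - 1e-9

    def test_quantification_is_idempotent(self, default_plate):
        _, annotated, _ = default_plate
        assert quantify_plate(annotated) == quantify_plate(annotated)


def _result(enzyme, substrate, product_pct, flag=False):
    return ReactionResult(
        enzyme=enzyme, substrate=substrate, donor="ATP", R=1000.0,
        consumed_donor_pct=product_pct / 1.2, product_pct=product_pct,
        n_replicates=3, sd_pct=0.0, flag_verify=flag,
    )


class TestSpectrum:
    def test_full_screen_has_no_missing_cells(self):
        results = [
            _result(e, s, 50.0)
            for e in ("E1", "E2", "E3", "E4")
            for s in (f"sub{i}" for i in range(20))
        ]
        matrix = build_spectrum(results)
        assert matrix.values.shape == (4, 20)
        assert not matrix.values.isna().any().any()

    def test_empty_results_give_empty_matrix(self):
        matrix = build_spectrum([])
        assert matrix.values.shape == (0, 0)

    def test_duplicate_pair_averaged_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="nkscreen"):
            matrix = build_spectrum([_result("E", "s", 40.0), _result("E", "s", 44.0)])
        assert matrix.values.loc["E", "s"] == pytest.approx(42.0)
        assert any("averaging" in rec.getMessage() for rec in caplog.records)
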