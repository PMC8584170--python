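"""Generator ground truth: donor response, mass balance, estimator consistency."""

import numpy as np
import pandas as pd
import pytest

from nkscreen import (
    SimulationConfig,
    default_donor_models,
    join_layout,
    quantify_plate,
    simulate_peak_table,
    simulate_plate,
)
from nkscreen.hplc import RetentionLibrary, annotate_peaks, hplc_consumed_atp, hplc_product
from nkscreen.plate_io import PlateError
from nkscreen.synthetic import (
    DEFAULT_PRODUCTS,
    DEFAULT_RETENTION_TIMES,
    expected_hplc_quantification,
    expected_lum_quantification,
)


class TestDonorModels:
    @pytest.mark.parametrize(
        "donor,rlu_at_500",
        [("ATP", 57892.0), ("dATP", 1128.0), ("GTP", 504.0), ("UTP", 220.0),
         ("CTP", 161.0), ("dGTP", 20.0), ("dCTP", 20.0), ("TTP", 20.0)],
    )
    def test_reference_signal_at_500_uM(self, donor, rlu_at_500):
        model = next(m for m in default_donor_models() if m.donor == donor)
        assert model.rlu(500.0) == pytest.approx(rlu_at_500)
        assert model.rlu(0.0) == 0.0


class TestPlateSimulation:
    def test_no_activity_reactions_equal_negative_controls(self):
        config = SimulationConfig(
            seed=0, noise_cv=0.0, basal_consumption=0.0,
            true_conversion={("E", s): 0.0 for s in ("dCyd", "Thd")},
        )
        layout, reading, _ = simulate_plate(
            config, [("E", "dCyd", "ATP"), ("E", "Thd", "ATP")]
        )
        ann = join_layout(reading, layout)
        reactions = ann[ann.role == "reaction"].rlu.unique()
        negatives = ann[ann.role == "negative_control"].rlu.unique()
        assert set(reactions) == set(negatives)

    def test_full_conversion_mass_balance_residual_67_uM(self):
        """conv=1, 400 uM donor vs 333 uM substrate leaves 67 uM donor."""
        config = SimulationConfig(
            seed=0, noise_cv=0.0, basal_consumption=0.0, atp_degradation=0.0,
            true_conversion={("E", "dCyd"): 1.0},
        )
        layout, reading, truth = simulate_plate(config, [("E", "dCyd", "ATP")])
        slope = config.donor_model("ATP").slope
        ann = join_layout(reading, layout)
        r = ann[ann.role == "reaction"].rlu.iloc[0]
        assert r == pytest.approx(slope * 67.0, rel=1e-12)
        assert truth.residual_frac.iloc[0] == pytest.approx(67.0 / 400.0)

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_plate(SimulationConfig(seed=7))
        b = simulate_plate(SimulationConfig(seed=7))
        assert a[0].wells == b[0].wells
        assert a[1].values == b[1].values
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_over_capacity_screen_errors_with_demand(self):
        screen = [("E", f"sub{i}", "ATP") for i in range(30)]
        config = SimulationConfig(
            seed=0, true_conversion={("E", f"sub{i}"): 0.5 for i in range(30)}
        )
        with pytest.raises(PlateError, match=r"\d+ wells"):
            simulate_plate(config, screen)

    def test_mass_conservation_of_pools(self, default_plate):
        _, _, truth = default_plate
        pool = truth.residual_frac + truth.degraded_frac + (
            1.0 - truth.residual_frac - truth.degraded_frac
        )
        assert np.allclose(pool, 1.0)
        # consumed + basal + degraded + residual account for the whole donor
        assert np.allclose(
            truth.consumed_frac + truth.basal_frac + truth.degraded_frac
            + truth.residual_frac,
            1.0,
        )


class TestEstimatorConsistency:
    """With zero noise, both quantification routes must return the generator's
    own closed-form mass balance exactly."""

    def test_luminescence_route_recovers_closed_form(self):
        config = SimulationConfig(seed=0, noise_cv=0.0)
        layout, reading, truth = simulate_plate(config)
        results = quantify_plate(join_layout(reading, layout))
        by_sub = {r.substrate: r for r in results}
        for _, row in truth.iterrows():
            consumed, product = expected_lum_quantification(
                row.true_conversion, config
            )
            r = by_sub[row.substrate]
            assert r.consumed_donor_pct == pytest.approx(consumed, abs=1e-9)
            assert r.product_pct == pytest.approx(product, abs=1e-9)

    def test_hplc_route_recovers_closed_form(self):
        config = SimulationConfig(seed=0, noise_cv=0.0)
        _, _, truth = simulate_plate(config)
        tables = simulate_peak_table(config, truth)
        library = RetentionLibrary(DEFAULT_RETENTION_TIMES)
        for table, (_, row) in zip(tables, truth.iterrows()):
            labeled = annotate_peaks(table, library)
            consumed, product = expected_hplc_quantification(
                row.true_conversion,
                config,
                amp_is_product=DEFAULT_PRODUCTS[row.substrate] == "AMP",
            )
            assert hplc_consumed_atp(labeled) == pytest.approx(consumed, abs=1e-9)
            assert hplc_product(
                labeled, row.substrate, [DEFAULT_PRODUCTS[row.substrate]]
            ) == pytest.approx(product, abs=1e-9)


class TestPeakTables:
    def _table_for(self, conv, **kwargs):
        config = SimulationConfig(
            seed=0, noise_cv=0.0, true_conversion={("E", "dCyd"): conv}, **kwargs
        )
        _, _, truth = simulate_plate(config, [("E", "dCyd", "ATP")])
        (table,) = simulate_peak_table(config, truth)
        return annotate_peaks(table, RetentionLibrary(DEFAULT_RETENTION_TIMES))

    def test_identity_no_conversion_no_degradation(self):
        table = self._table_for(0.0, basal_consumption=0.0, atp_degradation=0.0)
        assert hplc_consumed_atp(table) == 0.0
        assert table.area_of("ATP") > 0

    def test_half_transferred_donor_reads_fifty_percent(self):
        conv = 0.5 * 400.0 / 333.0  # consumes exactly half the donor
        table = self._table_for(conv, basal_consumption=0.0, atp_degradation=0.0)
        assert hplc_consumed_atp(table) == pytest.approx(50.0, abs=1e-9)

    def test_degradation_appears_as_one_percent_amp(self):
        table = self._table_for(0.0, basal_consumption=0.0, atp_degradation=0.01)
        pool = sum(table.area_of(a) for a in ("ATP", "ADP", "AMP"))
        assert table.area_of("AMP") / pool == pytest.approx(0.01, abs=1e-12)

    def test_adenosine_product_pool_collision_is_rejected(self):
        config = SimulationConfig(
            seed=0, noise_cv=0.0, true_conversion={("E", "Ado"): 0.5}
        )
        _, _, truth = simulate_plate(config, [("E", "Ado", "ATP")])
        with pytest.raises(PlateError, match="not separable"):
            simulate_peak_table(config, truth)


class TestParameterRecovery:
    def test_noisy_recovery_within_five_points(self):
        """At 3% noise and triplicates, product estimates should land within
        5 percentage points of the closed-form truth for >= 95% of pairs."""
        hits = total = 0
        for seed in range(200):
            config = SimulationConfig(seed=seed)
            layout, reading, truth = simulate_plate(config)
            results = quantify_plate(join_layout(reading, layout))
            expected = {
                row.substrate: expected_lum_quantification(row.true_conversion, config)[1]
                for _, row in truth.iterrows()
            }
            for r in results:
                total += 1
                hits += abs(r.product_pct - expected[r.substrate]) <= 5.0
        assert hits / total >= 0.95
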