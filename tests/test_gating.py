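"""Gating: MAD thresholds, well summaries, and the latent-state oracle."""

import numpy as np
import pandas as pd
import pytest

from devtoxglr.gating import (
    compute_plate_thresholds,
    mad_threshold,
    summarize_wells,
)
from devtoxglr.layouts import PlateLayout, make_control_plate
from devtoxglr.simulate import SimConfig, simulate_plate


class TestMadThreshold:
    def test_constant_input_collapses_to_constant(self):
        assert mad_threshold([7.0] * 10, multiplier=5) == 7.0

    def test_hand_computed_raw_mad(self):
        # median 3, raw MAD 1 -> 3 + 5*1
        assert mad_threshold([1, 2, 3, 4, 5], 5, convention="raw") == 8.0

    def test_zero_multiplier_is_median(self):
        assert mad_threshold([1, 2, 3, 4, 100], 0) == 3.0

    def test_scaled_convention_default(self):
        x = [1, 2, 3, 4, 5]
        assert mad_threshold(x, 1) == pytest.approx(3 + 1.4826, rel=1e-4)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            mad_threshold([1.0], 5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mad_threshold([1.0, np.nan, 2.0], 5)


def _cells(rows):
    return pd.DataFrame(rows, columns=["plate", "well", "field", "cell_id",
                                       "sox17", "sox2", "bra"])


def _two_control_layout(plate="p1"):
    wells = pd.DataFrame(
        [
            ("A01", "pluripotent_control", None, np.nan),
            ("A02", "pluripotent_control", None, np.nan),
            ("B01", "endoderm_control", None, np.nan),
            ("B02", "endoderm_control", None, np.nan),
            ("C01", "treatment", "c", 1.0),
        ],
        columns=["well", "role", "chemical_id", "conc_uM"],
    )
    return PlateLayout(plate, wells)


class TestPlateThresholds:
    def test_constant_pluripotent_intensity_gives_constant_threshold(self):
        rows = []
        for w in ("A01", "A02"):
            for i in range(5):
                rows.append(("p1", w, 0, i, 42.0, 10.0 + i, 42.0))
        for w in ("B01", "B02"):
            for i in range(5):
                rows.append(("p1", w, 0, i, 500.0, 7.0, 30.0 + i))
        thr = compute_plate_thresholds(_cells(rows), _two_control_layout())
        assert thr.threshold("p1", "sox17") == 42.0
        assert thr.threshold("p1", "bra") == 42.0
        # SOX2 baseline comes from the endoderm controls, which are constant
        assert thr.threshold("p1", "sox2") == 7.0

    def test_thresholds_are_per_plate(self):
        layouts = [make_control_plate("p1", 4), make_control_plate("p2", 4)]
        c1 = simulate_plate(layouts[0], [], SimConfig(seed=1))
        c2 = simulate_plate(layouts[1], [], SimConfig(seed=2))
        cells = pd.concat([c1, c2], ignore_index=True)
        thr = compute_plate_thresholds(cells, layouts)
        assert thr.threshold("p1", "sox17") != thr.threshold("p2", "sox17")

    def test_missing_control_role_raises(self):
        wells = pd.DataFrame(
            [("A01", "solvent_control", None, np.nan),
             ("A02", "solvent_control", None, np.nan)],
            columns=["well", "role", "chemical_id", "conc_uM"],
        )
        layout = PlateLayout("p1", wells)
        rows = [("p1", "A01", 0, i, 1.0, 1.0, 1.0) for i in range(4)]
        with pytest.raises(ValueError, match="pluripotent_control"):
            compute_plate_thresholds(_cells(rows), layout)


class TestSummarizeWells:
    def _thresholds(self, sox17=100.0, sox2=100.0, bra=100.0):
        from devtoxglr.gating import GateThresholds

        table = pd.DataFrame(
            [("p1", "sox17", "pluripotent_control", 0, 0, 5, sox17),
             ("p1", "sox2", "endoderm_control", 0, 0, 5, sox2),
             ("p1", "bra", "pluripotent_control", 0, 0, 5, bra)],
            columns=["plate", "channel", "baseline_role", "median", "mad",
                     "multiplier", "threshold"],
        )
        return GateThresholds(table)

    def test_percent_responders_and_field_aggregation(self):
        rows = []
        for f in range(5):  # 20 cells per field, 14 positive per field
            for i in range(20):
                sox17 = 200.0 if i < 14 else 50.0
                rows.append(("p1", "A01", f, 20 * f + i, sox17, 1.0, 1.0))
        wells = summarize_wells(_cells(rows), self._thresholds())
        assert wells.loc[0, "cell_count"] == 100
        assert wells.loc[0, "pct_sox17_pos"] == 70.0

    def test_threshold_below_minimum_gives_100pct(self):
        rows = [("p1", "A01", 0, i, 50.0, 1.0, 1.0) for i in range(10)]
        wells = summarize_wells(_cells(rows), self._thresholds(sox17=10.0))
        assert wells.loc[0, "pct_sox17_pos"] == 100.0

    def test_ties_count_negative(self):
        rows = [("p1", "A01", 0, i, 100.0, 1.0, 1.0) for i in range(10)]
        wells = summarize_wells(_cells(rows), self._thresholds(sox17=100.0))
        assert wells.loc[0, "pct_sox17_pos"] == 0.0

    def test_empty_well_flagged(self):
        layout = _two_control_layout()
        rows = []
        for w in ("A01", "A02", "B01", "B02"):  # C01 left empty
            for i in range(3):
                rows.append(("p1", w, 0, i, 50.0, 50.0, 50.0))
        wells = summarize_wells(_cells(rows), self._thresholds(), layout)
        c01 = wells[wells["well"] == "C01"].iloc[0]
        assert c01["cell_count"] == 0
        assert np.isnan(c01["pct_sox17_pos"])

    def test_permutation_invariance(self, screen_cells, screen_layout):
        thr = compute_plate_thresholds(screen_cells, screen_layout)
        a = summarize_wells(screen_cells, thr, screen_layout)
        shuffled = screen_cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = summarize_wells(shuffled, thr, screen_layout)
        pd.testing.assert_frame_equal(a, b)

    def test_multiplier_monotonicity(self, screen_cells, screen_layout):
        """Raising the MAD multiplier never increases any percent responder."""
        prev = None
        for mult in (2.0, 5.0, 8.0):
            thr = compute_plate_thresholds(screen_cells, screen_layout, mult)
            w = summarize_wells(screen_cells, thr, screen_layout)
            cur = w[["pct_sox17_pos", "pct_sox2_pos", "pct_bra_pos"]].to_numpy()
            if prev is not None:
                assert np.all(cur <= prev + 1e-12)
            prev = cur


class TestLatentOracle:
    def test_noiseless_gating_recovers_latent_states_exactly(self):
        """With separated two-spike intensity mixtures the gated percent
        responders equal the latent-state percentages exactly."""
        layout = make_control_plate("p1", wells_per_role=8)
        cfg = SimConfig(seed=17, keep_latent=True).noiseless()
        cells = simulate_plate(layout, [], cfg)
        thr = compute_plate_thresholds(cells, layout)
        wells = summarize_wells(cells, thr, layout).set_index("well")
        latent = 100.0 * cells.groupby("well")["sox17_state"].mean()
        for w, expected in latent.items():
            assert wells.loc[w, "pct_sox17_pos"] == pytest.approx(expected, abs=1e-9)

    def test_default_plate_threshold_separates_components(self, screen_wells,
                                                          screen_layout):
        """Gated endoderm-control %SOX17+ lands within 5 points of the
        generator's baseline differentiation fraction."""
        endo = screen_wells[screen_wells["role"] == "endoderm_control"]
        assert abs(endo["pct_sox17_pos"].mean() - 70.2) < 5.0
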