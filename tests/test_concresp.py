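"""Normalization, curve fitting, AIC selection, hit calling, potency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devtoxglr.concresp import (
    ENDPOINTS,
    ConcentrationResponse,
    acc_hill,
    acc_numeric,
    baseline_cutoff,
    call_hit,
    combined_call,
    gainloss_curve,
    hill_curve,
    normalize,
)

CONCS = 10.0 ** np.linspace(-3, 2.3, 8)  # 8-point series, 1 nM - 200 uM


class TestNormalize:
    def test_baseline_maps_to_zero(self):
        assert normalize(50.0, 50.0) == 0.0

    def test_inverted_loss_reads_positive(self):
        assert normalize(40.0, 50.0, invert=True) == pytest.approx(20.0)

    def test_gain_reads_positive(self):
        assert normalize(75.0, 50.0) == pytest.approx(50.0)

    def test_degenerate_baseline(self):
        with pytest.raises(ValueError, match="bval"):
            normalize(10.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        rval=st.floats(0.1, 1e4),
        bval=st.floats(0.1, 1e4),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_equivariance(self, rval, bval, scale):
        """Multiplying rval and bval by a constant leaves resp unchanged."""
        assert normalize(rval * scale, bval * scale) == pytest.approx(
            normalize(rval, bval), rel=1e-9, abs=1e-9
        )


class TestBaselineCutoff:
    def test_zero_solvent_noise(self):
        bmad, coff = baseline_cutoff([0.0] * 8)
        assert bmad == 0.0 and coff == 0.0

    def test_hand_computed_raw(self):
        bmad, coff = baseline_cutoff([-2, -1, 0, 1, 2], convention="raw")
        assert bmad == 1.0 and coff == 3.0

    def test_too_few_wells(self):
        with pytest.raises(ValueError):
            baseline_cutoff([0.0, 1.0, 2.0])


class TestCurveFitting:
    def test_noiseless_hill_recovered(self):
        resp = hill_curve(np.log10(CONCS), 100.0, 0.0, 1.0)
        res = ConcentrationResponse(CONCS, resp).fit()
        assert res.winner == "hill"
        p = res.winning_fit.params
        assert p["tp"] == pytest.approx(100.0, abs=1e-4)
        assert p["ga"] == pytest.approx(0.0, abs=1e-4)
        assert p["gw"] == pytest.approx(1.0, abs=1e-4)

    def test_null_series_picks_constant(self):
        """AIC prefers the constant model on pure noise (>=95% of 200 draws)."""
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(200):
            conc = np.repeat(CONCS, 4)  # the screen's n = 4 replicate design
            resp = rng.normal(0.0, 3.0, size=conc.size)
            res = ConcentrationResponse(conc, resp).fit(n_starts=1)
            wins += res.winner == "constant"
        assert wins >= 190

    def test_gainloss_beats_hill_on_gainloss_data(self):
        rng = np.random.default_rng(1)
        x = np.log10(np.repeat(CONCS, 4))
        resp = gainloss_curve(x, 90.0, -1.5, 1.5, 1.5, 2.0) + rng.normal(0, 3, x.size)
        res = ConcentrationResponse(np.repeat(CONCS, 4), resp).fit()
        assert res.fits["gainloss"].aic < res.fits["hill"].aic

    def test_distinct_concentration_floor(self):
        with pytest.raises(ValueError, match="distinct"):
            ConcentrationResponse([1, 1, 10, 10, 100], [0, 0, 1, 1, 2])

    def test_summary_and_aic_table(self):
        resp = hill_curve(np.log10(CONCS), 80.0, 0.5, 1.0)
        res = ConcentrationResponse(CONCS, resp, coff=20.0).fit()
        tab = res.aic_table()
        assert tab["winner"].sum() == 1
        assert tab.loc[0, "model"] == res.winner  # sorted by AIC
        text = res.summary()
        assert "hitc=1" in text and "AC50" in text


class TestHillProperties:
    @settings(derandomize=True, max_examples=50)
    @given(
        tp=st.floats(10, 150),
        ga=st.floats(-2, 2),
        gw=st.floats(0.3, 8),
    )
    def test_hill_monotone_nondecreasing(self, tp, ga, gw):
        x = np.linspace(-5, 5, 60)
        y = hill_curve(x, tp, ga, gw)
        assert np.all(np.diff(y) >= -1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        tp=st.floats(20, 150),
        ga=st.floats(-2, 2),
        gw=st.floats(0.3, 8),
        frac=st.floats(0.01, 0.5),
    )
    def test_acc_below_ac50_when_cutoff_below_half_top(self, tp, ga, gw, frac):
        coff = frac * tp
        acc = acc_hill(tp, ga, gw, coff)
        assert acc is not None
        assert acc <= 10.0 ** ga * (1 + 1e-12)


class TestPotency:
    def test_acc_equals_ac50_at_half_top(self):
        assert acc_hill(100.0, 0.0, 1.0, 50.0) == pytest.approx(1.0)

    def test_acc_closed_form_worked_example(self):
        acc = acc_hill(100.0, 0.0, 1.0, 20.3)
        assert acc == pytest.approx(10 ** (-math.log10(100 / 20.3 - 1)), rel=1e-12)
        assert acc == pytest.approx(0.2547, abs=2e-4)

    def test_acc_numeric_matches_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tp = rng.uniform(50, 120)
            ga = rng.uniform(-1, 1)
            gw = rng.uniform(0.5, 6)
            coff = rng.uniform(0.2, 0.8) * tp
            ana = acc_hill(tp, ga, gw, coff)
            num = acc_numeric(lambda x: hill_curve(x, tp, ga, gw), coff, -4, 4)
            assert num == pytest.approx(ana, rel=1e-6)

    def test_acc_numeric_none_when_curve_below_cutoff(self):
        assert acc_numeric(lambda x: hill_curve(x, 10.0, 0.0, 1.0), 50.0, -4, 4) is None


class TestHitCall:
    def _fit(self, resp_fn, coff, n_rep=2, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        conc = np.repeat(CONCS, n_rep)
        resp = resp_fn(np.log10(conc)) + rng.normal(0, noise, conc.size)
        model = ConcentrationResponse(conc, resp, coff=coff)
        return model.fit()

    def test_below_cutoff_is_inactive(self):
        res = self._fit(lambda x: hill_curve(x, 10.0, 0.0, 1.0), coff=50.0)
        assert res.hit.hitc == 0
        assert res.hit.acc_uM is None and res.hit.ac50_uM is None

    def test_active_hill_potencies(self):
        res = self._fit(lambda x: hill_curve(x, 100.0, 0.0, 1.0), coff=50.0)
        assert res.hit.hitc == 1
        assert res.hit.acc_uM == pytest.approx(1.0, rel=1e-3)
        assert res.hit.ac50_uM == pytest.approx(1.0, rel=1e-3)

    def test_constant_winner_blocks_hit(self):
        """Even medians above the cutoff do not hit when the constant wins."""
        conc = np.repeat(CONCS, 2)
        rng = np.random.default_rng(3)
        resp = 30.0 + rng.normal(0, 1.0, conc.size)  # flat but elevated
        res = ConcentrationResponse(conc, resp, coff=5.0).fit(n_starts=1)
        fits = {"constant": res.fits["constant"]}
        h = call_hit(np.log10(conc), resp, fits, "constant", 5.0)
        assert h.hitc == 0

    def test_effect_bands_from_max_med(self):
        res = self._fit(lambda x: hill_curve(x, 93.0, -1.0, 2.0), coff=20.0)
        assert res.hit.effect_band == "high"
        res = self._fit(lambda x: hill_curve(x, 45.0, -1.0, 2.0), coff=20.0)
        assert res.hit.effect_band == "moderate"

    def test_extrapolated_acc_flagged(self):
        # curve crosses the cutoff far below the lowest tested concentration
        res = self._fit(lambda x: hill_curve(x, 100.0, -4.5, 1.0), coff=20.0)
        assert res.hit.hitc == 1
        assert "extrapolated_acc" in res.hit.flags


class TestCombinedCall:
    @pytest.mark.parametrize(
        "h1,h2,expected", [(0, 1, True), (1, 0, True), (1, 1, True), (0, 0, False)]
    )
    def test_or_rule(self, h1, h2, expected):
        from devtoxglr.concresp import HitResult

        def hr(h):
            return HitResult(h, None, None, 0.0, "weak", "constant", 0.0, 1.0)

        assert combined_call(hr(h1), hr(h2)) is expected


class TestEndpointCatalogue:
    def test_six_endpoints_with_registered_names(self):
        assert sorted(ENDPOINTS) == [3093, 3094, 3095, 3096, 3097, 3098]
        assert ENDPOINTS[3093].name.endswith("Sox17_up")
        assert ENDPOINTS[3098].name.endswith("CellCount_dn")

    def test_loss_endpoints_inverted(self):
        inverted = {k for k, e in ENDPOINTS.items() if e.invert}
        assert inverted == {3094, 3098}

    def test_sox2_bra_unnormalized(self):
        assert ENDPOINTS[3095].normalization == "raw"
        assert ENDPOINTS[3096].normalization == "raw"
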