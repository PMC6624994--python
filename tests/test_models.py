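"""The three (RBE_alpha, R_beta) parameterizations: DDM, modified MKM, LEM."""

import math

import numpy as np
import pytest

from herbe import (
    DDMCoefficients,
    LEMTable,
    TissueParams,
    ZStarTable,
    ddm_r_beta,
    ddm_rbe_alpha,
    lem_beta_z,
    lem_r_beta,
    lem_rbe_alpha,
    mkm_r_beta,
    mkm_rbe_alpha,
    model_lq,
    rescale_let,
    single_traversal_dose,
)
from herbe.models import MKMParams


class TestLETRescaling:
    def test_track_segment_is_identity(self):
        assert rescale_let(15.0, mode="track_segment") == 15.0

    def test_clinical_cancellation(self):
        c = DDMCoefficients(let_x=0.4, let_co60=0.4)
        assert rescale_let(15.0, c, mode="clinical") == pytest.approx(15.0)

    def test_clinical_shift(self):
        c = DDMCoefficients(let_x=0.3, let_co60=0.4)
        assert rescale_let(15.0, c, mode="clinical") == pytest.approx(15.1)

    def test_clinical_unconfigured_rejected(self):
        with pytest.raises(ValueError, match="let_x"):
            rescale_let(15.0, mode="clinical")


class TestDDM:
    def test_rbe_alpha_zero_let_identity(self, water2):
        assert ddm_rbe_alpha(0.0, water2) == 1.0

    def test_rbe_alpha_hand_evaluation(self, water2):
        # 1 + (k0 + 1/2) * k1 * 15 * exp(-k2 * 225) with published coefficients
        assert ddm_rbe_alpha(15.0, water2) == pytest.approx(3.958, abs=1e-3)

    def test_rbe_alpha_anticorrelated_with_alpha_beta(self, water2, water10):
        for lstar in (1.0, 15.0, 60.0, 120.0):
            assert ddm_rbe_alpha(lstar, water2) > ddm_rbe_alpha(lstar, water10)

    def test_rbe_alpha_interior_maximum(self, water2):
        """Unique max at L* = 1/sqrt(2 k2) ~ 132.3 keV/um (grid-search oracle)."""
        grid = np.linspace(0.0, 300.0, 6001)
        vals = np.array([ddm_rbe_alpha(l, water2) for l in grid])
        argmax = grid[np.argmax(vals)]
        assert argmax == pytest.approx(1.0 / math.sqrt(2 * 2.858e-5), abs=0.05)
        # unique interior maximum: increasing before, decreasing after
        i = np.argmax(vals)
        assert np.all(np.diff(vals[:i]) > 0) and np.all(np.diff(vals[i + 1:]) < 0)

    @pytest.mark.parametrize(
        "lstar,expected,decimals",
        [(4.0, 0.6, 1), (15.0, 1.0, 1), (150.0, 0.0, None)],
    )
    def test_r_beta_published_values(self, lstar, expected, decimals):
        rb = ddm_r_beta(lstar)
        if decimals is None:
            assert rb == expected
        else:
            assert round(rb, decimals) == expected

    def test_r_beta_maximum_at_b1(self):
        grid = np.linspace(0.0, 100.0, 10001)
        vals = [ddm_r_beta(l) for l in grid]
        assert round(float(grid[np.argmax(vals)])) == 63
        assert max(vals) == pytest.approx(2.66, abs=1e-4)

    def test_r_beta_cutoff_configurable(self):
        c = DDMCoefficients(rbeta_cutoff=200.0)
        assert ddm_r_beta(150.0, c) > 0


class TestMKM:
    def test_zero_z_star(self, water2):
        assert mkm_rbe_alpha(0.0, water2) == 1.0

    def test_unit_slope(self):
        t = TissueParams(0.1, 0.05)  # ratio 2
        assert mkm_rbe_alpha(2.0, t) == pytest.approx(2.0)

    def test_direct_evaluation(self, water10):
        assert mkm_rbe_alpha(1.5, water10) == pytest.approx(1.15)

    def test_r_beta_constant_unity(self):
        assert mkm_r_beta() == 1.0
        assert mkm_r_beta() == mkm_r_beta()  # no state, no tissue dependence


class TestLEM:
    def test_beta_z_arithmetic(self):
        assert lem_beta_z(1.0, 0.4, 6.0) == pytest.approx(0.05)

    def test_beta_z_negative_clamped(self):
        assert lem_beta_z(0.4, 0.9, 6.0) == 0.0
        assert lem_beta_z(0.5, 0.5, 3.0) == 0.0

    def test_beta_z_requires_d_t(self):
        with pytest.raises(ValueError):
            lem_beta_z(1.0, 0.4, float("nan"))

    def test_single_traversal_dose(self):
        assert single_traversal_dose(0.0) == 0.0
        assert single_traversal_dose(15.0, MKMParams(0.3, 3.6)) == pytest.approx(
            0.1602 * 15 / (math.pi * 3.6**2), rel=1e-12
        )
        assert single_traversal_dose(15.0) == pytest.approx(0.0590, abs=1e-4)
        assert single_traversal_dose(30.0) == pytest.approx(
            2 * single_traversal_dose(15.0)
        )

    def test_rbe_alpha_low_dose_limit(self):
        t = TissueParams(0.25, 0.02)
        assert lem_rbe_alpha(0.5, 0.0, t) == pytest.approx(2.0)

    def test_rbe_alpha_direct(self):
        t = TissueParams(0.5, 0.02)
        assert lem_rbe_alpha(1.0, 0.1, t) == pytest.approx(1.9033, abs=1e-4)

    def test_rbe_alpha_decreasing_in_d1(self):
        t = TissueParams(0.5, 0.02)
        d1s = np.linspace(0.0, 2.0, 50)
        vals = [lem_rbe_alpha(1.0, d, t) for d in d1s]
        assert np.all(np.diff(vals) < 0)

    def test_r_beta(self):
        t = TissueParams(0.1, 0.025)
        assert lem_r_beta(0.4, 0.5, 0.0, t) == 0.0
        assert lem_r_beta(0.5, 0.5, 0.025, t) == pytest.approx(1.0)
        assert lem_r_beta(0.4, 0.5, 0.02, t) == pytest.approx(0.512)


class TestModelAdapter:
    def test_ddm_zero_let(self, water2):
        lq = model_lq("ddm", water2, l_star=0.0)
        assert lq.alpha == pytest.approx(water2.alpha_x)
        # R_beta at L*=0 is b0*exp(-(b1/b2)^2) ~ 0.49
        assert lq.beta / water2.beta_x == pytest.approx(0.49, abs=0.01)

    def test_mkm_zero_z_star(self, water2):
        lq = model_lq("mkm", water2, z_star=0.0)
        assert (lq.alpha, lq.beta) == (water2.alpha_x, water2.beta_x)

    def test_lem_photon_like_limit(self, water2):
        lq = model_lq(
            "lem", water2, alpha_z=water2.alpha_x, beta_z=water2.beta_x, d1=0.0
        )
        assert lq.alpha == pytest.approx(water2.alpha_x)
        assert lq.beta == pytest.approx(water2.beta_x)

    def test_missing_inputs_rejected(self, water2):
        with pytest.raises(ValueError, match="ddm requires"):
            model_lq("ddm", water2)
        with pytest.raises(ValueError, match="lem requires"):
            model_lq("lem", water2, alpha_z=0.5)

    def test_unknown_model(self, water2):
        with pytest.raises(ValueError, match="unknown model"):
            model_lq("lemiv", water2, l_star=1.0)

    def test_unit_quality_reduces_closed_form_to_unity(self, water2):
        """All three models at photon-equivalent quality give RBE = 1."""
        from herbe import rbe_closed_form

        for lq in (
            model_lq("mkm", water2, z_star=0.0),
            model_lq(
                "lem", water2, alpha_z=water2.alpha_x, beta_z=water2.beta_x, d1=0.0
            ),
        ):
            pt = rbe_closed_form(
                water2, 2.0, lq.alpha / water2.alpha_x, lq.beta / water2.beta_x
            )
            assert pt.rbe == pytest.approx(1.0, abs=1e-12)


class TestTables:
    def test_zstar_interpolation_and_range_error(self):
        t = ZStarTable(abscissa=[0.0, 10.0, 20.0], z_star_1d=[0.0, 2.0, 3.0])
        assert t(5.0) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="outside table range"):
            t(25.0)

    def test_zstar_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ZStarTable(abscissa=[0.0, 0.0, 1.0], z_star_1d=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match=">= 0"):
            ZStarTable(abscissa=[0.0, 1.0], z_star_1d=[0.0, -1.0])

    def test_lem_table_beta_z_derivation(self):
        t = TissueParams(0.1, 0.05, d_t=8.0)  # s_max = 0.9
        table = LEMTable(abscissa=[0.0, 50.0], alpha_z=[0.1, 0.8], s_max=t.s_max)
        bz = table.beta_z_at(50.0, t)
        assert bz == pytest.approx((0.9 - 0.8) / (2 * 8.0))
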