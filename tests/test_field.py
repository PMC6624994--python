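"""Mixed-field forward biological dose, SOBP optimization, DVH and EUD."""

import numpy as np
import pytest

from herbe import (
    BeamComponent,
    FieldProfile,
    LQPair,
    TissueParams,
    combine_profiles,
    dvh_stats,
    forward_drbe,
    lq_survival,
    isoeffective_photon_dose,
    lq_effect,
    mix_lq,
    optimize_sobp,
    percent_delta,
    pmma_to_wed,
    pristine_profile,
    rbe_closed_form,
    target_eud,
    zstar_fixture,
    BeamSpec,
)
from herbe.models import ddm_r_beta, ddm_rbe_alpha


class TestMixLQ:
    def test_single_component_identity(self):
        out = mix_lq([1.0], [LQPair(0.2, 0.02)])
        assert (out.alpha, out.beta) == (pytest.approx(0.2), pytest.approx(0.02))

    def test_equal_dose_symmetry(self):
        out = mix_lq([1.0, 1.0], [LQPair(0.1, 0.01), LQPair(0.3, 0.01)])
        assert out.alpha == pytest.approx(0.2)
        assert out.beta == pytest.approx(0.01)

    def test_hand_arithmetic(self):
        out = mix_lq([3.0, 1.0], [LQPair(0.1, 0.04), LQPair(0.3, 0.0)])
        assert out.alpha == pytest.approx(0.15)
        assert out.beta == pytest.approx((0.75 * 0.2) ** 2)  # 0.0225

    def test_all_zero_doses_rejected(self):
        with pytest.raises(ValueError):
            mix_lq([0.0, 0.0], [LQPair(0.1, 0.01), LQPair(0.2, 0.01)])


class TestPercentDelta:
    def test_identity_and_ten_percent(self):
        assert np.allclose(percent_delta([1.0, 2.0], [1.0, 2.0]), 0.0)
        assert percent_delta([1.1], [1.0])[0] == pytest.approx(10.0)

    def test_exact_antisymmetry_relation(self):
        a = np.array([1.9, 2.1, 2.4])
        b = np.array([2.0, 2.0, 2.0])
        dab = percent_delta(a, b)
        dba = percent_delta(b, a)
        assert np.allclose((1 + dab / 100) * (1 + dba / 100), 1.0)

    def test_zero_reference_masked(self):
        out = percent_delta([1.0], [0.0])
        assert np.isnan(out[0])


def _flat_profile(dose=2.0, let=15.0, n=11):
    depth = np.linspace(0.0, 10.0, n)
    comp = BeamComponent(
        name="He_primary_and_Z2", dose=np.full(n, dose), let_d=np.full(n, let), z=2
    )
    return FieldProfile(depth=depth, components=[comp])


class TestForward:
    def test_photon_equivalent_field_reduces_to_physical(self, water2):
        """MKM at z* = 0 has (RBE_a, R_b) = (1, 1): D_RBE must equal D."""
        profile = _flat_profile(dose=2.0)
        zt = zstar_fixture([0.0, 100.0], z_sat=0.0)  # identically zero
        report = forward_drbe(profile, "mkm", water2, zstar_table=zt)
        assert np.allclose(report.curves["mkm"].rbe, 1.0, atol=1e-12)
        assert np.allclose(report.curves["mkm"].d_rbe, report.dose)

    def test_constant_let_matches_pointwise_closed_form(self, water2):
        profile = _flat_profile(dose=2.0, let=15.0)
        report = forward_drbe(profile, "ddm", water2)
        expected = rbe_closed_form(
            water2, 2.0, ddm_rbe_alpha(15.0, water2), ddm_r_beta(15.0)
        ).rbe
        assert np.allclose(report.curves["ddm"].rbe, expected, atol=1e-12)

    def test_missing_component_input_named(self, water2):
        profile = _flat_profile()
        with pytest.raises(ValueError, match="He_primary_and_Z2"):
            forward_drbe(profile, "mkm", water2)  # no z_star, no table

    def test_let_mask_below_5pct_of_z2_max(self, water2):
        profile = pristine_profile(BeamSpec(), step=0.2)
        report = forward_drbe(profile, "ddm", water2)
        deep = report.dose < 0.05 * profile.max_z2_dose()
        assert np.all(np.isnan(report.let_d[deep]))
        assert np.all(~np.isnan(report.let_d[~deep]))

    def test_sobp_rbe_rises_with_depth_in_target(self, bio_sobp):
        # qualitative trend: RBE climbs with LET_d across the target (small
        # local wiggles from the weight ripple are tolerated)
        rbe = bio_sobp.report.curves["ddm"].rbe[bio_sobp.target_slice]
        assert rbe[-1] - rbe[0] > 0.5
        assert np.all(np.diff(rbe) > -0.02)


class TestWED:
    @pytest.mark.parametrize(
        "pmma,wed", [(0.0, 0.0), (3.0, 3.495), (8.35, 9.728)]
    )
    def test_multiplicative_factor(self, pmma, wed):
        assert pmma_to_wed(pmma) == pytest.approx(wed, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pmma_to_wed(-1.0)


class TestOptimizer:
    def test_physical_mode_flat(self, sobp_kernels):
        res = optimize_sobp(sobp_kernels, 2.0, (60.0, 100.0), mode="physical")
        d = res.profile.total_dose[res.target_slice]
        rms = np.sqrt(np.mean((d / 2.0 - 1.0) ** 2))
        assert rms < 0.01
        assert np.all(res.weights >= 0)

    def test_biological_mode_qualitative(self, bio_sobp, water2):
        curve = bio_sobp.report.curves["ddm"]
        assert bio_sobp.converged and bio_sobp.iterations < 200
        assert np.all(curve.rbe[bio_sobp.target_slice] > 1.0)
        assert curve.d_rbe[0] < 2.0  # entrance biological dose below prescription

    def test_single_kernel_fixed_point(self, water2):
        """1-D oracle: weight must solve D_RBE(peak; w) = prescription."""
        from scipy.optimize import brentq

        kernel = pristine_profile(BeamSpec(range_w=80.0), step=0.2)
        peak = float(kernel.depth[np.argmax(kernel.total_dose)])
        unit = forward_drbe(kernel, "ddm", water2)
        pk = int(np.argmax(kernel.total_dose))
        prescription = 2.0 * unit.curves["ddm"].d_rbe[pk]

        def peak_drbe(w):
            rep = forward_drbe(combine_profiles([kernel], [w]), "ddm", water2)
            return rep.curves["ddm"].d_rbe[pk]

        res = optimize_sobp(
            [kernel], prescription, (peak - 0.1, peak + 0.1),
            model="ddm", tissue=water2, mode="biological",
        )
        assert peak_drbe(res.weights[0]) == pytest.approx(prescription, rel=1e-3)
        w_oracle = brentq(lambda w: peak_drbe(w) - prescription, 0.1, 50.0)
        assert res.weights[0] == pytest.approx(w_oracle, rel=1e-3)

    def test_uncovered_target_rejected(self, water2):
        from herbe import kernel_library

        kernels = kernel_library(60.0, 80.0, spacing=2.0)
        with pytest.raises(ValueError, match="uncovered"):
            optimize_sobp(kernels, 2.0, (60.0, 120.0), mode="physical")


class TestDVH:
    def test_uniform_dose(self):
        s = dvh_stats(np.full(50, 4.0), prescription=4.0)
        assert s.d50 == s.d5 == s.d95 == 4.0
        assert s.i5 == 0.0

    def test_two_bins(self):
        s = dvh_stats([1.0, 3.0], prescription=2.0)
        assert (s.d50, s.d5, s.d95) == (3.0, 3.0, 1.0)
        assert s.i5 == pytest.approx(1.0)

    def test_linear_ramp(self):
        s = dvh_stats(np.linspace(0.0, 10.0, 1001), prescription=10.0)
        assert s.d5 == pytest.approx(9.5, abs=0.02)
        assert s.d95 == pytest.approx(0.5, abs=0.02)
        assert s.i5 == pytest.approx(0.9, abs=0.005)

    def test_brute_force_equivalence(self):
        """D_x% == largest sample dose with frac(doses >= d) >= x/100."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            doses = rng.gamma(4.0, 0.5, size=rng.integers(3, 200))
            s = dvh_stats(doses)
            for x, got in ((50.0, s.d50), (5.0, s.d5), (95.0, s.d95)):
                cands = [d for d in doses if np.mean(doses >= d) >= x / 100.0]
                assert got == max(cands)

    def test_spread_increases_i5(self):
        flat = dvh_stats(np.full(100, 2.0), prescription=2.0)
        spread = dvh_stats(
            np.concatenate([np.full(50, 1.9), np.full(50, 2.1)]), prescription=2.0
        )
        assert flat.i5 == 0.0
        assert spread.i5 > 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dvh_stats([])

    def test_volume_weights(self):
        # 3 Gy in 10% of volume, 1 Gy in 90%: D_50 must be 1
        s = dvh_stats([3.0, 1.0], volumes=[0.1, 0.9])
        assert s.d50 == 1.0
        assert s.d5 == 3.0


class TestTargetEUD:
    def test_uniform_target_equals_photon_equivalent(self, water2):
        profile = _flat_profile(dose=2.0, let=15.0)
        report = forward_drbe(profile, "ddm", water2)
        got = target_eud(report, water2)
        curve = report.curves["ddm"]
        expected = isoeffective_photon_dose(
            water2, lq_effect(LQPair(curve.alpha_mix[0], curve.beta_mix[0]), 2.0)
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_survival_averaging_convexity(self, water2):
        """Two-voxel mixed target: EUD below the mean of per-voxel doses."""
        n = 2
        depth = np.array([0.0, 1.0])
        comp = BeamComponent(
            name="He_primary_and_Z2",
            dose=np.array([1.0, 3.0]),
            let_d=np.full(n, 15.0),
        )
        report = forward_drbe(
            FieldProfile(depth=depth, components=[comp]), "ddm", water2
        )
        curve = report.curves["ddm"]
        per_voxel = [
            isoeffective_photon_dose(
                water2,
                lq_effect(LQPair(curve.alpha_mix[i], curve.beta_mix[i]),
                          float(report.dose[i])),
            )
            for i in range(n)
        ]
        got = target_eud(report, water2)
        assert got < np.mean(per_voxel)
        assert min(per_voxel) <= got <= max(per_voxel)

    def test_sobp_target_eud_within_voxel_bounds(self, bio_sobp, water2):
        report = bio_sobp.report
        sl = bio_sobp.target_slice
        curve = report.curves["ddm"]
        per_voxel = [
            isoeffective_photon_dose(
                water2,
                lq_effect(LQPair(curve.alpha_mix[i], curve.beta_mix[i]),
                          float(report.dose[i])),
            )
            for i in range(sl.start, sl.stop)
        ]
        got = target_eud(report, water2, target=bio_sobp.target_slice)
        assert min(per_voxel) <= got <= max(per_voxel)


class TestCombine:
    def test_grid_mismatch_rejected(self):
        a = _flat_profile(n=11)
        b = _flat_profile(n=12)
        with pytest.raises(ValueError, match="depth grid"):
            combine_profiles([a, b], [1.0, 1.0])

    def test_dose_additivity_and_let_weighting(self):
        a = _flat_profile(dose=1.0, let=10.0)
        b = _flat_profile(dose=3.0, let=20.0)
        out = combine_profiles([a, b], [1.0, 1.0])
        assert np.allclose(out.total_dose, 4.0)
        assert np.allclose(out.components[0].let_d, (1 * 10 + 3 * 20) / 4.0)
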