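"""Traction cytometry: forward/inverse models, PIV, drift, energy, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from junctionmech import synthetic as syn
from junctionmech import tfm
from junctionmech.errors import (ConfigError, DataError, NormalizationError,
                                 RegistrationError)

from oracle_boussinesq import direct_displacement


def rel_rms(ax, ay, bx, by):
    num = np.sqrt(np.mean((ax - bx) ** 2 + (ay - by) ** 2))
    den = np.sqrt(np.mean(bx ** 2 + by ** 2))
    return num / den


# ---------------------------------------------------------------- forward map
class TestForwardBoussinesq:
    def test_agrees_with_direct_space_oracle(self, smooth_dipole, gel):
        traction = smooth_dipole()
        disp = tfm.forward_boussinesq(traction, gel)
        oracle = direct_displacement(traction, gel.youngs_modulus_pa,
                                     gel.poisson_ratio, sub=3)
        assert rel_rms(disp.u_x, disp.u_y, oracle[0], oracle[1]) <= 0.01

    def test_zero_traction_gives_zero_displacement(self, gel):
        traction = tfm.TractionField(np.zeros((32, 32)), np.zeros((32, 32)))
        disp = tfm.forward_boussinesq(traction, gel)
        assert np.all(disp.u_x == 0) and np.all(disp.u_y == 0)

    def test_doubling_modulus_halves_displacement(self, smooth_dipole):
        traction = smooth_dipole()
        soft = tfm.forward_boussinesq(traction, tfm.GelProperties(8000.0))
        stiff = tfm.forward_boussinesq(traction, tfm.GelProperties(16000.0))
        np.testing.assert_allclose(soft.u_x, 2.0 * stiff.u_x, rtol=1e-12)
        np.testing.assert_allclose(soft.u_y, 2.0 * stiff.u_y, rtol=1e-12)

    def test_linearity_in_traction(self, smooth_dipole, gel):
        traction = smooth_dipole(magnitude_pa=50.0)
        scaled = tfm.TractionField(3.0 * traction.t_x, 3.0 * traction.t_y,
                                   traction.grid_spacing_um)
        u1 = tfm.forward_boussinesq(traction, gel)
        u3 = tfm.forward_boussinesq(scaled, gel)
        np.testing.assert_allclose(u3.u_x, 3.0 * u1.u_x, rtol=1e-10,
                                   atol=1e-15)


class TestFTTCInverse:
    def test_zero_displacement_gives_zero_traction(self, gel):
        disp = tfm.DisplacementField(np.zeros((32, 32)), np.zeros((32, 32)))
        rec = tfm.fttc_inverse(disp, gel)
        assert np.allclose(rec.t_x, 0) and np.allclose(rec.t_y, 0)

    def test_traction_scales_linearly_with_modulus(self, smooth_dipole, gel):
        disp = tfm.forward_boussinesq(smooth_dipole(), gel)
        t1 = tfm.fttc_inverse(disp, tfm.GelProperties(10000.0))
        t2 = tfm.fttc_inverse(disp, tfm.GelProperties(20000.0))
        np.testing.assert_allclose(t2.t_x, 2.0 * t1.t_x, rtol=1e-10,
                                   atol=1e-12)

    def test_displacement_scaling_scales_traction_and_energy(
            self, smooth_dipole, gel):
        disp = tfm.forward_boussinesq(smooth_dipole(), gel)
        c = 2.5
        scaled = tfm.DisplacementField(c * disp.u_x, c * disp.u_y,
                                       disp.grid_spacing_um)
        t1 = tfm.fttc_inverse(disp, gel)
        t2 = tfm.fttc_inverse(scaled, gel)
        np.testing.assert_allclose(t2.t_x, c * t1.t_x, rtol=1e-6, atol=1e-10)
        u1 = tfm.strain_energy(t1, disp)
        u2 = tfm.strain_energy(t2, scaled)
        assert u2 == pytest.approx(c ** 2 * u1, rel=1e-6)

    def test_small_grid_rejected(self, gel):
        disp = tfm.DisplacementField(np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(DataError):
            tfm.fttc_inverse(disp, gel)

    def test_tikhonov_damps_traction(self, smooth_dipole, gel):
        disp = tfm.forward_boussinesq(smooth_dipole(), gel)
        free = tfm.fttc_inverse(disp, gel, regularization=0.0)
        damped = tfm.fttc_inverse(disp, gel, regularization=1e-3)
        assert damped.magnitude().max() < free.magnitude().max()


# -------------------------------------------------------------------- energy
class TestStrainEnergy:
    def test_hand_computed_uniform_field(self):
        # 100 nodes, T = 1 Pa along x, u = 1 um along x, 2.6 um spacing:
        # U = 1/2 * 1 * 1e-6 * 100 * (2.6e-6)^2 = 3.38e-16 J
        t = tfm.TractionField(np.ones((10, 10)), np.zeros((10, 10)), 2.6)
        u = tfm.DisplacementField(np.ones((10, 10)), np.zeros((10, 10)), 2.6)
        assert tfm.strain_energy(t, u) == pytest.approx(3.38e-16, rel=1e-12)

    def test_zero_fields(self):
        t = tfm.TractionField(np.zeros((16, 16)), np.zeros((16, 16)))
        u = tfm.DisplacementField(np.zeros((16, 16)), np.zeros((16, 16)))
        assert tfm.strain_energy(t, u) == 0.0

    def test_grid_mismatch_rejected(self):
        t = tfm.TractionField(np.zeros((16, 16)), np.zeros((16, 16)))
        u = tfm.DisplacementField(np.zeros((20, 20)), np.zeros((20, 20)))
        with pytest.raises(DataError):
            tfm.strain_energy(t, u)

    def test_matches_independent_summation(self, smooth_dipole, gel):
        traction = smooth_dipole()
        disp = tfm.forward_boussinesq(traction, gel)
        expected = 0.5 * np.sum(traction.t_x * disp.u_x * 1e-6
                                + traction.t_y * disp.u_y * 1e-6) * (2.6e-6) ** 2
        assert tfm.strain_energy(traction, disp) == pytest.approx(expected)


class TestEquilibriumRatio:
    def test_identical_vectors_give_one(self):
        t = tfm.TractionField(np.ones((16, 16)), np.ones((16, 16)))
        assert tfm.equilibrium_ratio(t) == pytest.approx(1.0)

    def test_all_zero_is_zero_by_convention(self):
        t = tfm.TractionField(np.zeros((16, 16)), np.zeros((16, 16)))
        assert tfm.equilibrium_ratio(t) == 0.0

    def test_matches_brute_force_summation(self, noiseless_scene, gel):
        scene = noiseless_scene(size=64, seed=7)
        t = syn.make_island_traction(scene, 35.0, 80.0, "random_balanced")
        fx, fy = t.t_x.ravel(), t.t_y.ravel()
        expected = np.hypot(fx.sum(), fy.sum()) / np.hypot(fx, fy).sum()
        assert tfm.equilibrium_ratio(t) == pytest.approx(expected, abs=1e-14)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(0.0, 2 * np.pi))
    def test_invariant_under_global_rotation(self, angle):
        rng = np.random.default_rng(11)
        tx = rng.normal(size=(20, 20))
        ty = rng.normal(size=(20, 20))
        base = tfm.TractionField(tx, ty)
        c, s = np.cos(angle), np.sin(angle)
        rotated = tfm.TractionField(c * tx - s * ty, s * tx + c * ty)
        assert tfm.equilibrium_ratio(rotated) == pytest.approx(
            tfm.equilibrium_ratio(base), abs=1e-12)

    def test_empty_mask_rejected(self):
        t = tfm.TractionField(np.ones((8, 8)), np.ones((8, 8)))
        with pytest.raises(DataError):
            tfm.equilibrium_ratio(t, np.zeros((8, 8), dtype=bool))


# ------------------------------------------------------- drift, PIV, gridding
def _bead_scene(gel, seed=3, drift=(0.0, 0.0), magnitude=0.0, noise=0.02,
                size=320, n_beads=2000):
    scene = syn.SceneParams(image_size_px=(size, size), pixel_size_um=0.65,
                            rng_seed=seed,
                            noise_model=syn.NoiseModel(gaussian_sd=noise))
    traction = syn.make_island_traction(scene, 30.0, magnitude,
                                        "contractile_dipole")
    stressed, relaxed, truth = syn.render_bead_pair(
        traction, gel, scene, n_beads=n_beads, drift_px=drift)
    return stressed, relaxed, truth


class TestCorrectDrift:
    def test_identical_images_give_zero_shift(self, gel):
        stressed, relaxed, _ = _bead_scene(gel)
        pair = tfm.correct_drift(stressed, stressed)
        assert pair.applied_shift_px == (0.0, 0.0)
        assert pair.correlation_peak > 0.9

    def test_recovers_known_subpixel_drift(self, gel):
        stressed, relaxed, _ = _bead_scene(gel, drift=(3.0, -2.0))
        pair = tfm.correct_drift(stressed, relaxed)
        assert pair.applied_shift_px[0] == pytest.approx(3.0, abs=0.1)
        assert pair.applied_shift_px[1] == pytest.approx(-2.0, abs=0.1)

    def test_agrees_with_phase_correlation_oracle(self, gel):
        # independent check via skimage's phase correlation on full frames
        from skimage.registration import phase_cross_correlation
        stressed, relaxed, _ = _bead_scene(gel, drift=(1.5, 2.5))
        pair = tfm.correct_drift(stressed, relaxed)
        shift, _, _ = phase_cross_correlation(stressed, relaxed,
                                              upsample_factor=50)
        np.testing.assert_allclose(pair.applied_shift_px, shift, atol=0.1)

    def test_pure_noise_raises_registration_error(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(128, 128))
        b = rng.normal(size=(128, 128))
        with pytest.raises(RegistrationError):
            tfm.correct_drift(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            tfm.correct_drift(np.zeros((64, 64)), np.zeros((32, 32)))


class TestPIV:
    def test_null_field_measures_no_displacement(self, gel):
        stressed, relaxed, _ = _bead_scene(gel, noise=0.0)
        pair = tfm.MatchedPair(stressed, relaxed, (0.0, 0.0), 1.0)
        samples = tfm.piv_displacements(pair)
        assert len(samples) > 50
        assert np.all(np.hypot(samples[:, 2], samples[:, 3]) <= 0.2)

    def test_rigid_shift_recovered_uniformly(self, gel):
        # drift correction deliberately skipped: PIV sees the raw shift
        stressed, relaxed, _ = _bead_scene(gel, drift=(0.6, -0.4), noise=0.0,
                                           size=256)
        pair = tfm.MatchedPair(stressed, relaxed, (0.0, 0.0), 1.0)
        samples = tfm.piv_displacements(pair, window_px=48)
        assert np.allclose(samples[:, 2], -0.4, atol=0.1)
        assert np.allclose(samples[:, 3], 0.6, atol=0.1)
        # default windows: unbiased in aggregate
        default = tfm.piv_displacements(pair)
        assert np.median(default[:, 2]) == pytest.approx(-0.4, abs=0.02)
        assert np.median(default[:, 3]) == pytest.approx(0.6, abs=0.02)

    def test_window_constraints(self, gel):
        stressed, relaxed, _ = _bead_scene(gel)
        pair = tfm.MatchedPair(stressed, relaxed, (0.0, 0.0), 1.0)
        with pytest.raises(ConfigError):
            tfm.piv_displacements(pair, window_px=8)
        with pytest.raises(DataError):
            tfm.piv_displacements(pair, window_px=512)

    def test_dipole_scene_tracks_ground_truth(self, gel):
        stressed, relaxed, truth = _bead_scene(gel, magnitude=800.0,
                                               size=384, seed=9)
        pair = tfm.MatchedPair(stressed, relaxed, (0.0, 0.0), 1.0)
        samples = tfm.piv_displacements(pair)
        ux = truth.ground_truth["u_x_um"] / 0.65
        uy = truth.ground_truth["u_y_um"] / 0.65
        coords = np.stack([samples[:, 1], samples[:, 0]])
        tx = ndimage.map_coordinates(ux, coords, order=1)
        ty = ndimage.map_coordinates(uy, coords, order=1)
        err = np.sqrt(np.mean((samples[:, 2] - tx) ** 2
                              + (samples[:, 3] - ty) ** 2))
        truth_rms = np.sqrt(np.mean(tx ** 2 + ty ** 2))
        assert err <= 0.5 * truth_rms  # window smoothing bounds window PIV


class TestTrackBeads:
    def test_rigid_shift_recovered_per_bead(self, gel):
        stressed, relaxed, _ = _bead_scene(gel, drift=(0.6, -0.4), noise=0.0)
        pair = tfm.MatchedPair(stressed, relaxed, (0.0, 0.0), 1.0)
        samples = tfm.track_beads(pair)
        assert len(samples) > 500
        assert abs(np.median(samples[:, 2]) - (-0.4)) < 0.05
        assert abs(np.median(samples[:, 3]) - 0.6) < 0.05

    def test_refinement_beats_window_piv_on_dipole(self, gel):
        stressed, relaxed, truth = _bead_scene(gel, magnitude=800.0,
                                               size=384, seed=9)
        pair = tfm.MatchedPair(stressed, relaxed, (0.0, 0.0), 1.0)
        piv = tfm.piv_displacements(pair)
        tracked = tfm.track_beads(pair, predictor_samples=piv)
        ux = truth.ground_truth["u_x_um"] / 0.65
        uy = truth.ground_truth["u_y_um"] / 0.65

        def rms_error(samples):
            coords = np.stack([samples[:, 1], samples[:, 0]])
            tx = ndimage.map_coordinates(ux, coords, order=1)
            ty = ndimage.map_coordinates(uy, coords, order=1)
            return np.sqrt(np.mean((samples[:, 2] - tx) ** 2
                                   + (samples[:, 3] - ty) ** 2))

        assert rms_error(tracked) < rms_error(piv)


class TestInterpolateToGrid:
    def test_constant_samples_reproduced(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, size=(40, 2))
        samples = np.column_stack([pts, np.full(40, 1.0), np.zeros(40),
                                   np.ones(40)])
        field = tfm.interpolate_to_grid(samples, pixel_size_um=1.0)
        assert np.allclose(field.u_x[field.valid_mask], 1.0)
        assert np.allclose(field.u_y[field.valid_mask], 0.0)

    def test_planar_field_exact_at_nodes(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(60, 2))
        ux = 0.1 * pts[:, 0]
        samples = np.column_stack([pts, ux, np.zeros(60), np.ones(60)])
        field = tfm.interpolate_to_grid(samples, pixel_size_um=1.0,
                                        spacing_um=2.6)
        xs = np.arange(field.shape[1]) * 2.6
        expected = np.broadcast_to(0.1 * xs, field.shape)
        assert np.allclose(field.u_x[field.valid_mask],
                           expected[field.valid_mask], atol=1e-9)

    def test_insufficient_or_collinear_samples_rejected(self):
        with pytest.raises(DataError):
            tfm.interpolate_to_grid(np.zeros((2, 5)), pixel_size_um=1.0)
        collinear = np.column_stack([np.arange(10), np.arange(10),
                                     np.ones(10), np.ones(10), np.ones(10)])
        with pytest.raises(DataError):
            tfm.interpolate_to_grid(collinear, pixel_size_um=1.0)


# ---------------------------------------------------------- filters, summary
def _record(ratio, area=5000.0, density=1.0, gel_id="g1", cond="control",
            island_id="i"):
    return tfm.IslandRecord(island_id=island_id, island_mask=None,
                            area_um2=area, strain_energy_j=density * 1e-15,
                            energy_density_j_per_m2=density,
                            equilibrium_ratio=ratio, gel_id=gel_id,
                            condition_id=cond)


class TestFilterIslands:
    def test_threshold_rule_boundaries(self):
        records = [_record(0.12), _record(0.05), _record(0.10)]
        retained = tfm.filter_islands(records)
        # strictly-greater-than rule: 0.10 exactly is retained
        assert [r.retained for r in records] == [False, True, True]
        assert len(retained) == 2
        assert "out-of-equilibrium" in records[0].discard_reasons[0]

    def test_size_filter(self):
        records = [_record(0.01, area=100.0), _record(0.01, area=5000.0)]
        retained = tfm.filter_islands(records, size_range_um2=(1000.0, 1e4))
        assert len(retained) == 1 and retained[0].area_um2 == 5000.0

    def test_invalid_threshold(self):
        with pytest.raises(ConfigError):
            tfm.filter_islands([], ratio_threshold=1.5)


class TestSummarizeByGel:
    def test_fold_of_control_direct_arithmetic(self):
        records = [
            _record(0.0, density=1.0, gel_id="g1", cond="control", island_id="a"),
            _record(0.0, density=2.0, gel_id="g1", cond="treated", island_id="b"),
            _record(0.0, density=2.0, gel_id="g2", cond="control", island_id="c"),
            _record(0.0, density=4.0, gel_id="g2", cond="treated", island_id="d"),
        ]
        for r in records:
            r.retained = True
        summary = tfm.summarize_by_gel(records, "control")
        folds = summary.per_gel.query("condition_id == 'treated'")
        assert sorted(folds["fold_of_control"]) == [2.0, 2.0]

    def test_identity_condition_folds_are_one(self):
        records = [_record(0.0, density=d, gel_id="g1", island_id=str(i))
                   for i, d in enumerate([1.0, 2.0, 3.0])]
        for r in records:
            r.retained = True
        summary = tfm.summarize_by_gel(records, "control")
        assert np.allclose(summary.per_gel["fold_of_control"], 1.0)

    def test_missing_control_raises(self):
        records = [_record(0.0, gel_id="g1", cond="treated")]
        records[0].retained = True
        with pytest.raises(NormalizationError):
            tfm.summarize_by_gel(records, "control")


class TestDriftInvariance:
    def test_energy_density_stable_under_added_drift(self, gel):
        scene = syn.SceneParams(image_size_px=(384, 384), pixel_size_um=0.65,
                                rng_seed=13)
        traction = syn.make_island_traction(scene, 45.0, 800.0,
                                            "contractile_dipole")
        mask = syn.island_footprint_mask(scene, 45.0)
        densities = []
        for drift in ((0.0, 0.0), (3.0, -2.0)):
            stressed, relaxed, _ = syn.render_bead_pair(
                traction, gel, scene, n_beads=2000, drift_px=drift)
            rec, _, _ = tfm.analyze_island(stressed, relaxed, mask, gel,
                                           pixel_size_um=0.65)
            densities.append(rec.energy_density_j_per_m2)
        assert densities[1] == pytest.approx(densities[0], rel=0.02)
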