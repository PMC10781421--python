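import numpy as np
import pytest
from scipy import ndimage, stats

from osteounit import orientation as ori
from osteounit import phantoms

from conftest import make_grating


def bin_error(modal_deg, truth_deg):
    return float(ori.ang_dist_180(modal_deg, truth_deg))


class TestDirectionality:
    @pytest.mark.parametrize("angle", [0, 15, 30, 45, 60, 75, 90, 110, 145, 178])
    def test_grating_angle_recovery(self, angle):
        hist = ori.directionality_histogram(make_grating(angle))
        target = angle if angle <= 90 else angle - 180
        assert bin_error(hist.modal_angle_deg, target) <= hist.bin_width_deg

    def test_histogram_normalized(self):
        hist = ori.directionality_histogram(make_grating(30))
        assert float(np.sum(hist.frequencies)) == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_is_isotropic(self):
        rng = np.random.default_rng(7)
        hist = ori.directionality_histogram(rng.standard_normal((512, 512)))
        assert hist.frequencies.max() < 2.0 * hist.frequencies.mean()
        assert hist.anisotropy_score < 0.1

    def test_constant_image_flags_low_signal(self):
        hist = ori.directionality_histogram(np.full((128, 128), 37.0))
        assert hist.low_signal
        assert hist.anisotropy_score == 0.0
        assert np.allclose(hist.frequencies, hist.frequencies[0])

    def test_rotation_equivariance(self):
        base = make_grating(30, size=384)
        rot = ndimage.rotate(base, 20.0, reshape=False, order=3)
        hist = ori.directionality_histogram(rot[128:256, 128:256])
        assert bin_error(hist.modal_angle_deg, 50.0) <= hist.bin_width_deg

    def test_half_turn_invariance(self):
        img = make_grating(40) + np.random.default_rng(0).normal(0, 5, (256, 256))
        h0 = ori.directionality_histogram(img)
        h180 = ori.directionality_histogram(np.rot90(img, 2))
        assert np.allclose(h0.frequencies, h180.frequencies, atol=1e-12)

    def test_mirror_maps_angle_to_negative(self):
        img = make_grating(30)
        h = ori.directionality_histogram(np.flipud(img))
        assert bin_error(h.modal_angle_deg, -30.0) <= h.bin_width_deg

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="small"):
            ori.directionality_histogram(np.zeros((4, 4)))

    def test_gradient_estimator_agrees_on_thin_bands(self):
        tex = phantoms._oriented_texture(200, 512, 45.0, 8.0,
                                         np.random.default_rng(1))
        modal = ori.gradient_orientation_histogram(tex[40:52]).modal_angle_deg
        assert bin_error(modal, 45.0) <= 6.0


class TestPeakAreas:
    @staticmethod
    def mixture_hist(w0, w90, sd):
        centers = np.arange(-89.0, 91.0, 2.0)

        def wg(mu):
            d = centers[None, :] - mu + 180.0 * np.arange(-3, 4)[:, None]
            m = np.exp(-0.5 * (d / sd) ** 2).sum(0)
            return m / m.sum()

        f = w0 * wg(0.0) + w90 * wg(90.0)
        return ori.OrientationHistogram(centers, f / f.sum(), 2.0, 0.5)

    def test_single_bin_mass(self):
        centers = np.arange(-89.0, 91.0, 2.0)
        f = np.zeros_like(centers)
        f[np.argmin(np.abs(centers))] = 1.0
        p = ori.integrate_peaks(ori.OrientationHistogram(centers, f, 2.0, 1.0))
        assert p.area_0 == pytest.approx(1.0, abs=0.01)
        assert p.area_90 == pytest.approx(0.0, abs=0.01)

    def test_mixture_weights_recovered(self):
        p = ori.integrate_peaks(self.mixture_hist(0.7, 0.3, 10.0))
        assert p.area_0 == pytest.approx(0.70, abs=0.02)
        assert p.area_90 == pytest.approx(0.30, abs=0.02)
        assert p.method == "wrapped_gaussian"

    def test_off_axis_mass_warns(self):
        centers = np.arange(-89.0, 91.0, 2.0)
        d = centers[None, :] - 45.0 + 180.0 * np.arange(-3, 4)[:, None]
        f = np.exp(-0.5 * (d / 8.0) ** 2).sum(0)
        hist = ori.OrientationHistogram(centers, f / f.sum(), 2.0, 0.8)
        with pytest.warns(UserWarning, match="elsewhere"):
            p = ori.integrate_peaks(hist)
        assert p.area_0 < 0.1 and p.area_90 < 0.1

    def test_areas_bounded(self):
        p = ori.integrate_peaks(self.mixture_hist(0.5, 0.5, 15.0))
        assert 0.0 <= p.area_0 <= 1.0 and 0.0 <= p.area_90 <= 1.0
        assert p.area_0 + p.area_90 <= 1.0 + 1e-6

    def test_arcade_deep_layer_more_perpendicular_than_isotropic(self):
        arcade, _ = phantoms.orientation_preset("terrestrial", seed=0)
        iso, _ = phantoms.orientation_preset("aquatic_isotropic", seed=0)
        a = ori.integrate_peaks(ori.directionality_histogram(arcade[350:, :]))
        b = ori.integrate_peaks(ori.directionality_histogram(iso[350:, :]))
        assert a.area_90 > b.area_90

    def test_mirror_symmetry_of_areas(self, arcade_image):
        img, _ = arcade_image
        p = ori.integrate_peaks(ori.directionality_histogram(img))
        q = ori.integrate_peaks(ori.directionality_histogram(np.flipud(img)))
        assert q.area_0 == pytest.approx(p.area_0, abs=0.05)
        assert q.area_90 == pytest.approx(p.area_90, abs=0.05)


class TestDepthProfiles:
    def test_arcade_angle_deepens_to_perpendicular(self, arcade_image):
        img, _ = arcade_image
        prof = ori.depth_profiles(img, n_bands=50)
        dist_to_0 = ori.ang_dist_180(prof.modal_angle_deg, 0.0)
        assert dist_to_0[1] < 10.0                       # superficial ~ 0 deg
        deep = ori.ang_dist_180(prof.modal_angle_deg[-5:], 90.0)
        assert np.all(deep <= 4.0)                       # deep ~ 90 deg

    def test_isotropic_profile_has_no_depth_trend(self):
        rhos = []
        for seed in range(20):
            img, _ = phantoms.orientation_preset("aquatic_isotropic", seed=seed)
            prof = ori.depth_profiles(img, n_bands=30)
            rho = stats.spearmanr(
                prof.depth, ori.ang_dist_180(prof.modal_angle_deg, 0.0)).statistic
            rhos.append(abs(rho))
        assert np.median(rhos) < 0.5

    def test_single_layer_flat_profile(self):
        img, _ = phantoms.gen_orientation_image(
            (100.0, 0.0, 0.0), (0.0, 45.0, 90.0), concentration=8.0,
            size=256, seed=0)
        prof = ori.depth_profiles(img, n_bands=16)
        assert np.all(ori.ang_dist_180(prof.modal_angle_deg, 0.0) <= 4.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            ori.depth_profiles(np.zeros((20, 128)), n_bands=40)


class TestSegmentation:
    def test_constructed_boundaries(self):
        # profile with a birefringence minimum at depth 0.20 and an angle
        # plateau near 90 deg from depth 0.50 on must yield 20/30/50 layers
        n = 50
        depth = (np.arange(n) + 0.5) / n
        biref = np.abs(depth - 0.20) * 100.0 + 10.0
        angle = np.where(depth >= 0.50, 88.0, 30.0)
        prof = ori.DepthProfile(depth=depth, modal_angle_deg=angle,
                                birefringence=biref,
                                band_edges=np.arange(n) / n, n_bands=n)
        seg = ori.segment_layers(prof)
        assert seg.stratified
        assert seg.fractions_pct[0] == pytest.approx(20.0, abs=3.0)
        assert seg.fractions_pct[1] == pytest.approx(30.0, abs=3.0)
        assert seg.fractions_pct[2] == pytest.approx(50.0, abs=3.0)

    def test_phantom_truth_recovered(self, arcade_image):
        img, truth = arcade_image
        seg = ori.segment_layers(ori.depth_profiles(img, n_bands=50))
        assert seg.stratified
        for got, want in zip(seg.fractions_pct, truth.layer_fractions):
            assert got == pytest.approx(want, abs=3.0)

    def test_percentages_sum_to_100(self, arcade_image):
        img, _ = arcade_image
        seg = ori.segment_layers(ori.depth_profiles(img, n_bands=50))
        assert sum(seg.fractions_pct) == pytest.approx(100.0, abs=1e-9)

    def test_isotropic_marked_unstratified(self):
        img, _ = phantoms.orientation_preset("aquatic_isotropic", seed=2)
        seg = ori.segment_layers(ori.depth_profiles(img, n_bands=50))
        assert not seg.stratified
        assert seg.boundary_sup_mid is None and seg.fractions_pct is None

    def test_segmentation_deterministic(self, arcade_image):
        img, _ = arcade_image
        prof = ori.depth_profiles(img, n_bands=50)
        assert ori.segment_layers(prof) == ori.segment_layers(prof)

    def test_terrestrial_preset_has_thicker_deep_layer(self):
        deep = {}
        for kind in ("terrestrial", "aquatic"):
            img, _ = phantoms.orientation_preset(kind, seed=5)
            seg = ori.segment_layers(ori.depth_profiles(img, n_bands=50))
            assert seg.stratified
            deep[kind] = seg.fractions_pct[2]
        assert deep["terrestrial"] > deep["aquatic"]
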