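"""Distance-distribution mathematics and AZ image/point-set procedures."""

import numpy as np
import pytest
from scipy import integrate, stats

from synapstp.geometry import (
    SIGMA_DEFAULT,
    DistanceModel,
    average_centered_images,
    cylinder_radius_from_spacing,
    detect_peaks,
    deterministic_bins,
    fit_rayleigh,
    knn_mean_distance,
    planar_cdf,
    planar_pdf,
    planar_quantile,
    radial_profile,
)
from synapstp.synthetic_data import AZImageConfig, gen_az_image_stack


class TestRayleighFit:
    def test_closed_form_on_constant_sample(self):
        m = fit_rayleigh([5.0] * 10)
        assert m.sigma == pytest.approx(5.0 / np.sqrt(2))

    def test_closed_form_arithmetic(self):
        # sum x^2 = 25 over n = 2 -> sigma = sqrt(25/4) = 2.5
        assert fit_rayleigh([3.0, 4.0]).sigma == pytest.approx(2.5)

    def test_mle_consistency(self):
        rng = np.random.default_rng(42)
        sample = rng.rayleigh(SIGMA_DEFAULT, size=10_000)
        m = fit_rayleigh(sample)
        assert m.sigma == pytest.approx(SIGMA_DEFAULT, rel=0.02)

    @pytest.mark.parametrize("bad", [[], [1.0], [-1.0, 2.0], [0.0, 1.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_rayleigh(bad)


class TestPlanarDistribution:
    def test_density_normalises(self, distance_model):
        val, err = integrate.quad(lambda x: planar_pdf(x, distance_model),
                                  0, np.inf)
        assert abs(val - 1.0) < 1e-8

    def test_moments_match_closed_form(self, distance_model):
        mean, _ = integrate.quad(lambda x: x * planar_pdf(x, distance_model),
                                 0, np.inf)
        second, _ = integrate.quad(lambda x: x**2 * planar_pdf(x, distance_model),
                                   0, np.inf)
        sd = np.sqrt(second - mean**2)
        assert mean == pytest.approx(122.1, abs=0.05)
        assert sd == pytest.approx(51.5, abs=0.05)
        assert mean == pytest.approx(distance_model.planar_mean, rel=1e-9)
        assert sd == pytest.approx(distance_model.planar_sd, rel=1e-8)

    def test_mode_at_sqrt2_sigma(self, distance_model):
        xs = np.linspace(1.0, 400.0, 200_000)
        mode = xs[np.argmax(planar_pdf(xs, distance_model))]
        assert mode == pytest.approx(np.sqrt(2) * SIGMA_DEFAULT, abs=0.05)
        assert mode == pytest.approx(108.2, abs=0.1)

    def test_quantile_inverts_cdf(self, distance_model):
        q = np.linspace(1e-9, 1 - 1e-9, 101)
        back = planar_cdf(planar_quantile(q, distance_model), distance_model)
        assert np.max(np.abs(back - q)) < 1e-10

    def test_fraction_within_coupling_exclusion_zone(self, distance_model):
        # only ~1.5% of sites lie within 30 nm of the channel cluster
        assert planar_cdf(30.0, distance_model) == pytest.approx(0.0153, abs=0.0005)

    def test_median_against_monte_carlo(self, distance_model):
        rng = np.random.default_rng(3)
        sample = planar_quantile(rng.random(100_000), distance_model)
        emp = np.median(sample)
        assert planar_quantile(0.5, distance_model) == pytest.approx(
            emp, rel=0.01)

    def test_invalid_arguments(self, distance_model):
        with pytest.raises(ValueError):
            planar_pdf(-1.0, distance_model)
        with pytest.raises(ValueError):
            planar_quantile(1.5, distance_model)


class TestDeterministicBins:
    def test_single_bin_is_median(self, distance_model):
        assert deterministic_bins(distance_model, 1)[0] == pytest.approx(
            planar_quantile(0.5, distance_model))

    def test_bin_mean_approximates_distribution_mean(self, distance_model):
        bins = deterministic_bins(distance_model, 180)
        assert bins.mean() == pytest.approx(122.1, rel=0.005)

    def test_bins_strictly_increasing(self, distance_model):
        bins = deterministic_bins(distance_model, 64)
        assert np.all(np.diff(bins) > 0)


class TestNearestNeighbours:
    def test_interior_grid_point_unit_spacing(self):
        xs, ys = np.mgrid[0:5, 0:5]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        per_point, _ = knn_mean_distance(pts, k=4)
        centre = np.flatnonzero((pts[:, 0] == 2) & (pts[:, 1] == 2))[0]
        assert per_point[centre] == pytest.approx(1.0)

    def test_two_points(self):
        per_point, grand = knn_mean_distance([[0, 0], [0, 3.5]], k=1)
        assert np.allclose(per_point, 3.5)
        assert grand == pytest.approx(3.5)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 10, size=(60, 2))
        per_point, grand = knn_mean_distance(pts, k=4)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_sorted = np.sort(d, axis=1)
        brute = d_sorted[:, 1:5].mean(axis=1)  # skip self distance 0
        assert np.allclose(per_point, brute)
        assert grand == pytest.approx(brute.mean())

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            knn_mean_distance([[0, 0], [1, 1]], k=4)


class TestCylinderRadius:
    def test_measured_az_spacing(self):
        assert cylinder_radius_from_spacing(1.106) == pytest.approx(
            0.62399, abs=1e-5)

    def test_sqrt_pi_normalisation(self):
        assert cylinder_radius_from_spacing(np.sqrt(np.pi)) == pytest.approx(1.0)

    def test_area_identity(self):
        r = cylinder_radius_from_spacing(0.87)
        assert np.pi * r**2 == pytest.approx(0.87**2, rel=1e-12)


def _gaussian_spot(h, cy, cx, amp=200.0, sd=2.0):
    yy, xx = np.mgrid[0:h, 0:h]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sd**2))


class TestPeakDetection:
    def test_single_spot(self):
        img = _gaussian_spot(51, 20, 30)
        peaks = detect_peaks(img, threshold=25, min_separation=5)
        assert len(peaks) == 1
        assert tuple(peaks[0]) == (20, 30)

    def test_close_spots_keep_brighter(self):
        img = _gaussian_spot(51, 25, 24, amp=150) + _gaussian_spot(51, 25, 27, amp=220)
        peaks = detect_peaks(img, threshold=25, min_separation=5)
        assert len(peaks) == 1
        assert peaks[0][1] >= 26  # the brighter right-hand spot survives

    def test_all_below_threshold(self):
        img = np.full((51, 51), 10.0)
        assert len(detect_peaks(img, threshold=25)) == 0


class TestAveragingPipeline:
    def test_identical_centered_images(self):
        img = _gaussian_spot(51, 25, 25)
        avg, n_used = average_centered_images(np.stack([img] * 5), threshold=25)
        assert n_used == 5
        rescaled = (img - img.min()) / (img.max() - img.min()) * 255
        assert np.allclose(avg, rescaled, atol=1e-9)

    def test_translation_recovered(self):
        img = _gaussian_spot(51, 25, 25)
        shifted = np.roll(np.roll(img, 2, axis=0), 3, axis=1)
        avg, _ = average_centered_images(np.stack([img, shifted]), threshold=25)
        assert np.argmax(avg) == np.ravel_multi_index((25, 25), (51, 51))

    def test_ring_stack_profile_peaks_at_ring_radius(self):
        # clusters at a fixed 100 nm radius -> profile peak near 100 nm
        rng = np.random.default_rng(5)
        imgs = []
        for _ in range(120):
            # 8 evenly spaced clusters: their centre of mass is the ring
            # centre, so peak-based centring preserves the ring
            base = rng.uniform(0, 2 * np.pi)
            img = np.zeros((51, 51))
            for ang in base + np.arange(8) * np.pi / 4:
                img += _gaussian_spot(51, 25 + 10 * np.sin(ang),
                                      25 + 10 * np.cos(ang), sd=1.5)
            imgs.append(img)
        avg, _ = average_centered_images(np.array(imgs), threshold=25,
                                         min_separation=5)
        prof = radial_profile(avg, px_size=10.0)
        peak_r = prof.bin_centers[np.argmax(prof.fraction)]
        assert abs(peak_r - 100.0) <= 15.0

    def test_detected_peak_centring_matches_true_centroid_oracle(self):
        """Peak detection + centroid shifting reproduces an oracle that
        shifts by the centroid of the *known* cluster positions."""
        from synapstp.geometry import _integer_shift

        cfg = AZImageConfig(n_images=300, noise_sd=3.0, background=5.0,
                            n_clusters_range=(1, 2))
        stack, truth = gen_az_image_stack(cfg, sigma=SIGMA_DEFAULT, seed=21)
        avg, n_used = average_centered_images(stack, threshold=25,
                                              min_separation=5)
        assert n_used >= 290
        acc = np.zeros_like(stack[0])
        for img, tr in zip(stack, truth):
            pts = np.array([[c["y_px"], c["x_px"]] for c in tr["clusters"]])
            com = pts.mean(axis=0)
            acc += _integer_shift(img, int(np.rint(25 - com[0])),
                                  int(np.rint(25 - com[1])))
        oracle = acc / len(stack)
        p1 = radial_profile(avg, 10.0).fraction
        p2 = radial_profile(oracle, 10.0).fraction
        assert np.corrcoef(p1, p2)[0, 1] > 0.95

    def test_cluster_rich_stack_recovers_truth_centred_distribution(self):
        """With several clusters per image the centroid approximates the AZ
        centre, so the recovered profile matches one centred on the true
        AZ centres."""
        from synapstp.geometry import _integer_shift

        cfg = AZImageConfig(n_images=300, noise_sd=3.0, background=5.0,
                            n_clusters_range=(6, 8), center_jitter_px=3)
        stack, truth = gen_az_image_stack(cfg, sigma=SIGMA_DEFAULT, seed=22)
        avg, _ = average_centered_images(stack, threshold=25, min_separation=4)
        acc = np.zeros_like(stack[0])
        for img, tr in zip(stack, truth):
            cy, cx = tr["center_px"]
            acc += _integer_shift(img, 25 - cy, 25 - cx)
        oracle = acc / len(stack)
        p1 = radial_profile(avg, 10.0).fraction
        p2 = radial_profile(oracle, 10.0).fraction
        assert np.corrcoef(p1, p2)[0, 1] > 0.95

    def test_ground_truth_radii_follow_planar_distribution(self, distance_model):
        """Chi-square test of the synthetic cluster radii against the
        analytic planar distribution (alpha = 0.01)."""
        cfg = AZImageConfig(n_images=300)
        _, truth = gen_az_image_stack(cfg, sigma=SIGMA_DEFAULT, seed=9)
        radii = np.array([c["r_nm"] for tr in truth for c in tr["clusters"]])
        edges = planar_quantile(np.linspace(0, 1, 11), distance_model)
        counts, _ = np.histogram(radii, bins=edges)
        res = stats.chisquare(counts, f_exp=np.full(10, len(radii) / 10))
        assert res.pvalue > 0.01


class TestRadialProfile:
    def test_uniform_image_follows_annulus_areas(self):
        img = np.ones((51, 51))
        prof = radial_profile(img, px_size=10.0)
        yy, xx = np.mgrid[0:51, 0:51]
        r = np.hypot(yy - 25, xx - 25) * 10.0
        counts, _ = np.histogram(r.ravel(), bins=prof.bin_edges)
        assert np.allclose(prof.fraction, counts / counts.sum())

    def test_delta_at_centre(self):
        img = np.zeros((51, 51))
        img[25, 25] = 7.0
        prof = radial_profile(img, 10.0)
        assert prof.fraction[0] == pytest.approx(1.0)
        assert np.all(prof.fraction[1:] == 0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        prof = radial_profile(rng.random((51, 51)), 10.0)
        assert prof.fraction.sum() == pytest.approx(1.0, abs=1e-9)
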