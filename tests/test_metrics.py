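"""Segment geometry, profile extraction, sigmoid metrics, noise, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from smscine import (PhantomSpec, phantom_frame, SegmentGeometry, SigmoidFit,
                     place_segments, sample_lines, extract_profile, fit_sigmoid,
                     edge_sharpness, normalized_contrast, estimate_noise,
                     evaluate_slice, benjamini_hochberg)
from smscine.io import ImageSeries
from smscine.metrics import SEGMENT_LABELS, _logistic


def circle_geometry(radius=24.0, **kw):
    return SegmentGeometry(center=(0.0, 0.0), semi_axes=(radius, radius), **kw)


class TestSegments:
    def test_sectors_tile_360(self):
        layout = place_segments(circle_geometry(reference_angle_deg=105.0))
        widths = []
        for lab in SEGMENT_LABELS:
            lo, hi = layout["sectors"][lab]
            widths.append((hi - lo) % 360.0)
        assert np.allclose(widths, 60.0)
        assert len(layout["reference_lines_deg"]) == 3

    def test_labels_equivariant_under_rotation(self):
        base = place_segments(circle_geometry(reference_angle_deg=10.0))
        rot = place_segments(circle_geometry(reference_angle_deg=10.0 + 35.0))
        for lab in SEGMENT_LABELS:
            lo0, _ = base["sectors"][lab]
            lo1, _ = rot["sectors"][lab]
            assert (lo1 - lo0) % 360.0 == pytest.approx(35.0)

    def test_total_lines_per_slice(self):
        geom = circle_geometry(n_lines_per_segment=50)
        total = sum(len(sample_lines(geom, seg)) for seg in SEGMENT_LABELS)
        assert total == 300

    def test_angular_spacing(self):
        lines = sample_lines(circle_geometry(n_lines_per_segment=50), "S7")
        angles = np.array([ln["angle_deg"] for ln in lines])
        spacing = np.diff(np.unwrap(np.deg2rad(angles)))
        assert np.allclose(np.rad2deg(spacing), 1.2)

    def test_single_border_crossing(self):
        geom = SegmentGeometry(center=(2.0, -3.0), semi_axes=(24.0, 18.0),
                               reference_angle_deg=30.0)
        for seg in SEGMENT_LABELS:
            for ln in sample_lines(geom, seg):
                assert 0.0 < ln["border_mm"] < ln["length_mm"]

    def test_circle_equal_line_lengths(self):
        lines = sample_lines(circle_geometry(radius=20.0), "S9")
        lengths = [ln["length_mm"] for ln in lines]
        assert np.allclose(lengths, lengths[0])

    def test_degenerate_ellipse_rejected(self):
        with pytest.raises(ValueError):
            SegmentGeometry(center=(0, 0), semi_axes=(0.0, 10.0))

    def test_unknown_segment_rejected(self):
        with pytest.raises(ValueError):
            sample_lines(circle_geometry(), "S1")


class TestExtractProfile:
    def _line(self):
        return {"p0": (-20.0, -20.0), "p1": (10.0, 15.0)}

    def test_constant_image(self):
        img = np.full((64, 64), 3.5)
        pos, prof = extract_profile(img, self._line(), 2.0)
        assert np.allclose(prof, 3.5)

    def test_linear_ramp(self):
        """Bilinear sampling and cubic refinement reproduce a linear ramp."""
        n = 64
        img = np.tile(np.arange(n, dtype=float), (n, 1))  # ramp along x
        line = {"p0": (0.0, -40.0), "p1": (0.0, 40.0)}
        pos, prof = extract_profile(img, line, 2.0)
        expected = np.interp(pos, [0, 80], [img[32, 12], img[32, 52]])
        rng = img.max() - img.min()
        assert np.abs(prof - expected).max() < 1e-6 * rng

    def test_output_length(self):
        img = np.zeros((64, 64))
        pos, prof = extract_profile(img, self._line(), 2.0, upsample=100)
        length = np.hypot(30.0, 35.0)
        n_native = int(np.floor(length / 2.0)) + 1
        assert len(prof) == 100 * (n_native - 1) + 1


class TestSigmoidFit:
    def test_noiseless_recovery(self):
        x = np.linspace(0, 12, 601)
        y = _logistic(x, 10.0, 100.0, 5.0, 2.0)
        fit = fit_sigmoid(x, y)
        assert fit.valid
        assert abs(fit.slope) == pytest.approx(2.0, rel=0.01)
        assert fit.amplitude == pytest.approx(100.0, rel=0.01)

    def test_flat_profile_invalid(self):
        x = np.linspace(0, 10, 101)
        fit = fit_sigmoid(x, np.full_like(x, 7.0))
        assert not fit.valid

    def test_reversal_flips_slope_sign_only(self):
        x = np.linspace(0, 12, 401)
        y = _logistic(x, 5.0, 50.0, 6.0, 1.5)
        f_fwd = fit_sigmoid(x, y)
        f_rev = fit_sigmoid(x, y[::-1])
        assert np.sign(f_fwd.slope) == -np.sign(f_rev.slope)
        assert abs(f_rev.slope) == pytest.approx(abs(f_fwd.slope), rel=0.01)
        assert edge_sharpness(f_rev) == pytest.approx(edge_sharpness(f_fwd), rel=0.01)

    def test_steeper_edge_higher_es(self):
        x = np.linspace(0, 12, 401)
        es = [edge_sharpness(fit_sigmoid(x, _logistic(x, 0.0, 10.0, 6.0, s)))
              for s in (2.0, 4.0)]
        assert es[1] > es[0]

    def test_intensity_scaling_leaves_es_unchanged(self):
        x = np.linspace(0, 12, 401)
        y = _logistic(x, 2.0, 30.0, 6.0, 1.2)
        f1 = fit_sigmoid(x, y)
        f2 = fit_sigmoid(x, 25.0 * y)
        assert edge_sharpness(f2) == pytest.approx(edge_sharpness(f1), rel=1e-3)

    def test_noisy_recovery_at_snr20(self):
        """Median |s| over 300 noisy lines within 10% of truth at SNR 20."""
        rng = np.random.default_rng(42)
        x = np.linspace(0, 12, 301)
        s_true = 2.0
        recovered = []
        for _ in range(300):
            y = _logistic(x, 10.0, 100.0, 6.0, s_true)
            y = y + (100.0 / 20.0) * rng.standard_normal(x.size)
            fit = fit_sigmoid(x, y)
            if fit.valid:
                recovered.append(abs(fit.slope))
        assert len(recovered) > 250
        assert np.median(recovered) == pytest.approx(s_true, rel=0.10)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.arange(4), np.arange(4.0))


class TestContrast:
    def _fit(self, a, b):
        return SigmoidFit(baseline=a, amplitude=b, center=5.0, slope=2.0,
                          residual=0.0, valid=True)

    def test_zero_amplitude_zero_contrast_range_convention(self):
        assert normalized_contrast(self._fit(10.0, 0.0), 1.0,
                                   convention="range") == 0.0

    def test_conventions_agree_when_min_zero(self):
        fit = self._fit(0.0, 100.0)
        assert normalized_contrast(fit, 10.0, "range") == pytest.approx(6.0)
        assert normalized_contrast(fit, 10.0, "max") == pytest.approx(6.0)

    def test_scale_invariance(self):
        fit1 = self._fit(2.0, 30.0)
        fit2 = self._fit(2.0 * 7.0, 30.0 * 7.0)
        for conv in ("range", "max"):
            assert normalized_contrast(fit2, 7.0 * 3.0, conv) == pytest.approx(
                normalized_contrast(fit1, 3.0, conv))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            normalized_contrast(self._fit(0, 1), 0.0)

    def test_invalid_fit_propagates_nan(self):
        bad = SigmoidFit(0, 0, 0, 0, 0, False)
        assert np.isnan(normalized_contrast(bad, 1.0))
        assert np.isnan(edge_sharpness(bad))


class TestEstimateNoise:
    def _series(self, data):
        return ImageSeries(np.asarray(data, dtype=complex), 2.0, 45.0)

    def test_sigma_raw_matches_monte_carlo(self):
        """Background std of a magnitude-noise series vs a repeated-draw
        reference (complex Gaussian, known sigma)."""
        rng = np.random.default_rng(0)
        sigma = 0.4
        draws = [np.abs(sigma * (rng.standard_normal((32, 32))
                                 + 1j * rng.standard_normal((32, 32))))
                 for _ in range(40)]
        mc_ref = np.mean([d.std() for d in draws])
        bg = np.zeros((32, 32), bool)
        bg[:10, :10] = True
        blood = np.zeros((32, 32), bool)
        blood[14:18, 14:18] = True
        img = draws[0].copy()
        img[blood] += 10.0
        series = self._series(img[None, None])
        est = estimate_noise(series, bg, blood, series)  # identical -> scale 1
        assert est == pytest.approx(mc_ref, rel=0.10)

    def test_identical_series_scale_is_one(self):
        rng = np.random.default_rng(1)
        img = np.abs(rng.standard_normal((16, 16))) + 0.1
        bg = np.zeros((16, 16), bool); bg[:4, :4] = True
        blood = np.zeros((16, 16), bool); blood[8:12, 8:12] = True
        s = self._series(img[None, None])
        raw_std = np.abs(img)[bg].std()
        assert estimate_noise(s, bg, blood, s) == pytest.approx(raw_std, rel=1e-12)

    def test_iterative_scaling_linear(self):
        rng = np.random.default_rng(2)
        img = np.abs(rng.standard_normal((16, 16))) + 0.1
        bg = np.zeros((16, 16), bool); bg[:4, :4] = True
        blood = np.zeros((16, 16), bool); blood[8:12, 8:12] = True
        s = self._series(img[None, None])
        s2 = self._series(3.0 * img[None, None])
        assert estimate_noise(s, bg, blood, s2) == pytest.approx(
            3.0 * estimate_noise(s, bg, blood, s), rel=1e-12)

    def test_overlapping_rois_rejected(self):
        mask = np.ones((8, 8), bool)
        s = self._series(np.ones((1, 1, 8, 8)))
        with pytest.raises(ValueError):
            estimate_noise(s, mask, mask, s)


@pytest.fixture(scope="module")
def symmetric():
    spec = PhantomSpec(matrix_size=112, pixel_spacing=2.2,
                       epi_semiaxes=(34, 34), endo_semiaxes=(24, 24),
                       papillary=())
    img, ell = phantom_frame(spec, 0.0, 4)
    geom = SegmentGeometry(center=(ell["cy"], ell["cx"]),
                           semi_axes=(ell["semi_y"], ell["semi_x"]),
                           reference_angle_deg=105.0)
    return spec, img, geom


class TestEvaluateSlice:

    def test_rotationally_symmetric_contrast(self, symmetric):
        spec, img, geom = symmetric
        tab = evaluate_slice(img, geom, sigma=0.01, pixel_spacing=2.2)
        seg = tab[tab.segment != "AVG"]
        c = seg.contrast_mean.to_numpy()
        assert c.max() / c.min() < 1.05
        assert (seg.n_valid == 50).all()

    def test_avg_row_is_mean_of_segments(self, symmetric):
        spec, img, geom = symmetric
        tab = evaluate_slice(img, geom, sigma=0.01, pixel_spacing=2.2)
        seg = tab[tab.segment != "AVG"]
        avg = tab[tab.segment == "AVG"].iloc[0]
        assert avg.contrast_mean == pytest.approx(seg.contrast_mean.mean())
        assert avg.es_mean == pytest.approx(seg.es_mean.mean())

    def test_contrast_estimator_consistency(self, symmetric):
        """Known plateau difference Delta and sigma: measured contrast equals
        0.6*Delta/sigma within 10% (range convention)."""
        spec, img, geom = symmetric
        sigma = 0.02
        tab = evaluate_slice(img, geom, sigma=sigma, pixel_spacing=2.2,
                             contrast_convention="range")
        delta = spec.blood_intensity - spec.myocardium_intensity
        expected = 0.6 * delta / sigma
        measured = tab[tab.segment == "AVG"].contrast_mean.iloc[0]
        assert measured == pytest.approx(expected, rel=0.10)

    def test_rotation_invariance(self):
        """ES and contrast move < 5% when image and geometry rotate together.

        Uses a smooth-edged circular pool so that the interpolation of the
        rotation itself does not blur the edge being measured."""
        n, dx = 112, 2.2
        ax = (np.arange(n) - n / 2) * dx
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        r = np.hypot(yy, xx)
        img = 0.1 + 0.9 / (1.0 + np.exp((r - 24.0) / 1.5))
        geom = SegmentGeometry(center=(0.0, 0.0), semi_axes=(24.0, 24.0),
                               reference_angle_deg=105.0)
        base = evaluate_slice(img, geom, sigma=0.02, pixel_spacing=2.2)
        base_avg = base[base.segment == "AVG"].iloc[0]
        for angle in (15.0, 30.0):
            rot_img = ndimage.rotate(img, angle, reshape=False, order=3)
            rot_geom = SegmentGeometry(
                center=geom.center, semi_axes=geom.semi_axes,
                reference_angle_deg=geom.reference_angle_deg + angle)
            tab = evaluate_slice(rot_img, rot_geom, sigma=0.02, pixel_spacing=2.2)
            avg = tab[tab.segment == "AVG"].iloc[0]
            assert avg.es_mean == pytest.approx(base_avg.es_mean, rel=0.05)
            assert avg.contrast_mean == pytest.approx(base_avg.contrast_mean, rel=0.05)


class TestBenjaminiHochberg:
    def brute_force(self, p, q):
        """Exhaustive step-up oracle: try every cutoff k and keep the largest
        admissible one."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        reject = np.zeros(m, bool)
        reject[order[:k_star]] = True
        return reject

    def test_boundary_case_all_rejected(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert benjamini_hochberg(p, q=0.05).all()

    def test_all_ones_none_rejected(self):
        assert not benjamini_hochberg(np.ones(10), q=0.05).any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            m = rng.integers(1, 20)
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.3:  # inject some near-threshold ties
                p = np.round(p, 2)
            q = rng.uniform(0.01, 0.2)
            assert np.array_equal(benjamini_hochberg(p, q), self.brute_force(p, q))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 30))
            ours = benjamini_hochberg(p, 0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, theirs)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_q(self, p):
        r1 = benjamini_hochberg(p, q=0.02)
        r2 = benjamini_hochberg(p, q=0.10)
        assert np.all(r2 | ~r1)  # everything rejected at q=0.02 stays rejected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
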