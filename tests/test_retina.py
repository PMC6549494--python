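"""Retina stage: space-variant blur, contrast gain, ON/OFF, log-polar map."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from crowdsim import retina as ret
from crowdsim import stimuli as stim

from .conftest import bar_scene


def _impulse_scene(ecc_deg, geometry):
    img = np.full(geometry.shape, 0.0)
    r = geometry.fixation[0]
    c = int(round(geometry.col_of(ecc_deg)))
    img[r, c] = 1.0
    return stim.VisualScene(img, geometry.deg_per_pixel, geometry.fixation)


class TestEccentricityBlur:
    def test_constant_image_unchanged(self, geometry, retina_params):
        scene = stim.VisualScene(np.full(geometry.shape, 0.4),
                                 geometry.deg_per_pixel, geometry.fixation)
        out = ret.eccentricity_blur(scene, retina_params)
        assert np.allclose(out.pixels, 0.4, atol=1e-12)

    def test_zero_slope_equals_uniform_blur(self, geometry):
        params = ret.RetinaParams(blur_slope=0.0, sigma0_deg=0.1)
        scene = bar_scene(4.0, geometry)
        out = ret.eccentricity_blur(scene, params)
        expected = gaussian_filter(scene.pixels, 0.1 / geometry.deg_per_pixel,
                                   mode="reflect")
        assert np.allclose(out.pixels, np.clip(expected, 0, 1), atol=1e-10)

    def test_peripheral_impulse_spreads_more(self, geometry, retina_params):
        """Oracle: direct convolution with the local Gaussian at each site."""
        moments = {}
        for ecc in (2.0, 8.0):
            out = ret.eccentricity_blur(_impulse_scene(ecc, geometry),
                                        retina_params)
            rr, cc = np.indices(out.shape)
            w = out.pixels / out.pixels.sum()
            r0 = (w * rr).sum()
            c0 = (w * cc).sum()
            moments[ecc] = (w * ((rr - r0) ** 2 + (cc - c0) ** 2)).sum()
            # direct space-variant oracle at the impulse site: the response
            # is the site's own Gaussian kernel, second moment 2*sigma^2
            sigma_px = (retina_params.sigma0_deg
                        + retina_params.blur_slope * ecc) / geometry.deg_per_pixel
            assert moments[ecc] == pytest.approx(2 * sigma_px ** 2, rel=0.15)
        assert moments[8.0] > moments[2.0]


class TestContrastGain:
    def test_constant_image_gives_zero(self, geometry, retina_params):
        scene = stim.VisualScene(np.full(geometry.shape, 0.7),
                                 geometry.deg_per_pixel, geometry.fixation)
        resp = ret.contrast_gain(scene, retina_params)
        assert np.allclose(resp, 0.0, atol=1e-12)

    def test_response_is_compressive(self, geometry):
        """Closed form at one pixel: r = (x - mu) / (K + mu)."""
        params = ret.RetinaParams(gain_semisaturation=0.3)
        base = np.full(geometry.shape, 0.5)
        r, c = geometry.fixation[0], int(geometry.col_of(4.0))
        lo, hi = base.copy(), base.copy()
        lo[r, c] = 0.6
        hi[r, c] = 0.7  # doubled increment
        resp_lo = ret.contrast_gain(
            stim.VisualScene(lo, geometry.deg_per_pixel, geometry.fixation),
            params)[r, c]
        resp_hi = ret.contrast_gain(
            stim.VisualScene(hi, geometry.deg_per_pixel, geometry.fixation),
            params)[r, c]
        assert resp_hi < 2 * resp_lo
        mu = gaussian_filter(lo, params.gain_pool_deg / geometry.deg_per_pixel,
                             mode="reflect")[r, c]
        assert resp_lo == pytest.approx((0.6 - mu) / (0.3 + mu), rel=1e-9)

    def test_large_semisaturation_limit_is_linear(self, geometry):
        params = ret.RetinaParams(gain_semisaturation=1e9)
        scene = bar_scene(4.0, geometry)
        resp = ret.contrast_gain(scene, params)
        mu = gaussian_filter(scene.pixels,
                            params.gain_pool_deg / geometry.deg_per_pixel,
                            mode="reflect")
        assert np.allclose(resp * 1e9, scene.pixels - mu, atol=1e-5)


class TestDogGanglion:
    def test_uniform_image_silent(self, retina_params):
        on, off = ret.dog_ganglion(np.full((32, 32), 0.3), retina_params, 0.02)
        assert np.allclose(on, 0.0, atol=1e-12)
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_dark_bar_drives_off_center_cells(self, geometry, retina_params):
        scene = bar_scene(4.0, geometry)
        contrast = ret.contrast_gain(scene, retina_params)
        on, off = ret.dog_ganglion(contrast, retina_params,
                                   geometry.deg_per_pixel)
        r = geometry.fixation[0]
        c = int(round(geometry.col_of(4.0)))
        assert off[r, c] > 0 and on[r, c] == 0
        # ON cells flank the bar borders
        assert on[r, c - 6:c + 7].max() > 0

    def test_polarity_swaps_under_intensity_inversion(self, retina_params):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        on_a, off_a = ret.dog_ganglion(img, retina_params, 0.02)
        on_b, off_b = ret.dog_ganglion(-img, retina_params, 0.02)
        assert np.allclose(on_a, off_b, atol=1e-12)
        assert np.allclose(off_a, on_b, atol=1e-12)


class TestLogPolar:
    def test_magnification_shrinks_peripheral_footprints(self, geometry,
                                                         retina_params):
        footprints = []
        for ecc in (2.0, 4.0, 8.0):
            retinal = ret.retina_pipeline(bar_scene(ecc, geometry),
                                          retina_params)
            act = retinal.on + retinal.off
            footprints.append(int((act > act.max() / 2.0).sum()))
        assert footprints[0] > footprints[1] > footprints[2]

    def test_foveal_feature_maps_to_left_edge(self, geometry, vernier_retina):
        cmap = vernier_retina.coords
        _, u = cmap.forward(geometry.fixation[0], geometry.fixation[1] + 1)
        assert u < cmap.cortical_shape[1] * 0.1

    def test_roundtrip_within_one_cortical_pixel(self, vernier_retina,
                                                 geometry):
        cmap = vernier_retina.coords
        rows = np.linspace(60, 300, 10)
        cols = np.linspace(60, 680, 10)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        v, u = cmap.forward(rr.ravel(), cc.ravel())
        ok = (v >= 0) & (v < cmap.shape[0]) & (u >= 0) & (u < cmap.shape[1])
        r2, c2 = cmap.inverse(np.rint(v[ok]), np.rint(u[ok]))
        v2, u2 = cmap.forward(r2, c2)
        err = np.hypot(v2 - np.rint(v[ok]), u2 - np.rint(u[ok]))
        assert err.max() <= 1.0

    def test_pipeline_is_deterministic(self, geometry, retina_params):
        scene = bar_scene(4.0, geometry)
        a = ret.retina_pipeline(scene, retina_params)
        b = ret.retina_pipeline(scene, retina_params)
        assert np.array_equal(a.on, b.on)
        assert np.array_equal(a.off, b.off)

    def test_on_off_are_rectified_complements(self, geometry, retina_params,
                                              vernier_scene, vernier_retina):
        # exact complementarity before the cortical resampling
        blurred = ret.eccentricity_blur(vernier_scene, retina_params)
        contrast = ret.contrast_gain(blurred, retina_params)
        on, off = ret.dog_ganglion(contrast, retina_params,
                                   geometry.deg_per_pixel)
        assert np.minimum(on, off).max() == 0.0
        # after preimage averaging only marginal mixing remains
        overlap = np.minimum(vernier_retina.on, vernier_retina.off)
        peak = max(vernier_retina.on.max(), vernier_retina.off.max())
        assert overlap.max() <= 0.05 * peak


class TestCropToRoi:
    def test_full_scene_crop_is_identity(self, vernier_retina, geometry):
        h, w = geometry.shape
        cropped = ret.crop_to_roi(vernier_retina, (0, h, 0, w))
        assert cropped.on.shape == vernier_retina.on.shape
        assert np.array_equal(cropped.on, vernier_retina.on)

    def test_stimulus_activity_preserved(self, vernier_retina, vernier_scene,
                                         geometry):
        t = vernier_scene.meta["boxes"]["target"]
        m = int(geometry.px(0.8))
        bbox = (t[0] - m, t[1] + m, t[2] - m, t[3] + m)
        cropped = ret.crop_to_roi(vernier_retina, bbox)
        assert cropped.on.size < vernier_retina.on.size
        # activity inside the stimulus preimage survives the crop
        total = cropped.on.sum() + cropped.off.sum()
        assert total > 0.5 * (vernier_retina.on.sum() + vernier_retina.off.sum())
        # inverse stays correct after the crop offset
        peak = np.unravel_index(np.argmax(cropped.off), cropped.off.shape)
        r, c = cropped.coords.inverse(float(peak[0]), float(peak[1]))
        assert t[0] - m <= r <= t[1] + m and t[2] - m <= c <= t[3] + m

    def test_disjoint_bbox_rejected(self, vernier_retina):
        with pytest.raises(ValueError):
            ret.crop_to_roi(vernier_retina, (0, 1, 0, 1))


class TestBypass:
    def test_bypass_channels_split_contrast(self, vernier_scene):
        retinal = ret.bypass_retina(vernier_scene)
        assert (retinal.off > 0).any()        # dark stimulus drives OFF
        assert retinal.on.max() <= retinal.off.max()
        r, c = retinal.coords.inverse(10.0, 20.0)
        v, u = retinal.coords.forward(r, c)
        assert np.isclose(v, 10.0) and np.isclose(u, 20.0)
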