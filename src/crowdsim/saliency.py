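"""Saliency as a sampling density for covert selection.

The pipeline consumes saliency only as a probability density over scene
pixels from which one selection-signal location is drawn per trial.  For a
single high-contrast stimulus on a blank screen any contrast-based model
concentrates its mass on the stimulus, so a classical multi-scale
center-surround contrast map with a Gaussian central bias serves here; it is
pluggable behind :class:`SaliencyMap` so a learned model could be swapped in.
Saliency always operates on the undistorted scene, never on the retina
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .stimuli import VisualScene

__all__ = [
    "SaliencyParams",
    "SaliencyMap",
    "contrast_saliency",
    "gaussian_fallback",
    "sample_location",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class SaliencyParams:
    scales_deg: tuple[float, ...] = (0.05, 0.1)
    smooth_sigma_deg: float = 0.05
    bias_sigma_deg: float = 6.0
    fallback_sigma_deg: float = 0.23


@dataclass
class SaliencyMap:
    """Nonnegative density over scene pixels, summing to one."""

    density: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.density, dtype=float)
        if (d < 0).any():
            raise ValueError("saliency density must be nonnegative")
        if abs(d.sum() - 1.0) > _NORM_TOL:
            raise ValueError("saliency density must sum to 1")
        self.density = d
        self._cdf = None

    def cdf(self) -> np.ndarray:
        if self._cdf is None:
            self._cdf = np.cumsum(self.density.ravel())
        return self._cdf


def _central_bias(shape, sigma_px: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    r0 = (shape[0] - 1) / 2.0
    c0 = (shape[1] - 1) / 2.0
    return np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px ** 2))


def contrast_saliency(scene: VisualScene,
                      params: SaliencyParams | None = None) -> SaliencyMap:
    """Multi-scale center-surround contrast energy with a central bias.

    For each scale s the band energy |G(s) - G(2s)| is accumulated, smoothed,
    multiplied by a Gaussian central-bias window centered on the scene
    center, and normalized to sum one.  A blank scene (zero contrast energy)
    falls back to the normalized bias window alone.
    """
    params = params or SaliencyParams()
    x = scene.pixels
    dpp = scene.deg_per_pixel
    energy = np.zeros_like(x)
    for s_deg in params.scales_deg:
        s = s_deg / dpp
        energy += np.abs(gaussian_filter(x, s, mode="reflect")
                         - gaussian_filter(x, 2.0 * s, mode="reflect"))
    energy = gaussian_filter(energy, params.smooth_sigma_deg / dpp, mode="reflect")
    bias = _central_bias(x.shape, params.bias_sigma_deg / dpp)
    raw = energy * bias
    total = raw.sum()
    if total <= 1e-12:
        raw = bias
        total = raw.sum()
    return SaliencyMap(raw / total)


def gaussian_fallback(scene: VisualScene, center: tuple[float, float],
                      sigma_deg: float) -> SaliencyMap:
    """Isotropic Gaussian density at a fixed scene location.

    This is the saliency-ablation mode: selection signals are drawn from a
    two-dimensional Gaussian centered on a chosen location instead of the
    saliency output.
    """
    r0, c0 = center
    h, w = scene.shape
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("fallback center must lie inside the grid")
    s = sigma_deg / scene.deg_per_pixel
    rr, cc = np.indices(scene.shape)
    raw = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * s * s))
    return SaliencyMap(raw / raw.sum())


def sample_location(smap: SaliencyMap, rng: np.random.Generator
                    ) -> tuple[int, int]:
    """Draw one scene pixel with probability equal to the density."""
    idx = int(np.searchsorted(smap.cdf(), rng.random(), side="right"))
    idx = min(idx, smap.density.size - 1)
    return np.unravel_index(idx, smap.density.shape)
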