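"""Space-variant retina stage.

Four sub-stages, applied in order:

1. :func:`eccentricity_blur` — Gaussian pooling whose width grows linearly
   with eccentricity, sigma(e) = sigma0 + blur_slope * e.  This emulates the
   coarser spatial integration of peripheral retina.
2. :func:`contrast_gain` — steady-state divisive contrast normalization,
   r = (x - mu) / (K + mu) with mu a wide local mean.  The temporal feedback
   loops of a dynamical retina reduce to this fixed point for static scenes.
3. :func:`dog_ganglion` — X-cell-style center-surround difference of
   Gaussians, split into half-rectified ON (bright-center) and OFF
   (dark-center) channels.
4. :func:`logpolar_transform` — complex-log retinotopic mapping centered on
   fixation: cortical column ~ log(e + a), cortical row ~ polar angle.  The
   foveal field is magnified, the periphery compressed, which is the model's
   only source of inward-outward asymmetry.

All convolutions use reflect padding; this affects only the grid margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .stimuli import VisualScene

__all__ = [
    "RetinaParams",
    "CoordinateMap",
    "RetinalImage",
    "eccentricity_blur",
    "contrast_gain",
    "dog_ganglion",
    "logpolar_transform",
    "crop_to_roi",
    "retina_pipeline",
]


@dataclass(frozen=True)
class RetinaParams:
    """Tunable retina parameters (angular units in degrees).

    Defaults keep the 3.89-deg Vernier resolvable while degrading 10-deg
    stimuli, which is the regime the simulated experiments probe.
    """

    sigma0_deg: float = 0.03        # foveal pooling width
    blur_slope: float = 0.02        # pooling growth per degree of eccentricity
    dog_center_deg: float = 0.04    # ganglion RF center width
    dog_surround_deg: float = 0.16  # ganglion RF surround width
    gain_semisaturation: float = 0.3
    gain_pool_deg: float = 1.0      # width of the local-mean pool
    logpolar_a: float = 0.5         # shift constant of the complex-log map
    cortical_shape: tuple[int, int] = (96, 192)
    polar_range_deg: float = 60.0   # half-range of polar angle on the rows
    n_blur_levels: int = 8

    def __post_init__(self):
        if min(self.sigma0_deg, self.dog_center_deg, self.dog_surround_deg) <= 0:
            raise ValueError("all widths must be > 0")
        if self.dog_surround_deg <= self.dog_center_deg:
            raise ValueError("dog_surround_deg must exceed dog_center_deg")
        if self.logpolar_a <= 0:
            raise ValueError("logpolar_a must be > 0")


# ---------------------------------------------------------------------------
# coordinate map


@dataclass
class CoordinateMap:
    """Invertible scene <-> cortical mapping of the complex-log transform.

    ``forward`` maps scene pixel coordinates (row, col) to continuous cortical
    coordinates (v, u) where u grows with log(e + a) and v with polar angle;
    ``inverse`` is its analytic inverse.  A crop offset supports ROI views.
    """

    fixation: tuple[float, float]
    deg_per_pixel: float
    logpolar_a: float
    cortical_shape: tuple[int, int]
    e_max_deg: float
    polar_range_deg: float
    origin: tuple[int, int] = (0, 0)  # crop offset of this view, cortical px
    shape: tuple[int, int] = None     # shape of this (possibly cropped) view

    def __post_init__(self):
        if self.shape is None:
            self.shape = tuple(self.cortical_shape)
        rows, cols = self.cortical_shape
        a = self.logpolar_a
        self._ku = np.log((self.e_max_deg + a) / a) / (cols - 1)
        self._kv = 2.0 * np.radians(self.polar_range_deg) / (rows - 1)

    # -- continuous maps ----------------------------------------------------
    def forward(self, row, col):
        """Scene pixel (row, col) -> cortical (v, u), floats."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        dy = (row - self.fixation[0]) * self.deg_per_pixel
        dx = (col - self.fixation[1]) * self.deg_per_pixel
        e = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx)
        a = self.logpolar_a
        u = np.log((e + a) / a) / self._ku
        v = (theta + np.radians(self.polar_range_deg)) / self._kv
        return v - self.origin[0], u - self.origin[1]

    def inverse(self, v, u):
        """Cortical (v, u) -> scene pixel (row, col), floats."""
        v = np.asarray(v, dtype=float) + self.origin[0]
        u = np.asarray(u, dtype=float) + self.origin[1]
        a = self.logpolar_a
        e = a * np.exp(u * self._ku) - a
        theta = v * self._kv - np.radians(self.polar_range_deg)
        r = self.fixation[0] + e * np.sin(theta) / self.deg_per_pixel
        c = self.fixation[1] + e * np.cos(theta) / self.deg_per_pixel
        return r, c

    def in_domain(self, row, col):
        """Scene pixels whose polar angle and eccentricity are represented."""
        v, u = self.forward(row, col)
        rows, cols = self.shape
        return (v >= -0.5) & (v < rows - 0.5) & (u >= -0.5) & (u < cols - 0.5)

    def jacobian_area(self):
        """Scene area (deg^2) represented by each cortical pixel of this view."""
        rows, cols = self.shape
        u = np.arange(cols) + self.origin[1]
        a = self.logpolar_a
        e = a * np.exp(u * self._ku) - a
        de_du = (e + a) * self._ku
        arc = np.maximum(e, self.deg_per_pixel) * self._kv
        return np.broadcast_to(de_du * arc, (rows, cols)).copy()

    def scene_px_per_cortical_px(self, eccentricity_deg: float) -> float:
        """Local radial scale of the map (scene pixels per cortical column)."""
        return ((eccentricity_deg + self.logpolar_a) * self._ku
                / self.deg_per_pixel)

    def to_dict(self) -> dict:
        return {
            "fixation": list(self.fixation),
            "deg_per_pixel": self.deg_per_pixel,
            "logpolar_a": self.logpolar_a,
            "cortical_shape": list(self.cortical_shape),
            "e_max_deg": self.e_max_deg,
            "polar_range_deg": self.polar_range_deg,
            "origin": list(self.origin),
            "shape": list(self.shape),
        }


class IdentityCoordinateMap(CoordinateMap):
    """Uniformly scaled scene coordinates (retina-bypass mode).

    The bypass feeds the camera image to the grouping stage resampled to the
    cortical grid's average sampling density, so one bypass pixel covers
    ``scale`` scene pixels everywhere and the grouping stage keeps its
    native pixel-denominated parameters.
    """

    def __init__(self, scene_shape, fixation, deg_per_pixel, scale=1,
                 origin=(0, 0), shape=None):
        self.fixation = tuple(fixation)
        self.deg_per_pixel = deg_per_pixel
        self.logpolar_a = 1.0
        self.scale = int(scale)
        self.cortical_shape = (scene_shape[0] // self.scale,
                               scene_shape[1] // self.scale)
        self.e_max_deg = deg_per_pixel * max(scene_shape)
        self.polar_range_deg = 180.0
        self.origin = tuple(origin)
        self.shape = tuple(shape) if shape is not None else self.cortical_shape

    def forward(self, row, col):
        return (np.asarray(row, dtype=float) / self.scale - self.origin[0],
                np.asarray(col, dtype=float) / self.scale - self.origin[1])

    def inverse(self, v, u):
        return ((np.asarray(v, dtype=float) + self.origin[0]) * self.scale,
                (np.asarray(u, dtype=float) + self.origin[1]) * self.scale)

    def in_domain(self, row, col):
        v, u = self.forward(row, col)
        rows, cols = self.shape
        return (v >= -0.5) & (v < rows - 0.5) & (u >= -0.5) & (u < cols - 0.5)

    def jacobian_area(self):
        return np.full(self.shape, (self.scale * self.deg_per_pixel) ** 2)

    def scene_px_per_cortical_px(self, eccentricity_deg: float) -> float:
        return float(self.scale)


@dataclass
class RetinalImage:
    """ON/OFF ganglion activity in cortical coordinates plus the map."""

    on: np.ndarray
    off: np.ndarray
    coords: CoordinateMap
    params: RetinaParams | None = None

    def __post_init__(self):
        if self.on.shape != self.off.shape:
            raise ValueError("on and off channels must share shape")
        if (self.on < 0).any() or (self.off < 0).any():
            raise ValueError("ganglion activities must be nonnegative")


# ---------------------------------------------------------------------------
# stage 1: space-variant blur


def _eccentricity_grid(scene: VisualScene) -> np.ndarray:
    rr, cc = np.indices(scene.shape)
    dy = (rr - scene.fixation[0]) * scene.deg_per_pixel
    dx = (cc - scene.fixation[1]) * scene.deg_per_pixel
    return np.hypot(dx, dy)


def eccentricity_blur(scene: VisualScene, params: RetinaParams) -> VisualScene:
    """Gaussian pooling with width sigma(e) = sigma0 + blur_slope * e.

    Implemented by blending a small bank of uniform Gaussian blurs: each
    pixel interpolates linearly (in sigma) between the two bank levels that
    bracket its own sigma(e).  With blur_slope = 0 the bank degenerates to a
    single level and the operation is an exact uniform blur.
    """
    ecc = _eccentricity_grid(scene)
    sigma_px = (params.sigma0_deg + params.blur_slope * ecc) / scene.deg_per_pixel

    lo, hi = float(sigma_px.min()), float(sigma_px.max())
    if np.isclose(lo, hi):
        out = gaussian_filter(scene.pixels, lo, mode="reflect")
    else:
        levels = np.geomspace(lo, hi, params.n_blur_levels)
        stack = np.stack([gaussian_filter(scene.pixels, s, mode="reflect")
                          for s in levels])
        idx = np.clip(np.searchsorted(levels, sigma_px), 1, len(levels) - 1)
        s0, s1 = levels[idx - 1], levels[idx]
        w = (sigma_px - s0) / (s1 - s0)
        rows, cols = np.indices(scene.shape)
        out = (1 - w) * stack[idx - 1, rows, cols] + w * stack[idx, rows, cols]
    out = np.clip(out, 0.0, 1.0)
    return replace_scene(scene, out)


def replace_scene(scene: VisualScene, pixels: np.ndarray) -> VisualScene:
    return VisualScene(pixels, scene.deg_per_pixel, scene.fixation,
                       meta=dict(scene.meta))


# ---------------------------------------------------------------------------
# stage 2: contrast gain


def contrast_gain(scene: VisualScene, params: RetinaParams) -> np.ndarray:
    """Steady-state divisive normalization, (x - mu) / (K + mu).

    ``mu`` is a wide Gaussian local mean (``gain_pool_deg``).  The output is
    a signed contrast map bounded by 1/K in magnitude; a constant input maps
    to exactly zero.
    """
    x = scene.pixels
    mu = gaussian_filter(x, params.gain_pool_deg / scene.deg_per_pixel,
                         mode="reflect")
    return (x - mu) / (params.gain_semisaturation + mu)


# ---------------------------------------------------------------------------
# stage 3: ON/OFF ganglion cells


def dog_ganglion(contrast: np.ndarray, params: RetinaParams,
                 deg_per_pixel: float) -> tuple[np.ndarray, np.ndarray]:
    """Center-surround DoG followed by half-rectification into ON and OFF."""
    c = gaussian_filter(contrast, params.dog_center_deg / deg_per_pixel,
                        mode="reflect")
    s = gaussian_filter(contrast, params.dog_surround_deg / deg_per_pixel,
                        mode="reflect")
    d = c - s
    return np.maximum(d, 0.0), np.maximum(-d, 0.0)


# ---------------------------------------------------------------------------
# stage 4: log-polar cortical mapping


def _resample_to_cortical(channel: np.ndarray, cmap: CoordinateMap) -> np.ndarray:
    """Average scene pixels over each cortical pixel's preimage.

    Cortical pixels with an empty preimage (the magnified fovea, where the
    cortical grid is finer than the scene grid) are filled by bilinear
    sampling at the analytic inverse location.
    """
    rows, cols = cmap.cortical_shape
    rr, cc = np.indices(channel.shape)
    v, u = cmap.forward(rr, cc)
    vi = np.rint(v).astype(int)
    ui = np.rint(u).astype(int)
    valid = (vi >= 0) & (vi < rows) & (ui >= 0) & (ui < cols)
    flat = vi[valid] * cols + ui[valid]
    sums = np.bincount(flat, weights=channel[valid], minlength=rows * cols)
    counts = np.bincount(flat, minlength=rows * cols)
    out = np.zeros(rows * cols)
    hit = counts > 0
    out[hit] = sums[hit] / counts[hit]
    out = out.reshape(rows, cols)

    holes = ~hit.reshape(rows, cols)
    if holes.any():
        hv, hu = np.nonzero(holes)
        r, c = cmap.inverse(hv.astype(float), hu.astype(float))
        inside = (r >= 0) & (r <= channel.shape[0] - 1) & \
                 (c >= 0) & (c <= channel.shape[1] - 1)
        vals = np.zeros(len(hv))
        if inside.any():
            vals[inside] = map_coordinates(channel,
                                           [r[inside], c[inside]],
                                           order=1, mode="nearest")
        out[hv, hu] = vals
    return out


def logpolar_transform(on_scene: np.ndarray, off_scene: np.ndarray,
                       scene: VisualScene, params: RetinaParams) -> RetinalImage:
    """Map ON/OFF scene activity into log-polar cortical coordinates."""
    rows, cols = params.cortical_shape
    if rows < 4 or cols < 4:
        raise ValueError("cortical_shape too small for an injective mapping")
    e_max = scene.deg_per_pixel * (scene.shape[1] - scene.fixation[1])
    cmap = CoordinateMap(
        fixation=scene.fixation, deg_per_pixel=scene.deg_per_pixel,
        logpolar_a=params.logpolar_a, cortical_shape=(rows, cols),
        e_max_deg=e_max, polar_range_deg=params.polar_range_deg)
    on = _resample_to_cortical(on_scene, cmap)
    off = _resample_to_cortical(off_scene, cmap)
    return RetinalImage(on, off, cmap, params)


def crop_to_roi(retinal: RetinalImage, scene_bbox: tuple[int, int, int, int]
                ) -> RetinalImage:
    """Restrict both channels to the cortical image of a scene bounding box.

    ``scene_bbox`` is (r0, r1, c0, c1) in scene pixels (half-open).  The
    returned view's CoordinateMap carries the crop offset so that forward and
    inverse remain correct.
    """
    r0, r1, c0, c1 = scene_bbox
    cmap = retinal.coords
    rows, cols = cmap.shape

    if isinstance(cmap, IdentityCoordinateMap):
        corners_r = np.array([r0, r0, r1 - 1, r1 - 1], dtype=float)
        corners_c = np.array([c0, c1 - 1, c0, c1 - 1], dtype=float)
        v, u = cmap.forward(corners_r, corners_c)
    else:
        # u depends only on eccentricity: use the analytic distance range
        # from fixation to the rectangle (a probe lattice cannot resolve the
        # fovea, where the log map is steepest)
        fr, fc = cmap.fixation
        near_r = min(max(fr, r0), r1 - 1)
        near_c = min(max(fc, c0), c1 - 1)
        ext_r = np.array([near_r, r0, r0, r1 - 1, r1 - 1], dtype=float)
        ext_c = np.array([near_c, c0, c1 - 1, c0, c1 - 1], dtype=float)
        # polar angle: dense samples along the rectangle boundary, plus the
        # interior point nearest fixation
        t = np.linspace(0.0, 1.0, 257)
        edge_r = np.concatenate([np.full_like(t, r0), np.full_like(t, r1 - 1),
                                 r0 + t * (r1 - 1 - r0),
                                 r0 + t * (r1 - 1 - r0), ext_r])
        edge_c = np.concatenate([c0 + t * (c1 - 1 - c0),
                                 c0 + t * (c1 - 1 - c0),
                                 np.full_like(t, c0), np.full_like(t, c1 - 1),
                                 ext_c])
        if r0 <= fr < r1 and c0 <= fc < c1:
            edge_r = np.append(edge_r, fr + 0.5)
            edge_c = np.append(edge_c, fc + 0.5)
        v, u = cmap.forward(edge_r, edge_c)

    inside = (v >= 0) & (v < rows) & (u >= 0) & (u < cols)
    if not inside.any():
        raise ValueError("scene_bbox does not intersect the represented field")
    v0 = int(np.floor(max(v[inside].min(), 0)))
    v1 = int(np.ceil(min(v[inside].max(), rows - 1))) + 1
    u0 = int(np.floor(max(u[inside].min(), 0)))
    u1 = int(np.ceil(min(u[inside].max(), cols - 1))) + 1

    if isinstance(cmap, IdentityCoordinateMap):
        sub = IdentityCoordinateMap(
            (cmap.cortical_shape[0] * cmap.scale,
             cmap.cortical_shape[1] * cmap.scale),
            cmap.fixation, cmap.deg_per_pixel, scale=cmap.scale,
            origin=(cmap.origin[0] + v0, cmap.origin[1] + u0),
            shape=(v1 - v0, u1 - u0))
    else:
        sub = CoordinateMap(cmap.fixation, cmap.deg_per_pixel, cmap.logpolar_a,
                            cmap.cortical_shape, cmap.e_max_deg,
                            cmap.polar_range_deg,
                            origin=(cmap.origin[0] + v0, cmap.origin[1] + u0),
                            shape=(v1 - v0, u1 - u0))
    return RetinalImage(retinal.on[v0:v1, u0:u1].copy(),
                        retinal.off[v0:v1, u0:u1].copy(),
                        sub, retinal.params)


# ---------------------------------------------------------------------------
# full stage


def retina_pipeline(scene: VisualScene, params: RetinaParams | None = None
                    ) -> RetinalImage:
    """Run blur -> contrast gain -> DoG -> log-polar on a scene."""
    params = params or RetinaParams()
    blurred = eccentricity_blur(scene, params)
    contrast = contrast_gain(blurred, params)
    on, off = dog_ganglion(contrast, params, scene.deg_per_pixel)
    return logpolar_transform(on, off, scene, params)


def bypass_retina(scene: VisualScene,
                  cortical_cols: int = 192) -> RetinalImage:
    """Retina-ablation mode: the scene feeds the grouping stage directly.

    The camera image is block-averaged down to the cortical grid's mean
    column density (uniform, no magnification, no blur gradient); ON carries
    bright-excess contrast relative to the background level and OFF carries
    dark-excess contrast.
    """
    e_max = scene.deg_per_pixel * (scene.shape[1] - scene.fixation[1])
    scale = max(1, int(e_max / (cortical_cols * scene.deg_per_pixel)))
    h, w = (scene.shape[0] // scale) * scale, (scene.shape[1] // scale) * scale
    blocks = scene.pixels[:h, :w].reshape(h // scale, scale,
                                          w // scale, scale).mean(axis=(1, 3))
    b = float(np.median(blocks))
    on = np.maximum(blocks - b, 0.0)
    off = np.maximum(b - blocks, 0.0)
    cmap = IdentityCoordinateMap(scene.shape, scene.fixation,
                                 scene.deg_per_pixel, scale=scale)
    return RetinalImage(on, off, cmap, None)
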