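"""Procedural stimulus rendering for the crowding experiments.

Renders calibrated grayscale scenes for three paradigms:

* ``exp1b`` — a Vernier target (two nearly collinear vertical segments) at a
  fixed eccentricity of 3.89 deg in the right visual field, optionally flanked
  by a single short bar on the foveal ("inner") or peripheral ("outer") side.
* ``exp5`` — a two-tone face-proxy patch at 3, 6 or 10 deg of eccentricity,
  optionally flanked by an identical patch placed inner or outer.
* ``squares_demo`` — a row of outlined squares with the Vernier inside the
  central square, the classic uncrowding display.

All geometry is specified in degrees of visual angle and converted to pixels
through a single isotropic calibration (``deg_per_pixel``).  Eccentricity is
measured along the horizontal from the fixation column; the fixation point
sits on the vertical midline near the left edge of the grid so that the right
visual field up to ~12.5 deg is on screen.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SceneGeometry",
    "StimulusSpec",
    "VisualScene",
    "StimulusGeometryError",
    "render_vernier",
    "render_face_proxy",
    "render_square_array",
    "render_scene",
    "condition_table",
]

#: Internal seed for the frozen two-tone proxy pattern.  The same pattern is
#: used for the target and the flanker so conditions differ only in geometry.
_FACE_PATTERN_SEED = 20230517

BACKGROUND = 0.9
FOREGROUND = 0.1


class StimulusGeometryError(ValueError):
    """Raised when a stimulus element would fall outside the scene grid."""


@dataclass(frozen=True)
class SceneGeometry:
    """Scene grid, calibration and fixation anchor.

    The default 360x640 grid at 0.02 deg/px spans 12.8 deg horizontally,
    which covers the 10 deg eccentricity of exp5 plus an outer flanker with
    margin.
    """

    shape: tuple[int, int] = (360, 704)
    deg_per_pixel: float = 0.02
    fixation: tuple[int, int] = (180, 10)

    def px(self, deg: float) -> float:
        return deg / self.deg_per_pixel

    def col_of(self, eccentricity_deg: float) -> float:
        return self.fixation[1] + self.px(eccentricity_deg)


@dataclass(frozen=True)
class StimulusSpec:
    """One experimental condition (geometry only; no pixels)."""

    experiment_id: str
    eccentricity_deg: float
    flanker: str = "none"  # none | inner | outer
    vernier_offset_deg: float = 0.0167
    target_size_deg: float = 0.6
    flanker_gap_deg: float = 0.94
    flanker_size_deg: float = 0.4
    bar_width_deg: float = 0.04
    n_squares: int = 5
    square_size_deg: float = 1.0
    square_gap_deg: float = 1.4

    def __post_init__(self):
        if self.experiment_id not in {"exp1b", "exp5", "squares_demo"}:
            raise ValueError(f"unknown experiment_id {self.experiment_id!r}")
        if self.flanker not in {"none", "inner", "outer"}:
            raise ValueError(f"unknown flanker {self.flanker!r}")
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity_deg must be >= 0")
        if self.target_size_deg <= 0 or self.flanker_gap_deg <= 0:
            raise ValueError("sizes and gaps must be > 0")

    @property
    def label(self) -> str:
        return f"{self.experiment_id}_ecc{self.eccentricity_deg:g}_{self.flanker}"

    def flanker_eccentricity(self) -> float:
        if self.flanker == "inner":
            return self.eccentricity_deg - self.flanker_gap_deg
        if self.flanker == "outer":
            return self.eccentricity_deg + self.flanker_gap_deg
        raise ValueError("unflanked condition has no flanker eccentricity")


@dataclass
class VisualScene:
    """Grayscale stimulus image with angular calibration and fixation anchor."""

    pixels: np.ndarray
    deg_per_pixel: float
    fixation: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("scene intensities must lie in [0, 1]")
        r, c = self.fixation
        if not (0 <= r < self.pixels.shape[0] and 0 <= c < self.pixels.shape[1]):
            raise ValueError("fixation must lie inside the grid")
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save(self, path: str | Path) -> None:
        """Write an 8-bit grayscale PNG plus a JSON sidecar with calibration."""
        import imageio.v3 as iio

        path = Path(path)
        iio.imwrite(path, (self.pixels * 255).round().astype(np.uint8))
        sidecar = {
            "deg_per_pixel": self.deg_per_pixel,
            "fixation": list(self.fixation),
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# rasterization helpers


def _blank(geom: SceneGeometry) -> np.ndarray:
    return np.full(geom.shape, BACKGROUND, dtype=float)


def _check_rect(geom: SceneGeometry, name: str, r0: int, r1: int, c0: int, c1: int):
    h, w = geom.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r0 >= r1 or c0 >= c1:
        raise StimulusGeometryError(
            f"{name} with rows [{r0},{r1}) cols [{c0},{c1}) "
            f"falls outside the {h}x{w} grid"
        )


def _draw_rect(img, geom, name, *, center_rc, height_px, width_px, value=FOREGROUND):
    r, c = center_rc
    r0 = int(round(r - height_px / 2.0))
    r1 = r0 + max(1, int(round(height_px)))
    c0 = int(round(c - width_px / 2.0))
    c1 = c0 + max(1, int(round(width_px)))
    _check_rect(geom, name, r0, r1, c0, c1)
    img[r0:r1, c0:c1] = value
    return (r0, r1, c0, c1)


def _element_boxes(meta_boxes: dict, name: str, box):
    meta_boxes[name] = [int(v) for v in box]


# ---------------------------------------------------------------------------
# renderers


def render_vernier(spec: StimulusSpec, geom: SceneGeometry | None = None) -> VisualScene:
    """Render the Vernier-plus-bar display of the first crowding paradigm.

    The target is two vertical dark segments on a light background; the lower
    segment is displaced horizontally by ``vernier_offset_deg``.  An optional
    short bar flanks it on the foveal (inner) or peripheral (outer) side at a
    center-to-center distance of ``flanker_gap_deg``.
    """
    if spec.experiment_id != "exp1b" and spec.experiment_id != "squares_demo":
        raise ValueError("render_vernier expects an exp1b (or squares_demo) spec")
    geom = geom or SceneGeometry()
    img = _blank(geom)
    boxes: dict = {}

    fr = geom.fixation[0]
    tc = geom.col_of(spec.eccentricity_deg)
    seg_h = geom.px(spec.target_size_deg / 2.0)
    w = geom.px(spec.bar_width_deg)
    off = geom.px(spec.vernier_offset_deg)

    top = _draw_rect(img, geom, "vernier upper segment",
                     center_rc=(fr - seg_h / 2.0, tc), height_px=seg_h, width_px=w)
    bot = _draw_rect(img, geom, "vernier lower segment",
                     center_rc=(fr + seg_h / 2.0, tc + off), height_px=seg_h, width_px=w)
    _element_boxes(boxes, "target", (min(top[0], bot[0]), max(top[1], bot[1]),
                                     min(top[2], bot[2]), max(top[3], bot[3])))

    if spec.flanker != "none":
        fc = geom.col_of(spec.flanker_eccentricity())
        fb = _draw_rect(img, geom, f"{spec.flanker} flanker bar",
                        center_rc=(fr, fc), height_px=geom.px(spec.flanker_size_deg),
                        width_px=w)
        _element_boxes(boxes, "flanker", fb)

    return VisualScene(img, geom.deg_per_pixel, geom.fixation,
                       meta={"spec": spec, "boxes": boxes, "label": spec.label})


def face_proxy_patch(size_px: int, feature_px: float = 0.0) -> np.ndarray:
    """Frozen two-tone patch standing in for a Mooney face.

    A dark half-disc (a disc split by a vertical terminator, dark on the
    foveal side) on the light background: a deterministic two-tone shape
    whose boundary is a single closed contour, so the grouping stage
    represents it as one coherent object the way a face percept is one
    object.  The patch is synthetic: it carries no "face-ness", only
    two-tone shape statistics, and the identical patch serves as target and
    flanker so conditions differ only in geometry.
    """
    yy, xx = np.indices((size_px, size_px))
    r = (size_px - 1) / 2.0
    disc = (yy - r) ** 2 + (xx - r) ** 2 <= r * r
    dark = disc & (xx <= r)
    return np.where(dark, FOREGROUND, BACKGROUND)


def render_face_proxy(spec: StimulusSpec, geom: SceneGeometry | None = None,
                      feature_deg: float = 0.35) -> VisualScene:
    """Render the two-tone face-proxy display of the second paradigm.

    Target and flanker use the *same* frozen patch, so inner/outer conditions
    differ only by where the flanker sits.  Angular size is constant across
    eccentricities; only the retina stage magnifies.
    """
    if spec.experiment_id != "exp5":
        raise ValueError("render_face_proxy expects an exp5 spec")
    geom = geom or SceneGeometry()
    img = _blank(geom)
    boxes: dict = {}

    size_px = max(3, int(round(geom.px(spec.target_size_deg))))
    patch = face_proxy_patch(size_px, geom.px(feature_deg))

    def _paste(name, ecc):
        r = geom.fixation[0]
        c = geom.col_of(ecc)
        r0 = int(round(r - size_px / 2.0))
        c0 = int(round(c - size_px / 2.0))
        _check_rect(geom, name, r0, r0 + size_px, c0, c0 + size_px)
        img[r0:r0 + size_px, c0:c0 + size_px] = patch
        _element_boxes(boxes, "target" if name.startswith("target") else "flanker",
                       (r0, r0 + size_px, c0, c0 + size_px))

    _paste("target patch", spec.eccentricity_deg)
    if spec.flanker != "none":
        _paste(f"{spec.flanker} flanker patch", spec.flanker_eccentricity())

    return VisualScene(img, geom.deg_per_pixel, geom.fixation,
                       meta={"spec": spec, "boxes": boxes, "label": spec.label})


def render_square_array(n_squares: int, spec: StimulusSpec,
                        geom: SceneGeometry | None = None) -> VisualScene:
    """Render a row of outlined squares with the Vernier in the central one.

    A single square is the classic crowding display; five squares is the
    uncrowding display in which neighbouring squares can be tied together by
    illusory contours between their collinear horizontal edges.
    """
    if n_squares < 1 or n_squares % 2 == 0:
        raise ValueError("n_squares must be a positive odd integer")
    geom = geom or SceneGeometry()
    img = _blank(geom)
    boxes: dict = {}

    fr = geom.fixation[0]
    side = geom.px(spec.square_size_deg)
    lw = max(1, int(round(geom.px(spec.bar_width_deg))))
    half = int(round(side / 2.0))

    square_boxes = []
    for k in range(n_squares):
        idx = k - n_squares // 2
        ecc = spec.eccentricity_deg + idx * spec.square_gap_deg
        cc = int(round(geom.col_of(ecc)))
        r0, r1 = fr - half, fr + half
        c0, c1 = cc - half, cc + half
        _check_rect(geom, f"square {k}", r0, r1, c0, c1)
        img[r0:r0 + lw, c0:c1] = FOREGROUND
        img[r1 - lw:r1, c0:c1] = FOREGROUND
        img[r0:r1, c0:c0 + lw] = FOREGROUND
        img[r0:r1, c1 - lw:c1] = FOREGROUND
        square_boxes.append((r0, r1, c0, c1))

    # Vernier inside the central square
    vspec = dataclasses.replace(spec, experiment_id="squares_demo", flanker="none")
    tc = geom.col_of(spec.eccentricity_deg)
    seg_h = geom.px(spec.target_size_deg / 2.0)
    w = geom.px(spec.bar_width_deg)
    off = geom.px(spec.vernier_offset_deg)
    top = _draw_rect(img, geom, "vernier upper segment",
                     center_rc=(fr - seg_h / 2.0, tc), height_px=seg_h, width_px=w)
    bot = _draw_rect(img, geom, "vernier lower segment",
                     center_rc=(fr + seg_h / 2.0, tc + off), height_px=seg_h, width_px=w)
    _element_boxes(boxes, "target", (min(top[0], bot[0]), max(top[1], bot[1]),
                                     min(top[2], bot[2]), max(top[3], bot[3])))
    boxes["squares"] = [[int(v) for v in b] for b in square_boxes]

    return VisualScene(img, geom.deg_per_pixel, geom.fixation,
                       meta={"spec": vspec, "boxes": boxes,
                             "label": f"squares_{n_squares}"})


def render_scene(spec: StimulusSpec, geom: SceneGeometry | None = None) -> VisualScene:
    """Dispatch to the renderer for ``spec.experiment_id``."""
    if spec.experiment_id == "exp1b":
        return render_vernier(spec, geom)
    if spec.experiment_id == "exp5":
        return render_face_proxy(spec, geom)
    return render_square_array(spec.n_squares, spec, geom)


# ---------------------------------------------------------------------------
# condition tables

EXP1B_ECCENTRICITY = 3.89
EXP5_ECCENTRICITIES = (3.0, 6.0, 10.0)
FLANKER_CONFIGS = ("none", "inner", "outer")


def condition_table(experiment_id: str) -> list[StimulusSpec]:
    """All conditions of an experiment, in canonical order.

    exp1b: the three flanker configurations at 3.89 deg.
    exp5: three eccentricities (3, 6, 10 deg) x three flanker configurations.
    """
    if experiment_id == "exp1b":
        return [StimulusSpec("exp1b", EXP1B_ECCENTRICITY, flanker=f)
                for f in FLANKER_CONFIGS]
    if experiment_id == "exp5":
        return [StimulusSpec("exp5", ecc, flanker=f,
                             target_size_deg=1.5, flanker_gap_deg=2.2)
                for ecc in EXP5_ECCENTRICITIES for f in FLANKER_CONFIGS]
    if experiment_id == "squares_demo":
        return [StimulusSpec("squares_demo", EXP1B_ECCENTRICITY, n_squares=n)
                for n in (1, 5)]
    raise ValueError(f"unknown experiment_id {experiment_id!r}")
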