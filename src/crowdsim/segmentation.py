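"""Contour grouping and seeded segmentation.

The stage receives the retinal ON/OFF maps, extracts oriented edge elements,
links them into a contour graph (real links between adjacent co-oriented
elements, illusory links between collinear elements across gaps), and splits
the activity into two segmentation layers: a localized selection signal
(seed) recruits every connected component it touches into layer SL1; all
remaining activity stays in SL0.  A recurrent grouping circuit would reach
the same stable partition; here the stable state is computed in one shot,
which is this module's central simplification.

Per-trial variability enters through multiplicative activity noise: elements
near the node threshold flicker in and out of the graph, so whether the
target and a nearby flanker share a component is stochastic from trial to
trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from scipy.signal import fftconvolve
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _sparse_cc
from scipy.spatial import cKDTree

from .retina import RetinalImage

__all__ = [
    "SegmentationParams",
    "OrientationMap",
    "ContourGraph",
    "SelectionSignal",
    "SegmentationOutput",
    "extract_edges",
    "add_trial_noise",
    "complete_contours",
    "spread_segmentation",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Grouping-stage parameters (distances in cortical pixels)."""

    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    filter_sigma_long: float = 1.2    # oriented filter extent along the edge
    filter_sigma_short: float = 0.8   # extent across the edge
    saturation: float = 0.0           # response half-saturation, rel. to peak
    extract_threshold: float = 0.27   # relative to the map maximum
    node_threshold: float = 0.27     # relative to the map maximum
    gap_max: float = 8.0             # illusory-completion reach
    angle_tol_deg: float = 25.0      # collinearity tolerance
    noise_level: float = 0.2         # multiplicative trial noise
    seed_radius: float = 5.0         # selection-signal radius
    real_angle_tol_deg: float = 50.0  # orientation compatibility of adjacency


@dataclass
class OrientationMap:
    """Per-orientation edge activity over cortical coordinates.

    ``activity`` has shape (n_orientations, rows, cols); orientation angles
    are measured in degrees from vertical (0 = vertical edge elements).
    """

    activity: np.ndarray
    orientations_deg: tuple[float, ...]

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if (self.activity < 0).any():
            raise ValueError("orientation activity must be nonnegative")
        if self.activity.shape[0] != len(self.orientations_deg):
            raise ValueError("activity leading axis must match orientations")

    @property
    def shape(self):
        return self.activity.shape[1:]

    def orientation_mean(self) -> np.ndarray:
        return self.activity.mean(axis=0)

    def total(self) -> float:
        return float(self.activity.sum())


@dataclass(frozen=True)
class SelectionSignal:
    """Localized segmentation seed: a disc in cortical coordinates."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("seed radius must be > 0")


@dataclass
class ContourGraph:
    """Supra-threshold oriented elements plus real/illusory links."""

    positions: np.ndarray           # (N, 2) int, cortical (row, col)
    orientation_idx: np.ndarray     # (N,) int channel index
    orientation_deg: np.ndarray     # (N,) float
    activity: np.ndarray            # (N,) float
    real_links: np.ndarray          # (R, 2) int node-index pairs
    illusory_links: np.ndarray      # (I, 2) int node-index pairs
    component: np.ndarray           # (N,) int component label
    source: OrientationMap = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return len(self.activity)

    @property
    def n_components(self) -> int:
        return int(self.component.max()) + 1 if self.n_nodes else 0


@dataclass
class SegmentationOutput:
    """Partition of the input activity into the two segmentation layers."""

    sl0: OrientationMap
    sl1: OrientationMap
    seed: SelectionSignal
    in_sl1: np.ndarray              # (N,) bool per graph node
    success_flag: bool | None = None


# ---------------------------------------------------------------------------
# oriented edge extraction


def _oriented_kernel(angle_deg: float, sigma_long: float, sigma_short: float
                     ) -> np.ndarray:
    """Elongated Gaussian kernel whose long axis follows the orientation.

    Angle is degrees from vertical, i.e. 0 deg elongates along rows.
    """
    half = int(np.ceil(3.0 * sigma_long))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    th = np.radians(angle_deg)
    t = y * np.cos(th) + x * np.sin(th)      # along the edge
    s = -y * np.sin(th) + x * np.cos(th)     # across the edge
    k = np.exp(-0.5 * (t / sigma_long) ** 2 - 0.5 * (s / sigma_short) ** 2)
    return k / k.sum()


def extract_edges(retinal: RetinalImage,
                  params: SegmentationParams | None = None,
                  ref_peak: float | None = None) -> OrientationMap:
    """Oriented edge energy of the signed ganglion contrast.

    The signed map (ON - OFF) is smoothed with an elongated Gaussian at each
    orientation; the absolute response is the orientation energy.  Activity
    below ``extract_threshold`` times the reference peak is zeroed.  The
    reference is the map's own maximum unless ``ref_peak`` is given; a run
    passes the unflanked (target-alone) peak so that the firing threshold is
    a fixed property of the experiment, not of each display.
    """
    params = params or SegmentationParams()
    d = retinal.on - retinal.off
    chans = []
    for ang in params.orientations_deg:
        k = _oriented_kernel(ang, params.filter_sigma_long,
                             params.filter_sigma_short)
        half = k.shape[0] // 2
        if half <= 4:
            resp = convolve(d, k, mode="reflect")
        else:  # large kernels: FFT convolution on a reflect-padded copy
            padded = np.pad(d, half, mode="reflect")
            resp = fftconvolve(padded, k, mode="valid")
        chans.append(np.abs(resp))
    act = np.stack(chans)
    peak = ref_peak if ref_peak is not None else float(act.max())
    if peak > 0 and params.saturation > 0:
        # neural response saturation: compresses strong responses so weakly
        # and strongly represented elements carry comparable activity
        h = params.saturation
        act = (1.0 + h) * act / (act + h * peak)
        peak = ref_peak if ref_peak is not None else float(act.max())
    if peak > 0:
        act[act < params.extract_threshold * peak] = 0.0
    return OrientationMap(act, params.orientations_deg)


def add_trial_noise(emap: OrientationMap, rng: np.random.Generator,
                    level: float) -> OrientationMap:
    """Multiplicative noise, a * (1 + level * eps), re-rectified at zero."""
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return OrientationMap(emap.activity.copy(), emap.orientations_deg)
    eps = rng.standard_normal(emap.activity.shape)
    noisy = np.maximum(emap.activity * (1.0 + level * eps), 0.0)
    return OrientationMap(noisy, emap.orientations_deg)


# ---------------------------------------------------------------------------
# contour graph construction


def _angdiff(a, b):
    """Smallest difference between orientations (degrees, mod 180)."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)


def complete_contours(emap: OrientationMap, gap_max: float,
                      angle_tol_deg: float,
                      node_threshold: float = 0.0,
                      real_angle_tol_deg: float = 50.0,
                      ref_peak: float | None = None) -> ContourGraph:
    """Link oriented elements into contours and label connected components.

    Nodes are elements whose activity exceeds ``node_threshold`` times the
    map maximum.  Real links join 8-adjacent nodes whose orientations are
    compatible (within ``real_angle_tol_deg``, so smooth curves chain across
    neighboring orientation channels while perpendicular crossings stay
    separate).  Illusory links join node pairs separated by at most
    ``gap_max`` whose orientations agree within ``angle_tol_deg`` and whose
    connecting line also agrees with both orientations within the same
    tolerance (collinear completion).
    """
    act = emap.activity
    peak = ref_peak if ref_peak is not None else (act.max() if act.size else 0.0)
    thr = node_threshold * peak if peak > 0 else 0.0
    o, r, c = np.nonzero(act > max(thr, 0.0))
    positions = np.column_stack([r, c])
    n = len(o)
    odeg = np.asarray(emap.orientations_deg, dtype=float)[o]
    values = act[o, r, c]
    n_ori, h, w = act.shape

    # real links: 8-adjacency (including co-located nodes of compatible
    # orientation in different channels), via per-channel index grids
    real_parts = []
    index = np.full((n_ori, h, w), -1, dtype=int)
    index[o, r, c] = np.arange(n)
    shifts = [(0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1)]
    shifts += [(do, dr, dc) for do in range(1, n_ori)
               for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    for do, dr, dc in shifts:
        o2 = (o + do) % n_ori
        if _angdiff(emap.orientations_deg[0],
                    emap.orientations_deg[do % n_ori]) > real_angle_tol_deg:
            continue
        r2, c2 = r + dr, c + dc
        ok = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
        j = index[o2[ok], r2[ok], c2[ok]]
        hit = j >= 0
        if hit.any():
            real_parts.append(np.column_stack(
                [np.nonzero(ok)[0][hit], j[hit]]))
    real = (np.concatenate(real_parts) if real_parts
            else np.zeros((0, 2), dtype=int))

    # illusory links: collinear completion across gaps, per channel pair
    ill_parts = []
    for a_idx in range(n_ori):
        for b_idx in range(a_idx, n_ori):
            if _angdiff(emap.orientations_deg[a_idx],
                        emap.orientations_deg[b_idx]) > angle_tol_deg:
                continue
            ia = np.nonzero(o == a_idx)[0]
            ib = np.nonzero(o == b_idx)[0]
            if len(ia) == 0 or len(ib) == 0:
                continue
            ta = cKDTree(positions[ia])
            if a_idx == b_idx:
                pq = ta.query_pairs(gap_max, output_type="ndarray")
                pairs = np.column_stack([ia[pq[:, 0]], ia[pq[:, 1]]]) \
                    if len(pq) else np.zeros((0, 2), dtype=int)
            else:
                tb = cKDTree(positions[ib])
                rows = ta.query_ball_tree(tb, gap_max)
                pi = np.repeat(np.arange(len(rows)),
                               [len(x) for x in rows])
                qj = np.concatenate([np.asarray(x, dtype=int) for x in rows]) \
                    if len(pi) else np.zeros(0, dtype=int)
                pairs = np.column_stack([ia[pi], ib[qj]]) \
                    if len(pi) else np.zeros((0, 2), dtype=int)
            if not len(pairs):
                continue
            dr = positions[pairs[:, 1], 0] - positions[pairs[:, 0], 0]
            dc = positions[pairs[:, 1], 1] - positions[pairs[:, 0], 1]
            far = dr * dr + dc * dc > 2        # adjacency is a real link
            line = np.degrees(np.arctan2(dc, dr)) % 180.0
            keep = far & (_angdiff(line, odeg[pairs[:, 0]]) <= angle_tol_deg) \
                & (_angdiff(line, odeg[pairs[:, 1]]) <= angle_tol_deg)
            if keep.any():
                ill_parts.append(pairs[keep])
    illusory = (np.concatenate(ill_parts) if ill_parts
                else np.zeros((0, 2), dtype=int))

    if n:
        links = np.concatenate([real, illusory])
        if len(links):
            adj = coo_matrix((np.ones(len(links)),
                              (links[:, 0], links[:, 1])), shape=(n, n))
            _, component = _sparse_cc(adj, directed=False)
        else:
            component = np.arange(n)
    else:
        component = np.zeros(0, dtype=int)

    return ContourGraph(
        positions=positions, orientation_idx=o.astype(int),
        orientation_deg=odeg, activity=values,
        real_links=real, illusory_links=illusory,
        component=np.asarray(component, dtype=int), source=emap)


# ---------------------------------------------------------------------------
# seeded spreading


def spread_segmentation(graph: ContourGraph, seed: SelectionSignal
                        ) -> SegmentationOutput:
    """Recruit every component the seed disc touches into layer SL1.

    Node activity of the recruited components moves to SL1; everything else
    (including sub-threshold residual activity of the source map) stays in
    SL0, so SL0 + SL1 reproduces the input exactly.
    """
    emap = graph.source
    sl1_act = np.zeros_like(emap.activity)
    in_sl1 = np.zeros(graph.n_nodes, dtype=bool)
    if graph.n_nodes:
        d2 = ((graph.positions[:, 0] - seed.center[0]) ** 2
              + (graph.positions[:, 1] - seed.center[1]) ** 2)
        hit = d2 <= seed.radius ** 2
        if hit.any():
            sel = np.unique(graph.component[hit])
            in_sl1 = np.isin(graph.component, sel)
            idx = np.nonzero(in_sl1)[0]
            sl1_act[graph.orientation_idx[idx],
                    graph.positions[idx, 0],
                    graph.positions[idx, 1]] = graph.activity[idx]
    sl0_act = emap.activity - sl1_act
    return SegmentationOutput(
        sl0=OrientationMap(sl0_act, emap.orientations_deg),
        sl1=OrientationMap(sl1_act, emap.orientations_deg),
        seed=seed, in_sl1=in_sl1)
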