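"""Experiment orchestration: trials, conditions, sessions, ablations.

One trial runs scene -> retina (or bypass) -> oriented edges -> trial noise
-> contour graph -> saliency-drawn selection signal -> seeded segmentation
-> template match -> threshold.  A condition aggregates ``n_trials`` trials
into a threshold list; an experiment runs every condition of its table over
``n_sessions`` independent sessions and reports per-session threshold
elevations against the unflanked baseline.

Seeds are derived deterministically from (master_seed, stream, session,
condition, trial), so a re-run with the same config reproduces every
threshold bit-identically and conditions can be re-ordered without changing
their trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import saliency as sal
from . import segmentation as seg
from . import stimuli as stim
from . import threshold as thr
from .retina import RetinaParams, RetinalImage, bypass_retina, crop_to_roi, \
    retina_pipeline

__all__ = [
    "RunConfig",
    "TrialRecord",
    "ExperimentReport",
    "prepare_condition",
    "run_trial",
    "run_condition",
    "run_experiment",
    "run_ablation",
    "run_squares_demo",
]

# rng stream tags
_STREAM_TEMPLATE = 1
_STREAM_TRIALS = 2
_STREAM_SEARCH = 3


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of an experiment run."""

    experiment_id: str = "exp1b"
    n_trials: int = 20
    n_sessions: int = 1
    master_seed: int = 0
    disabled_modules: frozenset = frozenset()
    geometry: stim.SceneGeometry = field(default_factory=stim.SceneGeometry)
    retina: RetinaParams = field(default_factory=RetinaParams)
    saliency: sal.SaliencyParams = field(default_factory=sal.SaliencyParams)
    segmentation: seg.SegmentationParams = field(
        default_factory=seg.SegmentationParams)
    threshold: thr.ThresholdParams = field(default_factory=thr.ThresholdParams)
    roi_margin_deg: float = 0.6
    classify_margin_deg: float = 0.1

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        bad = set(self.disabled_modules) - {"retina", "saliency"}
        if bad:
            raise ValueError(f"unknown modules to disable: {sorted(bad)}")

    @property
    def retina_enabled(self) -> bool:
        return "retina" not in self.disabled_modules

    @property
    def saliency_enabled(self) -> bool:
        return "saliency" not in self.disabled_modules

    @property
    def ablation_label(self) -> str:
        if not self.disabled_modules:
            return "full"
        return "no_" + "_no_".join(sorted(self.disabled_modules))


@dataclass
class TrialRecord:
    session: int
    condition: str
    eccentricity_deg: float
    flanker: str
    trial: int
    M: float
    T: float
    success: bool
    merged: bool                # target and flanker share a contour component
    layer_index: int
    seed_v: float
    seed_u: float
    n_nodes: int
    n_target_nodes: int
    n_flanker_nodes: int


@dataclass
class ExperimentReport:
    """Trial table plus per-session threshold elevations."""

    trials: pd.DataFrame
    elevations: pd.DataFrame
    config: RunConfig
    ablation: str

    def mean_elevation(self, flanker: str, eccentricity_deg: float | None = None
                       ) -> float:
        df = self.elevations[self.elevations.flanker == flanker]
        if eccentricity_deg is not None:
            df = df[np.isclose(df.eccentricity_deg, eccentricity_deg)]
        return float(df.E.mean())

    def session_difference(self, eccentricity_deg: float | None = None
                           ) -> np.ndarray:
        """Per-session E_outer - E_inner."""
        df = self.elevations
        if eccentricity_deg is not None:
            df = df[np.isclose(df.eccentricity_deg, eccentricity_deg)]
        piv = df.pivot_table(index="session", columns="flanker", values="E")
        return (piv["outer"] - piv["inner"]).to_numpy()


# ---------------------------------------------------------------------------
# condition preparation


@dataclass
class ConditionContext:
    """Everything per-condition that is deterministic across trials."""

    spec: stim.StimulusSpec
    scene: stim.VisualScene
    retinal: RetinalImage
    edges: seg.OrientationMap
    saliency_map: sal.SaliencyMap
    target_mask: np.ndarray      # cortical-crop bool grids
    flanker_mask: np.ndarray
    seed_radius_px: float
    gap_max_px: float
    ref_peak: float = 0.0        # firing-threshold anchor (edge-energy units)
    fallback_center: tuple[float, float] | None = None  # scene px


def _union_boxes(boxes: list) -> tuple[int, int, int, int]:
    arr = np.asarray(boxes)
    return (int(arr[:, 0].min()), int(arr[:, 1].max()),
            int(arr[:, 2].min()), int(arr[:, 3].max()))


def roi_bbox(config: RunConfig, eccentricity_deg: float,
             specs: list[stim.StimulusSpec] | None = None
             ) -> tuple[int, int, int, int]:
    """Shared scene bounding box of all flanker configs at one eccentricity.

    Every condition at the same eccentricity is cropped to the same region so
    that templates and responses share a grid.
    """
    geom = config.geometry
    if specs is None:
        specs = [s for s in stim.condition_table(config.experiment_id)
                 if np.isclose(s.eccentricity_deg, eccentricity_deg)]
    boxes = []
    for s in specs:
        scene = stim.render_scene(s, geom)
        b = scene.meta["boxes"]
        boxes.append(b["target"])
        if "flanker" in b:
            boxes.append(b["flanker"])
        if "squares" in b:
            boxes.extend(b["squares"])
    r0, r1, c0, c1 = _union_boxes(boxes)
    m = int(round(geom.px(config.roi_margin_deg)))
    h, w = geom.shape
    return (max(r0 - m, 0), min(r1 + m, h), max(c0 - m, 0), min(c1 + m, w))


def _dilated_mask(retinal: RetinalImage, box, margin_px: float) -> np.ndarray:
    """Cortical-crop mask of the scene box dilated by a small margin."""
    rows, cols = retinal.on.shape
    vv, uu = np.indices((rows, cols))
    r, c = retinal.coords.inverse(vv.astype(float), uu.astype(float))
    r0, r1, c0, c1 = box
    return ((r >= r0 - margin_px) & (r < r1 + margin_px)
            & (c >= c0 - margin_px) & (c < c1 + margin_px))


def prepare_condition(spec: stim.StimulusSpec, config: RunConfig,
                      bbox: tuple[int, int, int, int] | None = None,
                      ref_peak: float | None = None) -> ConditionContext:
    """Render, run the retina (or bypass), extract edges, prepare saliency.

    ``ref_peak`` anchors the firing thresholds of the grouping stage; an
    experiment passes the unflanked condition's peak edge energy so that
    thresholds do not depend on which flankers are on screen.
    """
    geom = config.geometry
    scene = stim.render_scene(spec, geom)
    if bbox is None:
        bbox = roi_bbox(config, spec.eccentricity_deg,
                        specs=[spec] if spec.experiment_id == "squares_demo"
                        else None)

    seg_p = config.segmentation
    if config.retina_enabled:
        retinal = crop_to_roi(retina_pipeline(scene, config.retina), bbox)
    else:
        retinal = crop_to_roi(
            bypass_retina(scene, config.retina.cortical_shape[1]), bbox)
    edges = seg.extract_edges(retinal, seg_p, ref_peak=ref_peak)

    if config.saliency_enabled:
        smap = sal.contrast_saliency(scene, config.saliency)
    else:
        smap = None  # filled in by the fallback grid search

    margin_px = geom.px(config.classify_margin_deg)
    boxes = scene.meta["boxes"]
    target_mask = _dilated_mask(retinal, boxes["target"], margin_px)
    if "flanker" in boxes:
        flanker_mask = _dilated_mask(retinal, boxes["flanker"], margin_px)
    else:
        flanker_mask = np.zeros_like(target_mask)

    return ConditionContext(
        spec=spec, scene=scene, retinal=retinal, edges=edges,
        saliency_map=smap, target_mask=target_mask, flanker_mask=flanker_mask,
        seed_radius_px=seg_p.seed_radius,
        gap_max_px=seg_p.gap_max,
        ref_peak=float(ref_peak) if ref_peak is not None
        else float(edges.activity.max()))


# ---------------------------------------------------------------------------
# trials


def _draw_seed(ctx: ConditionContext, rng: np.random.Generator
               ) -> seg.SelectionSignal:
    """Sample a scene location, map it to the cortical crop; resample if it
    falls outside the represented region."""
    coords = ctx.retinal.coords
    rows, cols = ctx.retinal.on.shape
    if ctx.saliency_map is not None:
        for _ in range(200):
            r, c = sal.sample_location(ctx.saliency_map, rng)
            v, u = coords.forward(float(r), float(c))
            if 0 <= v < rows and 0 <= u < cols:
                return seg.SelectionSignal((float(v), float(u)),
                                           ctx.seed_radius_px)
    # fallback: the target-box center (blank map or repeated misses)
    b = ctx.scene.meta["boxes"]["target"]
    v, u = coords.forward((b[0] + b[1]) / 2.0, (b[2] + b[3]) / 2.0)
    return seg.SelectionSignal((float(v), float(u)), ctx.seed_radius_px)


def _node_groups(ctx: ConditionContext, graph: seg.ContourGraph):
    pos = graph.positions
    if not len(pos):
        return (np.zeros(0, dtype=bool),) * 2
    t = ctx.target_mask[pos[:, 0], pos[:, 1]]
    f = ctx.flanker_mask[pos[:, 0], pos[:, 1]] & ~t
    return t, f


def _success_flag(is_t, is_f, in_sl1) -> bool:
    """Target wholly in one layer that contains no flanker node."""
    if not is_t.any():
        return False
    t1 = in_sl1[is_t]
    if t1.all():
        return not in_sl1[is_f].any() if is_f.any() else True
    if not t1.any():
        return in_sl1[is_f].all() if is_f.any() else True
    return False


@dataclass
class ScoringContext:
    """Per-experiment scoring state shared across conditions."""

    templates: dict           # eccentricity (rounded) -> Template
    a: float                  # threshold intercept (shared)
    params: thr.ThresholdParams

    def template_for(self, ecc: float) -> thr.Template:
        return self.templates[round(float(ecc), 3)]


def run_trial(ctx: ConditionContext, config: RunConfig,
              rng: np.random.Generator, scoring: ScoringContext,
              session: int = 0, trial: int = 0) -> TrialRecord:
    """One complete trial of the visual system on a prepared condition."""
    seg_p = config.segmentation
    noisy = seg.add_trial_noise(ctx.edges, rng, seg_p.noise_level)
    graph = seg.complete_contours(noisy, ctx.gap_max_px, seg_p.angle_tol_deg,
                                  seg_p.node_threshold,
                                  seg_p.real_angle_tol_deg,
                                  ref_peak=ctx.ref_peak)
    seed = _draw_seed(ctx, rng)
    out = seg.spread_segmentation(graph, seed)
    is_t, is_f = _node_groups(ctx, graph)
    out.success_flag = _success_flag(is_t, is_f, out.in_sl1)
    merged = bool(is_t.any() and is_f.any()
                  and len(np.intersect1d(graph.component[is_t],
                                         graph.component[is_f])))

    tpl = scoring.template_for(ctx.spec.eccentricity_deg)
    layer = thr.select_scored_layer(out, tpl)
    resp = (out.sl1 if layer else out.sl0).orientation_mean()
    s, n = thr.split_signal_noise(resp, tpl)
    p = scoring.params
    M = thr.match_score(s, n, p.I0, p.sigma_px, p.kernel)
    T = thr.match_to_threshold(M, scoring.a, p.b, p.floor_factor)

    return TrialRecord(
        session=session, condition=ctx.spec.label,
        eccentricity_deg=ctx.spec.eccentricity_deg, flanker=ctx.spec.flanker,
        trial=trial, M=M, T=T, success=out.success_flag, merged=merged,
        layer_index=layer, seed_v=seed.center[0], seed_u=seed.center[1],
        n_nodes=graph.n_nodes, n_target_nodes=int(is_t.sum()),
        n_flanker_nodes=int(is_f.sum()))


def _trial_rng(config: RunConfig, session: int, cond_idx: int, trial: int
               ) -> np.random.Generator:
    return np.random.default_rng(
        [config.master_seed, _STREAM_TRIALS, session, cond_idx, trial])


def _variant_specs(spec: stim.StimulusSpec) -> list[stim.StimulusSpec]:
    """Stimulus variants presented interleaved across trials.

    For Vernier displays the offset direction alternates randomly from trial
    to trial (the direction is what an observer would report), which keeps
    the rendered displays statistically symmetric about the target column.
    """
    if spec.experiment_id in {"exp1b", "squares_demo"} \
            and spec.vernier_offset_deg != 0:
        return [spec, dataclasses.replace(
            spec, vernier_offset_deg=-spec.vernier_offset_deg)]
    return [spec]


def prepare_condition_pair(spec: stim.StimulusSpec, config: RunConfig,
                           bbox=None, ref_peak=None, cond_idx: int = 0
                           ) -> list[ConditionContext]:
    """Prepare all stimulus variants of one condition."""
    ctxs = [prepare_condition(s, config, bbox, ref_peak)
            for s in _variant_specs(spec)]
    _ablate_saliency_if_needed(ctxs[0], config, cond_idx)
    if len(ctxs) > 1 and ctxs[0].fallback_center is not None:
        ctxs[1].fallback_center = ctxs[0].fallback_center
        ctxs[1].saliency_map = sal.gaussian_fallback(
            ctxs[1].scene, ctxs[0].fallback_center,
            config.saliency.fallback_sigma_deg)
    return ctxs


def _pick_variant(ctxs: list[ConditionContext], rng: np.random.Generator
                  ) -> ConditionContext:
    if len(ctxs) == 1:
        return ctxs[0]
    return ctxs[int(rng.integers(len(ctxs)))]


def run_condition(spec: stim.StimulusSpec, config: RunConfig,
                  scoring: ScoringContext | None = None,
                  ctx: ConditionContext | list | None = None,
                  session: int = 0, cond_idx: int = 0
                  ) -> tuple[thr.ThresholdResult, list[TrialRecord]]:
    """Run ``n_trials`` independent trials of one condition."""
    if ctx is None:
        ctxs = prepare_condition_pair(spec, config, cond_idx=cond_idx)
    elif isinstance(ctx, ConditionContext):
        ctxs = [ctx]
    else:
        ctxs = list(ctx)
    if scoring is None:
        scoring = build_scoring(
            config, {round(spec.eccentricity_deg, 3): ctxs})
    records = []
    for t in range(config.n_trials):
        rng = _trial_rng(config, session, cond_idx, t)
        records.append(run_trial(_pick_variant(ctxs, rng), config, rng,
                                 scoring, session=session, trial=t))
    return thr.ThresholdResult([r.T for r in records], condition=spec), records


# ---------------------------------------------------------------------------
# templates and scoring


def build_scoring(config: RunConfig, unflanked_ctxs: dict) -> ScoringContext:
    """Templates per eccentricity plus the shared threshold intercept.

    ``unflanked_ctxs`` maps rounded eccentricity to the unflanked condition's
    context.  The intercept ``a`` anchors on the template of the smallest
    eccentricity (the best-represented target), which for the face paradigm
    matches normalizing all thresholds by the unflanked 3-deg condition.
    """
    p = config.threshold
    templates = {}
    for i, (ecc, ctxs) in enumerate(sorted(unflanked_ctxs.items())):
        if isinstance(ctxs, ConditionContext):
            ctxs = [ctxs]
        rng = np.random.default_rng([config.master_seed, _STREAM_TEMPLATE, i])

        nt = config.segmentation.node_threshold

        def response(r, _ctxs=ctxs, _nt=nt):
            _ctx = _pick_variant(_ctxs, r)
            noisy = seg.add_trial_noise(_ctx.edges, r,
                                        config.segmentation.noise_level)
            act = noisy.activity
            if _ctx.ref_peak > 0:  # the segmented (supra-threshold) part
                act = np.where(act > _nt * _ctx.ref_peak, act, 0.0)
            return act.mean(axis=0)

        templates[ecc] = thr.build_template(response, p.n_template_reps, rng, p)
    ref = min(templates)
    a = p.a_factor * templates[ref].self_match
    return ScoringContext(templates=templates, a=a, params=p)


def _ablate_saliency_if_needed(ctx: ConditionContext, config: RunConfig,
                               cond_idx: int) -> None:
    """Saliency-off mode: place the sampling Gaussian by a success grid search.

    Candidate centers form a coarse 5x5 grid over the stimulus neighborhood;
    each candidate is scored by the empirical segmentation-success rate over
    100 probe trials (shared noise draws across candidates), and the winner
    becomes the center of the fallback Gaussian.
    """
    if config.saliency_enabled:
        return
    boxes = [ctx.scene.meta["boxes"]["target"]]
    if "flanker" in ctx.scene.meta["boxes"]:
        boxes.append(ctx.scene.meta["boxes"]["flanker"])
    r0, r1, c0, c1 = _union_boxes(boxes)
    pad = config.geometry.px(0.3)
    rows = np.linspace(r0 - pad, r1 + pad, 5)
    cols = np.linspace(c0 - pad, c1 + pad, 5)

    seg_p = config.segmentation
    rng = np.random.default_rng(
        [config.master_seed, _STREAM_SEARCH, cond_idx])
    graphs = []
    for _ in range(100):
        noisy = seg.add_trial_noise(ctx.edges, rng, seg_p.noise_level)
        graphs.append(seg.complete_contours(noisy, ctx.gap_max_px,
                                            seg_p.angle_tol_deg,
                                            seg_p.node_threshold,
                                            seg_p.real_angle_tol_deg,
                                            ref_peak=ctx.ref_peak))
    best, best_rate = None, -1.0
    for r in rows:
        for c in cols:
            smap = sal.gaussian_fallback(ctx.scene, (r, c),
                                         config.saliency.fallback_sigma_deg)
            ctx.saliency_map = smap
            wins = 0
            sub = np.random.default_rng(
                [config.master_seed, _STREAM_SEARCH, cond_idx, 7])
            for g in graphs:
                seed = _draw_seed(ctx, sub)
                out = seg.spread_segmentation(g, seed)
                is_t, is_f = _node_groups(ctx, g)
                wins += _success_flag(is_t, is_f, out.in_sl1)
            rate = wins / len(graphs)
            if rate > best_rate:
                best, best_rate = (r, c), rate
    ctx.fallback_center = best
    ctx.saliency_map = sal.gaussian_fallback(
        ctx.scene, best, config.saliency.fallback_sigma_deg)


# ---------------------------------------------------------------------------
# experiments


def run_experiment(config: RunConfig) -> ExperimentReport:
    """All conditions of the experiment over ``n_sessions`` sessions.

    Threshold elevations divide each condition's per-session mean threshold
    by the unflanked baseline of the same session: the experiment's own
    unflanked condition for the Vernier paradigm, the unflanked 3-deg
    condition for the face paradigm.
    """
    specs = stim.condition_table(config.experiment_id)
    if config.experiment_id not in {"exp1b", "exp5"}:
        raise ValueError("run_experiment handles exp1b and exp5")

    eccs = sorted({round(s.eccentricity_deg, 3) for s in specs})
    bboxes = {e: roi_bbox(config, e) for e in eccs}
    # the unflanked condition of each eccentricity anchors the firing
    # thresholds for its flanked siblings
    refs = {}
    for s in specs:
        if s.flanker == "none":
            e = round(s.eccentricity_deg, 3)
            ctx = prepare_condition(s, config, bboxes[e])
            refs[e] = ctx.ref_peak
    ctxs = {}
    for i, s in enumerate(specs):
        e = round(s.eccentricity_deg, 3)
        ctxs[s.label] = prepare_condition_pair(s, config, bboxes[e],
                                               ref_peak=refs[e], cond_idx=i)

    unflanked = {round(s.eccentricity_deg, 3): ctxs[s.label]
                 for s in specs if s.flanker == "none"}
    scoring = build_scoring(config, unflanked)

    records: list[TrialRecord] = []
    for session in range(config.n_sessions):
        for cond_idx, s in enumerate(specs):
            for t in range(config.n_trials):
                rng = _trial_rng(config, session, cond_idx, t)
                records.append(run_trial(_pick_variant(ctxs[s.label], rng),
                                         config, rng, scoring,
                                         session=session, trial=t))
    trials = pd.DataFrame([dataclasses.asdict(r) for r in records])

    base_ecc = min(eccs) if config.experiment_id == "exp5" else eccs[0]
    rows = []
    for session, sdf in trials.groupby("session"):
        base = sdf.loc[(sdf.flanker == "none")
                       & np.isclose(sdf.eccentricity_deg, base_ecc), "T"].mean()
        for (ecc, fl), cdf in sdf.groupby(["eccentricity_deg", "flanker"]):
            rows.append({"session": session, "eccentricity_deg": ecc,
                         "flanker": fl, "E": cdf["T"].mean() / base,
                         "mean_T": cdf["T"].mean(),
                         "success_rate": cdf["success"].mean()})
    elevations = pd.DataFrame(rows)
    return ExperimentReport(trials, elevations, config, config.ablation_label)


def run_ablation(config: RunConfig) -> ExperimentReport:
    """Experiment run with at least one module disabled."""
    if not config.disabled_modules:
        raise ValueError("run_ablation requires a nonempty disabled set")
    return run_experiment(config)


def run_squares_demo(config: RunConfig, n_squares: int = 5) -> dict:
    """Illusory-contour formation across a row of outlined squares.

    Builds the (noiseless) contour graph of the square-array stimulus under
    the current config and counts illusory links whose endpoints belong to
    different squares.  Returns the counts plus per-square node totals.
    """
    if n_squares < 1 or n_squares % 2 == 0:
        raise ValueError("n_squares must be a positive odd integer")
    spec = stim.StimulusSpec("squares_demo", stim.EXP1B_ECCENTRICITY,
                             n_squares=n_squares)
    geom = config.geometry
    scene = stim.render_scene(spec, geom)
    boxes = scene.meta["boxes"]["squares"]
    bbox = roi_bbox(config, spec.eccentricity_deg, specs=[spec])
    ctx = prepare_condition(spec, config, bbox)

    seg_p = config.segmentation
    graph = seg.complete_contours(ctx.edges, ctx.gap_max_px,
                                  seg_p.angle_tol_deg, seg_p.node_threshold,
                                  seg_p.real_angle_tol_deg,
                                  ref_peak=ctx.ref_peak)

    # assign nodes to squares through the inverse map
    margin = geom.px(config.classify_margin_deg)
    pos = graph.positions.astype(float)
    r, c = ctx.retinal.coords.inverse(pos[:, 0], pos[:, 1])
    square_of = np.full(graph.n_nodes, -1, dtype=int)
    for k, (r0, r1, c0, c1) in enumerate(boxes):
        inside = ((r >= r0 - margin) & (r < r1 + margin)
                  & (c >= c0 - margin) & (c < c1 + margin))
        square_of[inside & (square_of < 0)] = k

    inter = 0
    for i, j in graph.illusory_links:
        si, sj = square_of[i], square_of[j]
        if si >= 0 and sj >= 0 and si != sj:
            inter += 1
    return {
        "n_squares": n_squares,
        "ablation": config.ablation_label,
        "n_nodes": graph.n_nodes,
        "n_illusory_links": int(len(graph.illusory_links)),
        "inter_square_links": int(inter),
        "n_components": graph.n_components,
        "graph": graph,
        "context": ctx,
    }
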