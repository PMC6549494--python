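"""Contour grouping: edge extraction, completion, seeded spreading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdsim import retina as ret
from crowdsim import segmentation as seg

ORIS = (0.0, 45.0, 90.0, 135.0)


def _map_from(act):
    return seg.OrientationMap(act, ORIS)


def _vertical_pair_map(gap, rows=40, cols=40, length=6):
    """Two collinear vertical segments separated by ``gap`` empty pixels."""
    act = np.zeros((4, rows, cols))
    col = cols // 2
    top = rows // 2 - gap // 2 - length
    act[0, top:top + length, col] = 1.0
    bot = rows // 2 + (gap + 1) // 2
    act[0, bot:bot + length, col] = 1.0
    return _map_from(act)


def _random_graph(rng, n_nodes=30, shape=(24, 24)):
    act = np.zeros((4,) + shape)
    for _ in range(n_nodes):
        o = rng.integers(4)
        r = rng.integers(shape[0])
        c = rng.integers(shape[1])
        act[o, r, c] = rng.uniform(0.2, 1.0)
    emap = _map_from(act)
    return seg.complete_contours(emap, gap_max=4.0, angle_tol_deg=25.0)


def _components_bruteforce(graph):
    """Oracle: exhaustive DFS over the explicit link lists."""
    n = graph.n_nodes
    adj = [[] for _ in range(n)]
    for links in (graph.real_links, graph.illusory_links):
        for i, j in links:
            adj[i].append(j)
            adj[j].append(i)
    labels = np.full(n, -1)
    cur = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        while stack:
            k = stack.pop()
            if labels[k] >= 0:
                continue
            labels[k] = cur
            stack.extend(adj[k])
        cur += 1
    return labels


class TestExtractEdges:
    def test_blank_input_gives_empty_map(self):
        cmap = ret.IdentityCoordinateMap((40, 40), (20, 0), 0.02)
        retinal = ret.RetinalImage(np.zeros((40, 40)), np.zeros((40, 40)), cmap)
        emap = seg.extract_edges(retinal)
        assert emap.total() == 0.0

    def test_vertical_bar_drives_vertical_channel(self):
        on = np.zeros((40, 40))
        off = np.zeros((40, 40))
        off[10:30, 20] = 1.0
        cmap = ret.IdentityCoordinateMap((40, 40), (20, 0), 0.02)
        emap = seg.extract_edges(ret.RetinalImage(on, off, cmap))
        per_channel = emap.activity[:, 15:25, 20].sum(axis=1)
        assert np.argmax(per_channel) == 0  # 0 deg = vertical

    def test_inner_flanker_better_represented_than_outer(
            self, geometry, retina_params, exp1b_specs):
        """Closer to the fovea means more edge activity after magnification."""
        from crowdsim import runner, stimuli as stim

        import crowdsim
        cfg = crowdsim.RunConfig()
        bbox = runner.roi_bbox(cfg, exp1b_specs[0].eccentricity_deg)
        ref = runner.prepare_condition(exp1b_specs[0], cfg, bbox)
        masses = {}
        for spec in exp1b_specs[1:]:
            ctx = runner.prepare_condition(spec, cfg, bbox,
                                           ref_peak=ref.ref_peak)
            g = seg.complete_contours(ctx.edges, ctx.gap_max_px, 25.0, 0.27,
                                      ref_peak=ctx.ref_peak)
            is_t, is_f = runner._node_groups(ctx, g)
            masses[spec.flanker] = g.activity[is_f].sum()
        assert masses["inner"] > masses["outer"]


class TestTrialNoise:
    def test_zero_level_is_identity(self):
        emap = _vertical_pair_map(3)
        out = seg.add_trial_noise(emap, np.random.default_rng(0), 0.0)
        assert np.array_equal(out.activity, emap.activity)

    def test_fixed_seed_reproducible(self):
        emap = _vertical_pair_map(3)
        a = seg.add_trial_noise(emap, np.random.default_rng(3), 0.2)
        b = seg.add_trial_noise(emap, np.random.default_rng(3), 0.2)
        assert np.array_equal(a.activity, b.activity)
        assert not np.array_equal(a.activity, emap.activity)

    def test_noisy_trials_never_match_the_template_perfectly(self,
                                                             exp1b_specs):
        """Even fully successful target-alone trials fall short of the
        template self-match: trial noise drops borderline elements from the
        segmented representation."""
        import crowdsim
        from crowdsim import runner

        cfg = crowdsim.RunConfig(master_seed=1)
        bbox = runner.roi_bbox(cfg, exp1b_specs[0].eccentricity_deg)
        ctxs = runner.prepare_condition_pair(exp1b_specs[0], cfg, bbox)
        scoring = runner.build_scoring(cfg, {3.89: ctxs})
        Ms = []
        for t in range(40):
            rng = np.random.default_rng([1, 2, 0, 0, t])
            rec = runner.run_trial(runner._pick_variant(ctxs, rng), cfg, rng,
                                   scoring)
            Ms.append(rec.M)
        assert np.std(Ms) > 0
        # oracle: the same trial without intrinsic noise
        import dataclasses
        cfg0 = dataclasses.replace(
            cfg, segmentation=dataclasses.replace(cfg.segmentation,
                                                  noise_level=0.0))
        rng0 = np.random.default_rng([1, 2, 0, 0, 0])
        m_clean = runner.run_trial(runner._pick_variant(ctxs, rng0), cfg0,
                                   rng0, scoring).M
        assert np.mean(Ms) < m_clean


class TestCompleteContours:
    def test_isolated_element_has_no_links(self):
        act = np.zeros((4, 20, 20))
        act[0, 10, 10] = 1.0
        g = seg.complete_contours(_map_from(act), 5.0, 25.0)
        assert g.n_nodes == 1
        assert len(g.illusory_links) == 0

    @pytest.mark.parametrize("gap,expected", [(3, 1), (9, 2)])
    def test_collinear_segments_group_within_reach(self, gap, expected):
        g = seg.complete_contours(_vertical_pair_map(gap), gap_max=5.0,
                                  angle_tol_deg=25.0)
        assert g.n_components == expected

    def test_parallel_offset_segments_stay_apart(self):
        # two vertical segments side by side: within reach but not collinear
        act = np.zeros((4, 30, 30))
        act[0, 10:20, 12] = 1.0
        act[0, 10:20, 16] = 1.0
        g = seg.complete_contours(_map_from(act), gap_max=5.0,
                                  angle_tol_deg=25.0)
        assert g.n_components == 2


class TestSpreadSegmentation:
    def test_empty_seed_leaves_all_in_sl0(self):
        emap = _vertical_pair_map(3)
        g = seg.complete_contours(emap, 5.0, 25.0)
        out = seg.spread_segmentation(g, seg.SelectionSignal((0.0, 0.0), 2.0))
        assert out.sl1.total() == 0.0
        assert np.array_equal(out.sl0.activity, emap.activity)

    def test_seeded_component_moves_to_sl1(self):
        emap = _vertical_pair_map(9)  # two components at gap_max 5
        g = seg.complete_contours(emap, 5.0, 25.0)
        top_node = g.positions[np.argmin(g.positions[:, 0])]
        out = seg.spread_segmentation(
            g, seg.SelectionSignal(tuple(top_node.astype(float)), 2.0))
        assert 0 < out.sl1.total() < emap.total()

    def test_partition_is_exact(self):
        rng = np.random.default_rng(2)
        emap = seg.add_trial_noise(_vertical_pair_map(3), rng, 0.3)
        g = seg.complete_contours(emap, 5.0, 25.0)
        out = seg.spread_segmentation(
            g, seg.SelectionSignal((20.0, 20.0), 6.0))
        assert np.array_equal(out.sl0.activity + out.sl1.activity,
                              emap.activity)

    def test_matches_dfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            g = _random_graph(rng)
            labels = _components_bruteforce(g)
            center = (float(rng.integers(24)), float(rng.integers(24)))
            radius = float(rng.uniform(1.0, 6.0))
            out = seg.spread_segmentation(
                g, seg.SelectionSignal(center, radius))
            d2 = ((g.positions[:, 0] - center[0]) ** 2
                  + (g.positions[:, 1] - center[1]) ** 2)
            hit_labels = np.unique(labels[d2 <= radius ** 2])
            expected = np.isin(labels, hit_labels)
            assert np.array_equal(out.in_sl1, expected)

    def test_growing_seed_never_evicts_nodes(self):
        rng = np.random.default_rng(4)
        g = _random_graph(rng, n_nodes=60)
        prev = np.zeros(g.n_nodes, dtype=bool)
        for radius in (2.0, 4.0, 6.0, 9.0):
            out = seg.spread_segmentation(
                g, seg.SelectionSignal((12.0, 12.0), radius))
            assert (prev & ~out.in_sl1).sum() == 0
            prev = out.in_sl1


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_partition_conservation_is_universal(seed):
    """SL0 + SL1 reproduce the input exactly for arbitrary random maps."""
    rng = np.random.default_rng(seed)
    act = rng.random((4, 12, 12)) * (rng.random((4, 12, 12)) > 0.7)
    emap = seg.OrientationMap(act, ORIS)
    g = seg.complete_contours(emap, 3.0, 25.0, node_threshold=0.3)
    out = seg.spread_segmentation(
        g, seg.SelectionSignal((float(rng.integers(12)),
                                float(rng.integers(12))), 3.0))
    assert np.array_equal(out.sl0.activity + out.sl1.activity, emap.activity)
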