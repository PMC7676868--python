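"""Linking, tracklet maintenance rules, and graph construction."""

import numpy as np
import pytest

from tagtrax import (
    ArenaSpec,
    GroundTruth,
    NoiseParams,
    RunConfig,
    agents_from_labels,
    build_graph,
    estimate_flow,
    link_blobs,
    render,
    render_frame,
)
from tagtrax.classification import blob_members
from tagtrax.segmentation import BackgroundModel, segment_frame
from tagtrax.synthetic_arena import _BG_COLOR


def _clean_bg(h, w):
    return BackgroundModel(image=np.full((h, w, 3), _BG_COLOR), mean_color=_BG_COLOR.copy())


def _one_agent_frames(positions, heading=0.5, wh=(160, 120)):
    agents = agents_from_labels(["BG"])
    arena = ArenaSpec(*wh)
    n = len(positions)
    gt = GroundTruth(
        ("BG",),
        np.asarray(positions, float).reshape(n, 1, 2),
        np.full((n, 1), heading),
        np.ones((n, 1), bool),
        np.zeros((n, 1), int),
    )
    return [render_frame(gt, agents, arena, t, NoiseParams(0.0), seed=1) for t in range(n)]


class TestFlow:
    def test_identical_frames_zero_field(self):
        (f,) = _one_agent_frames([(80, 60)])
        flow = estimate_flow(f, f, (40, 20, 120, 100))
        assert np.abs(flow).max() < 0.25

    def test_translation_recovered(self):
        f0, f1 = _one_agent_frames([(70, 60), (75, 60)])
        bg = _clean_bg(120, 160)
        (blob,) = segment_frame(f0, bg, 40, 30)
        x0, y0, x1, y1 = blob.bbox
        region = (max(0, x0 - 15), max(0, y0 - 15), x1 + 15, y1 + 15)
        flow = estimate_flow(f0, f1, region)
        ys, xs = np.nonzero(blob.mask)
        ys = ys + y0 - region[1]
        xs = xs + x0 - region[0]
        assert abs(flow[1][ys, xs].mean() - 5.0) <= 1.0
        assert abs(flow[0][ys, xs].mean() - 0.0) <= 1.0

    def test_noise_frames_do_not_crash(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 255, (60, 60, 3)).astype(np.uint8)
        b = rng.integers(0, 255, (60, 60, 3)).astype(np.uint8)
        flow = estimate_flow(a, b, (0, 0, 60, 60))
        assert flow.shape == (2, 60, 60)

    def test_empty_region_rejected(self):
        (f,) = _one_agent_frames([(80, 60)])
        with pytest.raises(ValueError):
            estimate_flow(f, f, (10, 10, 10, 40))


class TestLinkBlobs:
    def test_stationary_blob_links_with_full_support(self):
        f0, f1 = _one_agent_frames([(80, 60), (80, 60)])
        bg = _clean_bg(120, 160)
        b0 = segment_frame(f0, bg, 40, 30, frame_index=0)
        b1 = segment_frame(f1, bg, 40, 30, frame_index=1)
        links = link_blobs(b0, b1, f0, f1)
        assert len(links) == 1
        assert links[0].support > 0.9

    def test_merge_produces_two_links_into_one_blob(self, motif_scene):
        _, _, gt, frames = motif_scene
        bg = _clean_bg(96, 256)
        # find the merge frame: blobs go from 2 to 1
        prev = segment_frame(np.asarray(frames[0]), bg, 40, 30, frame_index=0)
        for t in range(1, len(frames)):
            cur = segment_frame(np.asarray(frames[t]), bg, 40, 30, frame_index=t)
            if len(prev) == 2 and len(cur) == 1:
                links = link_blobs(prev, cur, frames[t - 1], frames[t])
                assert sorted(l.prev_idx for l in links) == [0, 1]
                assert {l.cur_idx for l in links} == {0}
                return
            prev = cur
        pytest.fail("no merge event found in the scripted scene")

    def test_disappearing_blob_gets_no_link(self):
        f0, _ = _one_agent_frames([(80, 60), (80, 60)])
        bg = _clean_bg(120, 160)
        b0 = segment_frame(f0, bg, 40, 30, frame_index=0)
        empty = bg.image.astype(np.uint8)
        assert link_blobs(b0, [], f0, empty) == []


class TestGraphConstruction:
    def test_motif_five_tracklets_and_edges(self, motif_graph):
        assert len(motif_graph) == 5
        assert motif_graph.edges == [(0, 2), (1, 2), (2, 3), (2, 4)]
        kinds = {tid: motif_graph.tracklet(tid) for tid in motif_graph.node_ids}
        assert kinds[2].start_frame == kinds[0].end_frame + 1

    def test_single_agent_single_tracklet(self):
        agents = agents_from_labels(["BG"])
        arena = ArenaSpec(160, 120)
        from tagtrax import MotionParams, simulate

        gt = simulate(agents, arena, 40, MotionParams(attraction=0.0), seed=2)
        frames = render(gt, agents, arena, seed=3)
        g = build_graph(frames, RunConfig())
        assert len(g) == 1
        assert g.edges == []
        (tr,) = g.tracklets
        assert (tr.start_frame, tr.end_frame, tr.n_blobs) == (0, 39, 40)

    def test_empty_video_empty_graph(self):
        frames = [np.full((60, 60, 3), 200, np.uint8)] * 10
        g = build_graph(frames, RunConfig())
        assert len(g) == 0

    def test_invariants_on_simulated_run(self, tiny_graph):
        g = tiny_graph
        g.assert_valid()  # acyclic + consecutive-frame edges
        seen = {}
        for tr in g.tracklets:
            assert tr.end_frame - tr.start_frame + 1 == tr.n_blobs
            for t, blob in zip(range(tr.start_frame, tr.end_frame + 1), tr.blobs):
                assert blob.frame_index == t
                key = (t, blob.bbox)
                assert key not in seen, "blob belongs to two tracklets"
                seen[key] = tr.tracklet_id
        # topological order consistent with start frames
        for u, v in g.edges:
            assert g.tracklet(u).start_frame < g.tracklet(v).start_frame

    def test_ground_truth_coverage_closed_roi(self, tiny_scene, tiny_graph):
        _, _, gt, _ = tiny_scene
        per_frame_blobs = {}
        for tr in tiny_graph.tracklets:
            for blob in tr.blobs:
                per_frame_blobs.setdefault(blob.frame_index, []).append(blob)
        covered = 0
        total = 0
        for t in range(gt.n_frames):
            for i in range(gt.n_agents):
                total += 1
                hits = [
                    b for b in per_frame_blobs.get(t, [])
                    if b.contains_point(*gt.pos[t, i])
                ]
                assert len(hits) <= 1  # masks disjoint
                covered += bool(hits)
        assert covered / total >= 0.99

    def test_tracklet_composition_matches_aggregates(self, tiny_scene, tiny_graph):
        """Agents share a blob iff they share a ground-truth contact cluster,
        up to a 1-frame tolerance at merge/split boundaries and the ~2 px by
        which thresholded masks fuse before the bodies geometrically touch."""
        from tagtrax.synthetic_arena import capsule_distance

        agents, _, gt, _ = tiny_scene
        for tr in tiny_graph.tracklets:
            for blob in tr.blobs:
                t = blob.frame_index
                members = blob_members(blob, gt)
                if len(members) < 2:
                    continue
                labels = {gt.aggregate[t, i] for i in members}
                if len(labels) == 1:
                    continue
                # disagreement allowed at cluster transitions ...
                window = gt.aggregate[max(0, t - 1) : t + 2]
                if not all(np.array_equal(window[0], w) for w in window):
                    continue
                # ... or when the clusters are within mask-fusing distance
                gap = min(
                    capsule_distance(
                        gt.pos[t, i], gt.heading[t, i], agents[i],
                        gt.pos[t, j], gt.heading[t, j], agents[j],
                    )
                    for i in members
                    for j in members
                    if gt.aggregate[t, i] != gt.aggregate[t, j]
                )
                assert gap <= 2.5, f"distant clusters share a blob at frame {t}"
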