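"""Shared fixtures: scripted and simulated scenes, tracked graphs.

Everything is generated programmatically and deterministically; no data
files are stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from tagtrax import (
    ArenaSpec,
    GroundTruth,
    MotionParams,
    NoiseParams,
    RunConfig,
    agents_from_labels,
    render,
    simulate,
)
from tagtrax.tracklet_graph import Tracklet, TrackletGraph, build_graph


def scripted_merge_split(overlap_frames: int = 8, n_frames: int = 60):
    """Two agents approach head-on, overlap, then separate (one merge/split).

    Returns (agents, arena, gt, frames).
    """
    agents = agents_from_labels(["BG", "OP"])
    arena = ArenaSpec(256, 96)
    pos = np.zeros((n_frames, 2, 2))
    head = np.zeros((n_frames, 2))
    head[:, 1] = np.pi
    approach_end = 22
    for t in range(n_frames):
        if t < approach_end:
            d = 160 - 6.5 * t
        elif t < approach_end + overlap_frames:
            d = 160 - 6.5 * (approach_end - 0.01)
        else:
            d = (160 - 6.5 * (approach_end - 0.01)) + 6.5 * (t - approach_end - overlap_frames + 1)
        d = max(d, 17.0)
        pos[t, 0] = [120 - d / 2, 48]
        pos[t, 1] = [120 + d / 2, 48]
    gt = GroundTruth(
        ("BG", "OP"),
        pos,
        head,
        np.ones((n_frames, 2), bool),
        np.zeros((n_frames, 2), int),
    )
    frames = render(gt, agents, arena, NoiseParams(sigma=2), seed=3)
    return agents, arena, gt, frames


@pytest.fixture(scope="session")
def motif_scene():
    return scripted_merge_split()


@pytest.fixture(scope="session")
def motif_graph(motif_scene):
    _, _, _, frames = motif_scene
    return build_graph(frames, RunConfig())


@pytest.fixture(scope="session")
def tiny_scene():
    """4 agents, 250 frames, closed arena with aggregation on."""
    agents = agents_from_labels(["BG", "OP", "GO", "PB"])
    arena = ArenaSpec(192, 192)
    motion = MotionParams(p_social_on=0.03)
    gt = simulate(agents, arena, 250, motion, seed=42)
    frames = render(gt, agents, arena, seed=43)
    return agents, arena, gt, frames


@pytest.fixture(scope="session")
def tiny_graph(tiny_scene):
    _, _, _, frames = tiny_scene
    return build_graph(frames, RunConfig(seed=1))


def abstract_motif(n_frames: int = 30) -> TrackletGraph:
    """The canonical merge/split motif as a bare graph (no blobs):

    singles tau1, tau2 -> multi tau3 -> singles tau4, tau5.
    """
    g = TrackletGraph(n_frames=n_frames, open_boundary=False)
    third = n_frames // 3
    spans = [
        (0, third - 1, "single"),
        (0, third - 1, "single"),
        (third, 2 * third - 1, "multi"),
        (2 * third, n_frames - 1, "single"),
        (2 * third, n_frames - 1, "single"),
    ]
    for i, (s, e, k) in enumerate(spans):
        g.add_tracklet(Tracklet(i, s, e, kind=k))
    for u, v in [(0, 2), (1, 2), (2, 3), (2, 4)]:
        g.add_edge(u, v)
    return g
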