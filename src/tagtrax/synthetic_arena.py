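"""Synthetic arena: simulate and render color-tagged agents with ground truth.

This module stands in for benchmark videos: it simulates N tagged agents
moving in a bounded 2D arena (correlated random walk with heading
persistence, soft-core repulsion, and optional attraction that creates
transient aggregates), renders each frame as a light background with dark
elongated bodies carrying small colored tag patches, and records full
per-frame ground truth (position, heading, presence, contact-cluster
label).

Conventions used repo-wide: 0-based pixel indices, x rightward, y
downward, centroids as floats, headings in radians measured from +x
toward +y (i.e. screen-clockwise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "TAG_PALETTE",
    "AgentSpec",
    "ArenaSpec",
    "MotionParams",
    "NoiseParams",
    "GroundTruth",
    "FrameSequence",
    "simulate",
    "render",
    "render_frame",
    "write_fixture",
    "read_fixture_gt",
    "agents_from_labels",
    "small16",
    "capsule_distance",
]

#: Named tag colors (RGB). Letters follow the usual field shorthand:
#: B(lue), G(reen), O(range), P(ink), Y(ellow), W(hite).
TAG_PALETTE: dict[str, tuple[int, int, int]] = {
    "B": (45, 80, 235),
    "G": (60, 205, 75),
    "O": (255, 150, 40),
    "P": (250, 100, 180),
    "Y": (245, 225, 60),
    "W": (245, 245, 245),
}

_BG_COLOR = np.array([231.0, 229.0, 225.0])
_BODY_COLOR = np.array([58.0, 55.0, 52.0])
_HEAD_COLOR = np.array([24.0, 23.0, 25.0])


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AgentSpec:
    """One tagged individual.

    ``id_label`` is the tag-color combination read head-to-tail (e.g. "BG"
    is a blue thorax tag and a green abdomen tag). ``tag_colors`` holds the
    1-3 RGB patches in the same head-to-tail order.
    """

    id_label: str
    tag_colors: tuple[tuple[int, int, int], ...]
    body_length_px: float = 22.0
    speed_px_per_frame: float = 2.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.tag_colors) <= 3:
            raise ValueError("an agent carries between 1 and 3 tags")
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")
        if self.speed_px_per_frame < 0:
            raise ValueError("speed_px_per_frame must be non-negative")

    @property
    def body_width_px(self) -> float:
        return self.body_length_px / 3.0


@dataclass
class ArenaSpec:
    """Arena geometry and region of interest.

    ``roi_mask`` is a boolean raster with the frame's shape; ``None`` means
    the whole frame is tracked. ``open_boundary`` states whether agents may
    leave/enter the ROI (they always stay inside the frame itself).
    """

    width_px: int
    height_px: int
    roi_mask: np.ndarray | None = None
    open_boundary: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("arena dimensions must be positive integers")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != (self.height_px, self.width_px):
                raise ValueError("roi_mask dimensions must equal frame dimensions")

    def full_mask(self) -> np.ndarray:
        if self.roi_mask is not None:
            return self.roi_mask
        return np.ones((self.height_px, self.width_px), dtype=bool)


@dataclass
class MotionParams:
    """Parameters of the correlated random walk.

    Agents alternate between a wandering state and a social state. Social
    agents steer toward their nearest neighbor (strength ``attraction``)
    until they touch, then slow down — this is what creates transient
    aggregates. Soft-core repulsion keeps centers at least
    ``min_center_frac`` body lengths apart, so bodies overlap partially
    (touch) but never coincide.
    """

    attraction: float = 0.25  # 0..1 steering blend toward neighbor
    attract_radius_px: float = 120.0
    p_social_on: float = 0.015
    p_social_off: float = 0.010
    rest_prob: float = 0.02  # per-frame probability to start resting
    p_rest_off: float = 0.25
    heading_sigma: float = 0.30  # rad/frame of heading noise while wandering
    aggregate_speed_factor: float = 0.25
    min_center_frac: float = 0.35  # of mean body length


@dataclass
class NoiseParams:
    """Rendering noise: i.i.d. additive Gaussian pixel noise (8-bit units)."""

    sigma: float = 3.0


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-frame, per-agent truth produced by :func:`simulate`.

    Arrays are shaped ``(n_frames, n_agents)`` (positions have a trailing
    xy axis). ``aggregate`` holds the contact-cluster label of each agent:
    the smallest agent index in its transitive touch-cluster.
    """

    labels: tuple[str, ...]
    pos: np.ndarray  # (T, N, 2) float, x/y
    heading: np.ndarray  # (T, N) float radians
    present: np.ndarray  # (T, N) bool
    aggregate: np.ndarray  # (T, N) int

    @property
    def n_frames(self) -> int:
        return self.pos.shape[0]

    @property
    def n_agents(self) -> int:
        return self.pos.shape[1]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_dataframe(self) -> pd.DataFrame:
        t_idx, a_idx = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_agents), indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": t_idx.ravel(),
                "id_label": np.array(self.labels)[a_idx.ravel()],
                "x": self.pos[..., 0].ravel(),
                "y": self.pos[..., 1].ravel(),
                "heading": self.heading.ravel(),
                "present": self.present.ravel().astype(int),
                "aggregate": self.aggregate.ravel(),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroundTruth":
        labels = tuple(pd.unique(df["id_label"]))
        n = len(labels)
        t = int(df["frame"].max()) + 1
        order = {lab: i for i, lab in enumerate(labels)}
        pos = np.zeros((t, n, 2))
        heading = np.zeros((t, n))
        present = np.zeros((t, n), dtype=bool)
        aggregate = np.zeros((t, n), dtype=int)
        fi = df["frame"].to_numpy()
        ai = df["id_label"].map(order).to_numpy()
        pos[fi, ai, 0] = df["x"].to_numpy()
        pos[fi, ai, 1] = df["y"].to_numpy()
        heading[fi, ai] = df["heading"].to_numpy()
        present[fi, ai] = df["present"].to_numpy().astype(bool)
        aggregate[fi, ai] = df["aggregate"].to_numpy()
        return cls(labels, pos, heading, present, aggregate)


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------


def _capsule_segment(pos: np.ndarray, heading: float, agent: AgentSpec):
    """Endpoints of the body's center segment (tail, head)."""
    half = 0.5 * (agent.body_length_px - agent.body_width_px)
    u = np.array([np.cos(heading), np.sin(heading)])
    return pos - half * u, pos + half * u


def _seg_seg_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between two 2D segments (standard clamped form)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    if a <= 1e-12 and e <= 1e-12:
        return float(np.hypot(*r))
    if a <= 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.hypot(*(closest1 - closest2)))


def capsule_distance(
    pos_i, heading_i, agent_i: AgentSpec, pos_j, heading_j, agent_j: AgentSpec
) -> float:
    """Surface-to-surface distance between two body capsules (<= 0 = touching)."""
    pi, qi = _capsule_segment(np.asarray(pos_i, float), heading_i, agent_i)
    pj, qj = _capsule_segment(np.asarray(pos_j, float), heading_j, agent_j)
    d = _seg_seg_distance(pi, qi, pj, qj)
    return d - 0.5 * (agent_i.body_width_px + agent_j.body_width_px)


def _contact_clusters(
    pos: np.ndarray, heading: np.ndarray, agents: Sequence[AgentSpec], present: np.ndarray
) -> np.ndarray:
    """Transitive touch-cluster label (min member index) per agent."""
    n = len(agents)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        if not present[i]:
            continue
        for j in range(i + 1, n):
            if not present[j]:
                continue
            # quick reject on center distance
            if np.hypot(*(pos[i] - pos[j])) > agents[i].body_length_px + agents[j].body_length_px:
                continue
            if capsule_distance(pos[i], heading[i], agents[i], pos[j], heading[j], agents[j]) <= 0.0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return np.array([find(i) for i in range(n)], dtype=int)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------


def simulate(
    agents: Sequence[AgentSpec],
    arena: ArenaSpec,
    n_frames: int,
    motion: MotionParams | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Simulate agent motion; deterministic given ``seed``.

    Raises ``ValueError`` for an empty agent list, non-positive frame count,
    or duplicate ID labels.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(agents) == 0:
        raise ValueError("agent list must not be empty")
    labels = [a.id_label for a in agents]
    if len(set(labels)) != len(labels):
        raise ValueError("agent id_labels must be unique")
    motion = motion or MotionParams()
    rng = np.random.default_rng(seed)
    n = len(agents)
    w, h = arena.width_px, arena.height_px
    margin = max(a.body_length_px for a in agents) / 2.0 + 1.0
    if w <= 2 * margin or h <= 2 * margin:
        raise ValueError("arena too small for the given body lengths")

    # initial positions: rejection-sample for pairwise separation
    pos = np.empty((n, 2))
    min_sep = 1.2 * max(a.body_length_px for a in agents)
    for i in range(n):
        for _ in range(200):
            cand = rng.uniform([margin, margin], [w - 1 - margin, h - 1 - margin])
            if all(np.hypot(*(cand - pos[j])) > min_sep for j in range(i)):
                break
        pos[i] = cand
    heading = rng.uniform(0.0, 2 * np.pi, n)
    social = np.zeros(n, dtype=bool)
    resting = np.zeros(n, dtype=bool)
    speeds = np.array([a.speed_px_per_frame for a in agents])
    mean_len = float(np.mean([a.body_length_px for a in agents]))
    d_min = motion.min_center_frac * mean_len
    roi = arena.full_mask()

    out_pos = np.empty((n_frames, n, 2))
    out_head = np.empty((n_frames, n))
    out_present = np.empty((n_frames, n), dtype=bool)
    out_agg = np.empty((n_frames, n), dtype=int)

    for t in range(n_frames):
        if arena.open_boundary:
            xi = np.clip(np.round(pos[:, 0]).astype(int), 0, w - 1)
            yi = np.clip(np.round(pos[:, 1]).astype(int), 0, h - 1)
            present = roi[yi, xi]
        else:
            present = np.ones(n, dtype=bool)
        out_pos[t] = pos
        out_head[t] = heading
        out_present[t] = present
        out_agg[t] = _contact_clusters(pos, heading, agents, present)
        if t == n_frames - 1:
            break

        # state switching
        u = rng.random((4, n))
        social = np.where(social, u[0] >= motion.p_social_off,
                          u[0] < motion.p_social_on * (motion.attraction > 0))
        resting = np.where(resting, u[1] >= motion.p_rest_off, u[1] < motion.rest_prob)

        in_contact = out_agg[t] != np.arange(n)
        # min-index members of nontrivial clusters are also "in contact"
        for i in range(n):
            if out_agg[t][i] == i and np.any(out_agg[t] == i) and np.sum(out_agg[t] == i) > 1:
                in_contact[i] = True

        noise = rng.normal(0.0, motion.heading_sigma, n)
        noise[in_contact & social] *= 0.3
        heading = heading + noise

        # social steering toward nearest neighbor
        if motion.attraction > 0:
            for i in np.flatnonzero(social & ~in_contact & ~resting):
                d = np.hypot(pos[:, 0] - pos[i, 0], pos[:, 1] - pos[i, 1])
                d[i] = np.inf
                j = int(np.argmin(d))
                if d[j] <= motion.attract_radius_px:
                    bearing = np.arctan2(pos[j, 1] - pos[i, 1], pos[j, 0] - pos[i, 0])
                    delta = np.angle(np.exp(1j * (bearing - heading[i])))
                    heading[i] = heading[i] + motion.attraction * delta

        v = speeds * ~resting
        v[in_contact & social] *= motion.aggregate_speed_factor
        pos = pos + np.column_stack([v * np.cos(heading), v * np.sin(heading)])

        # soft-core repulsion (one relaxation pass)
        for i in range(n):
            for j in range(i + 1, n):
                dvec = pos[j] - pos[i]
                dist = float(np.hypot(*dvec))
                if dist < d_min:
                    if dist < 1e-9:
                        ang = rng.uniform(0, 2 * np.pi)
                        dvec = np.array([np.cos(ang), np.sin(ang)])
                        dist = 1e-9
                    push = 0.5 * (d_min - dist) * dvec / dist
                    pos[i] -= push
                    pos[j] += push

        # walls: clamp to frame with body margin, reflect heading
        lo = np.array([margin, margin])
        hi = np.array([w - 1 - margin, h - 1 - margin])
        below = pos < lo
        above = pos > hi
        pos = np.clip(pos, lo, hi)
        flip_x = below[:, 0] | above[:, 0]
        flip_y = below[:, 1] | above[:, 1]
        heading = np.where(flip_x, np.pi - heading, heading)
        heading = np.where(flip_y, -heading, heading)
        heading = np.mod(heading, 2 * np.pi)

    return GroundTruth(tuple(labels), out_pos, out_head, out_present, out_agg)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _draw_agent(img: np.ndarray, pos: np.ndarray, heading: float, agent: AgentSpec) -> None:
    """Alpha-composite one agent (capsule body, darker head cap, tag squares)."""
    h, w = img.shape[:2]
    L = agent.body_length_px
    wd = agent.body_width_px
    r = wd / 2.0
    half = 0.5 * (L - wd)
    ux, uy = np.cos(heading), np.sin(heading)
    pad = L / 2.0 + 2.0
    x0 = max(0, int(np.floor(pos[0] - pad)))
    x1 = min(w, int(np.ceil(pos[0] + pad)) + 1)
    y0 = max(0, int(np.floor(pos[1] - pad)))
    y1 = min(h, int(np.ceil(pos[1] + pad)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - pos[0]
    dy = ys - pos[1]
    along = dx * ux + dy * uy  # head-positive axis coordinate
    perp = -dx * uy + dy * ux
    clamped = np.clip(along, -half, half)
    dist = np.hypot(along - clamped, perp)
    body_alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)

    sub = img[y0:y1, x0:x1]
    sub *= (1.0 - body_alpha)[..., None]
    sub += body_alpha[..., None] * _BODY_COLOR

    # darker head cap at the front end (breaks fore-aft symmetry)
    head_d = np.hypot(along - half, perp)
    head_alpha = np.clip(0.9 * r + 0.5 - head_d, 0.0, 1.0) * (along > 0.3 * half)
    sub *= (1.0 - head_alpha)[..., None]
    sub += head_alpha[..., None] * _HEAD_COLOR

    # tag patches along the axis, head-to-tail order
    n_tags = len(agent.tag_colors)
    if n_tags == 1:
        offsets = [-0.05 * L]
    elif n_tags == 2:
        offsets = [0.08 * L, -0.26 * L]
    else:
        offsets = [0.14 * L, -0.06 * L, -0.30 * L]
    s = max(3.0, L / 5.0)
    for off, color in zip(offsets, agent.tag_colors):
        tag_alpha = (
            np.clip(s / 2 + 0.5 - np.abs(along - off), 0, 1)
            * np.clip(s / 2 + 0.5 - np.abs(perp), 0, 1)
            * (body_alpha > 0.5)
        )
        sub *= (1.0 - tag_alpha)[..., None]
        sub += tag_alpha[..., None] * np.asarray(color, float)


def render_frame(
    gt: GroundTruth,
    agents: Sequence[AgentSpec],
    arena: ArenaSpec,
    t: int,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render frame ``t`` as an (H, W, 3) uint8 image; deterministic per frame.

    Drawing order of overlapping agents is randomized per frame so that tags
    of a lower-drawn agent can be hidden, as happens with real occlusions.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng([seed, t])
    h, w = arena.height_px, arena.width_px
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _BG_COLOR
    order = rng.permutation(gt.n_agents)
    for i in order:
        if gt.present[t, i]:
            _draw_agent(img, gt.pos[t, i], gt.heading[t, i], agents[i])
    if noise.sigma > 0:
        img += rng.normal(0.0, noise.sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


class FrameSequence:
    """Lazy, random-access rendered frame sequence.

    Frames are rendered on demand (deterministically, each from its own
    seed stream), so long videos never have to be materialized in memory.
    """

    def __init__(self, gt: GroundTruth, agents, arena, noise=None, seed: int = 0):
        if len(agents) != gt.n_agents:
            raise ValueError("ground truth is inconsistent with the agent list")
        self.gt = gt
        self.agents = tuple(agents)
        self.arena = arena
        self.noise = noise or NoiseParams()
        self.seed = seed

    def __len__(self) -> int:
        return self.gt.n_frames

    def __getitem__(self, t: int) -> np.ndarray:
        if t < 0:
            t += len(self)
        if not 0 <= t < len(self):
            raise IndexError(t)
        return render_frame(self.gt, self.agents, self.arena, t, self.noise, self.seed)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.arena.height_px, self.arena.width_px)


def render(
    gt: GroundTruth,
    agents: Sequence[AgentSpec],
    arena: ArenaSpec,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> FrameSequence:
    """Rendered view of a simulation (lazy; index it like a list of frames)."""
    return FrameSequence(gt, agents, arena, noise, seed)


# --------------------------------------------------------------------------
# Fixtures on disk
# --------------------------------------------------------------------------


def write_fixture(
    gt: GroundTruth,
    frames: FrameSequence | Sequence[np.ndarray],
    path: str | Path,
    spec: dict | None = None,
) -> Path:
    """Write ``frames/%06d.png``, ``gt.csv`` and ``spec.json`` under ``path``."""
    path = Path(path)
    (path / "frames").mkdir(parents=True, exist_ok=True)
    for t in range(len(frames)):
        iio.imwrite(path / "frames" / f"{t:06d}.png", frames[t])
    gt.to_dataframe().to_csv(path / "gt.csv", index=False)
    with open(path / "spec.json", "w") as fh:
        json.dump(spec or {}, fh, indent=2, sort_keys=True)
    return path


def read_fixture_gt(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dataframe(pd.read_csv(path / "gt.csv" if isinstance(path, Path) else Path(path) / "gt.csv"))


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------


def agents_from_labels(
    labels: Sequence[str],
    body_length_px: float = 22.0,
    speed_px_per_frame: float = 2.0,
) -> list[AgentSpec]:
    """Build agents whose tag colors spell out their labels (e.g. "BG")."""
    out = []
    for lab in labels:
        colors = tuple(TAG_PALETTE[c] for c in lab)
        out.append(AgentSpec(lab, colors, body_length_px, speed_px_per_frame))
    return out


def small16(n_frames: int = 2000, seed: int = 1234, open_boundary: bool = False):
    """The standard 16-agent fixture: 4 colors x 2 tags, closed 384x384 arena.

    Mirrors the canonical benchmark condition of 16 individuals tagged with
    ordered two-color combinations drawn from four colors, filmed at a
    resolution where a body spans ~22 px.

    Returns ``(agents, arena, motion, gt)``.
    """
    labels = [a + b for a in "BGOP" for b in "BGOP"]
    agents = agents_from_labels(labels)
    roi = None
    if open_boundary:
        yy, xx = np.mgrid[0:384, 0:384]
        roi = (np.hypot(xx - 192, yy - 192) < 150).astype(bool)
    arena = ArenaSpec(384, 384, roi_mask=roi, open_boundary=open_boundary)
    motion = MotionParams()
    gt = simulate(agents, arena, n_frames, motion, seed=seed)
    return agents, arena, motion, gt
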