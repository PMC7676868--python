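"""Blob linking across frames and construction of the tracklet graph.

Blobs in consecutive frames are linked either by an exclusive-overlap fast
path or, when several linking options exist, by advecting the previous
blob's pixels along a dense optical-flow field and counting where they
land. Tracklets (maximal runs of exclusively linked blobs) are maintained
by four update rules: an unlinked current blob opens a tracklet, an
unlinked previous blob closes its tracklet, an exclusively linked pair
extends a tracklet, and any branching (merge or split) closes all involved
tracklets, opens new ones, and records directed edges from the earlier
tracklets to the later ones. The result over a whole video is a directed
acyclic tracklet graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.registration import optical_flow_ilk

from .config import RunConfig
from .segmentation import Blob, estimate_background, segment_frame

__all__ = [
    "Link",
    "Tracklet",
    "TrackletGraph",
    "GraphBuilder",
    "estimate_flow",
    "link_blobs",
    "build_graph",
]


@dataclass(frozen=True)
class Link:
    """A link from blob ``prev_idx`` (frame t-1) to ``cur_idx`` (frame t).

    ``support`` is the fraction of the previous blob's pixels that land in
    the current blob (1.0 for exclusive-overlap fast-path links).
    """

    prev_idx: int
    cur_idx: int
    support: float


@dataclass
class Tracklet:
    """A maximal run of exclusively linked blobs with constant composition."""

    tracklet_id: int
    start_frame: int
    end_frame: int
    blobs: list[Blob] = field(default_factory=list)
    kind: str = "unknown"  # single | multi | unknown
    label: str | None = None
    confidence: float | None = None
    starts_open: bool = False
    ends_open: bool = False

    @property
    def n_blobs(self) -> int:
        return len(self.blobs)

    def blob_at(self, frame: int) -> Blob:
        if not self.start_frame <= frame <= self.end_frame:
            raise KeyError(f"frame {frame} outside tracklet span")
        return self.blobs[frame - self.start_frame]

    def overlaps(self, other: "Tracklet") -> bool:
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame


class TrackletGraph:
    """Directed acyclic graph over tracklets.

    Nodes are tracklet ids; each node stores its :class:`Tracklet`. Edges go
    from a tracklet ending at frame ``t-1`` to one opening at frame ``t``
    and mean that some or all animals of the first are present in the
    second.
    """

    def __init__(self, n_frames: int = 0, open_boundary: bool = False):
        self.g = nx.DiGraph()
        self.n_frames = n_frames
        self.open_boundary = open_boundary

    # -- construction ------------------------------------------------------

    def add_tracklet(self, tr: Tracklet) -> None:
        self.g.add_node(tr.tracklet_id, tracklet=tr)

    def add_edge(self, from_id: int, to_id: int) -> None:
        t_from = self.tracklet(from_id)
        t_to = self.tracklet(to_id)
        if t_to.start_frame != t_from.end_frame + 1:
            raise ValueError("edges must join consecutive-frame tracklets")
        self.g.add_edge(from_id, to_id)

    # -- access ------------------------------------------------------------

    def tracklet(self, tid: int) -> Tracklet:
        return self.g.nodes[tid]["tracklet"]

    @property
    def tracklets(self) -> list[Tracklet]:
        return [self.g.nodes[n]["tracklet"] for n in sorted(self.g.nodes)]

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.g.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.g.edges)

    def successors(self, tid: int) -> list[int]:
        return sorted(self.g.successors(tid))

    def predecessors(self, tid: int) -> list[int]:
        return sorted(self.g.predecessors(tid))

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def assert_valid(self) -> None:
        """Check acyclicity and edge/frame consistency; raise on violation."""
        if not nx.is_directed_acyclic_graph(self.g):
            raise AssertionError("tracklet graph contains a cycle")
        for u, v in self.g.edges:
            if self.tracklet(v).start_frame != self.tracklet(u).end_frame + 1:
                raise AssertionError(f"edge {u}->{v} does not join consecutive frames")

    # -- serialization -----------------------------------------------------

    def to_csv(self, out_dir) -> None:
        import pandas as pd

        rows = [
            {
                "tracklet_id": tr.tracklet_id,
                "start": tr.start_frame,
                "end": tr.end_frame,
                "n_blobs": tr.n_blobs,
                "kind": tr.kind,
                "label": tr.label if tr.label is not None else "",
                "confidence": tr.confidence if tr.confidence is not None else "",
                "starts_open": int(tr.starts_open),
                "ends_open": int(tr.ends_open),
            }
            for tr in self.tracklets
        ]
        pd.DataFrame(rows).to_csv(f"{out_dir}/nodes.csv", index=False)
        pd.DataFrame(self.edges, columns=["from", "to"]).to_csv(
            f"{out_dir}/edges.csv", index=False
        )


# --------------------------------------------------------------------------
# Optical flow
# --------------------------------------------------------------------------


def estimate_flow(
    frame_prev: np.ndarray,
    frame_cur: np.ndarray,
    region_bbox: tuple[int, int, int, int],
    radius: int = 7,
) -> np.ndarray:
    """Dense displacement field over ``region_bbox`` (half-open x0,y0,x1,y1).

    Returns an array of shape (2, h, w): row 0 is the y-displacement, row 1
    the x-displacement, such that a pixel at (y, x) in the previous frame
    moves to (y + dy, x + dx) in the current frame.
    """
    x0, y0, x1, y1 = region_bbox
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty flow region")
    prev = rgb2gray(np.asarray(frame_prev)[y0:y1, x0:x1])
    cur = rgb2gray(np.asarray(frame_cur)[y0:y1, x0:x1])
    return optical_flow_ilk(prev, cur, radius=radius)


# --------------------------------------------------------------------------
# Linking
# --------------------------------------------------------------------------


def _label_map(blobs: Sequence[Blob], shape: tuple[int, int]) -> np.ndarray:
    lm = np.zeros(shape, dtype=np.int32)
    for i, b in enumerate(blobs, start=1):
        x0, y0, x1, y1 = b.bbox
        lm[y0:y1, x0:x1][b.mask] = i
    return lm


def _bbox_near(a: Blob, b: Blob, margin: float) -> bool:
    ax0, ay0, ax1, ay1 = a.bbox
    bx0, by0, bx1, by1 = b.bbox
    return ax0 - margin < bx1 and bx0 - margin < ax1 and ay0 - margin < by1 and by0 - margin < ay1


def link_blobs(
    blobs_prev: Sequence[Blob],
    blobs_cur: Sequence[Blob],
    frame_prev: np.ndarray,
    frame_cur: np.ndarray,
    support_min: float = 0.25,
    search_margin: float = 30.0,
    flow_radius: int = 7,
    single_area_ref: float | None = None,
) -> list[Link]:
    """Link blobs of consecutive frames.

    Fast path: when a previous blob's mask overlaps exactly one current
    blob and vice versa, link directly. Everything else goes through
    optical flow restricted to the region of the ambiguity: the previous
    blob's pixels are advected by the flow and a link is made to every
    current blob (mask dilated by 1 px) catching at least ``support_min``
    of the smaller of the two blobs' areas, capped at ``single_area_ref``
    (the expected single-animal area) when given. A link asserts that at
    least one animal moved between the blobs, so the evidence is measured
    in units of one animal's pixels: without the cap, a single animal
    transferring between two large aggregates carries too small a
    fraction of either pile to register. A blob may end up with zero,
    one, or several links.
    """
    if not blobs_prev or not blobs_cur:
        return []
    shape = np.asarray(frame_cur).shape[:2]
    cur_map = _label_map(blobs_cur, shape)
    np_, nc = len(blobs_prev), len(blobs_cur)

    # pixel-overlap counts prev x cur
    overlap = np.zeros((np_, nc), dtype=np.int64)
    for i, b in enumerate(blobs_prev):
        x0, y0, x1, y1 = b.bbox
        under = cur_map[y0:y1, x0:x1][b.mask]
        vals, counts = np.unique(under[under > 0], return_counts=True)
        overlap[i, vals - 1] = counts

    # candidate adjacency (overlap or bbox proximity)
    cand = overlap > 0
    for i, b in enumerate(blobs_prev):
        for j, c in enumerate(blobs_cur):
            if not cand[i, j] and _bbox_near(b, c, search_margin):
                cand[i, j] = True

    links: list[Link] = []
    resolved_prev = np.zeros(np_, dtype=bool)
    resolved_cur = np.zeros(nc, dtype=bool)

    # exclusive-overlap fast path
    for i in range(np_):
        js = np.flatnonzero(overlap[i] > 0)
        if len(js) == 1:
            j = int(js[0])
            if np.flatnonzero(overlap[:, j] > 0).size == 1:
                denom = min(blobs_prev[i].area_px, blobs_cur[j].area_px)
                if single_area_ref:
                    denom = min(denom, single_area_ref)
                links.append(Link(i, j, float(min(1.0, overlap[i, j] / denom))))
                resolved_prev[i] = True
                resolved_cur[j] = True

    # ambiguous groups: connected components of the candidate bipartite graph
    remaining = [
        (i, j) for i in range(np_) for j in range(nc)
        if cand[i, j] and not (resolved_prev[i] and resolved_cur[j])
    ]
    if not remaining:
        return links

    bi = nx.Graph()
    bi.add_edges_from((("p", i), ("c", j)) for i, j in remaining)
    dilated_cur = ndimage.grey_dilation(cur_map, size=(3, 3))
    h, w = shape

    for comp in nx.connected_components(bi):
        pis = sorted(i for side, i in comp if side == "p" and not resolved_prev[i])
        cjs = sorted(j for side, j in comp if side == "c")
        if not pis or not cjs:
            continue
        boxes = [blobs_prev[i].bbox for i in pis] + [blobs_cur[j].bbox for j in cjs]
        x0 = max(0, min(b[0] for b in boxes) - 10)
        y0 = max(0, min(b[1] for b in boxes) - 10)
        x1 = min(w, max(b[2] for b in boxes) + 10)
        y1 = min(h, max(b[3] for b in boxes) + 10)
        flow = estimate_flow(frame_prev, frame_cur, (x0, y0, x1, y1), radius=flow_radius)
        for i in pis:
            b = blobs_prev[i]
            bx0, by0, bx1, by1 = b.bbox
            ys, xs = np.nonzero(b.mask)
            ys = ys + by0
            xs = xs + bx0
            dy = flow[0][ys - y0, xs - x0]
            dx = flow[1][ys - y0, xs - x0]
            ty = np.clip(np.round(ys + dy).astype(int), 0, h - 1)
            tx = np.clip(np.round(xs + dx).astype(int), 0, w - 1)
            landed = dilated_cur[ty, tx]
            vals, counts = np.unique(landed[landed > 0], return_counts=True)
            landings = {int(v) - 1: int(c) for v, c in zip(vals, counts)}
            for j in cjs:
                # flow advection plus direct mask overlap: overlap is the
                # stronger evidence inside dense, low-texture aggregates
                # where the flow field is unreliable; a surplus link only
                # defers resolution to the graph, a missing one corrupts
                # tracklet compositions
                n_px = max(landings.get(j, 0), int(overlap[i, j]))
                denom = min(b.area_px, blobs_cur[j].area_px)
                if single_area_ref:
                    denom = min(denom, single_area_ref)
                support = float(min(1.0, n_px / denom))
                if support >= support_min:
                    links.append(Link(i, j, support))
    links.sort(key=lambda l: (l.prev_idx, l.cur_idx))
    return links


# --------------------------------------------------------------------------
# Tracklet maintenance
# --------------------------------------------------------------------------


class GraphBuilder:
    """Incrementally applies the tracklet open/close/extend rules."""

    def __init__(self, open_boundary: bool = False):
        self.graph = TrackletGraph(open_boundary=open_boundary)
        self._next_id = 0
        self._open: dict[int, int] = {}  # prev-frame blob index -> tracklet id

    def _open_tracklet(self, t: int, blob: Blob) -> int:
        tid = self._next_id
        self._next_id += 1
        tr = Tracklet(tid, start_frame=t, end_frame=t, blobs=[blob])
        self.graph.add_tracklet(tr)
        return tid

    def step(self, t: int, blobs_cur: Sequence[Blob], links: Sequence[Link]) -> None:
        """Advance to frame ``t`` given links from frame ``t-1``.

        Must be called with t = 0, 1, 2, ... in order; frame 0 takes no links.
        """
        if t == 0:
            self._open = {j: self._open_tracklet(0, b) for j, b in enumerate(blobs_cur)}
            self.graph.n_frames = 1
            return
        for l in links:
            if l.prev_idx not in self._open:
                raise RuntimeError(
                    f"internal consistency failure: link references prev blob "
                    f"{l.prev_idx} with no open tracklet at frame {t - 1}"
                )
        prev_of = {}
        cur_of = {}
        for l in links:
            prev_of.setdefault(l.prev_idx, []).append(l.cur_idx)
            cur_of.setdefault(l.cur_idx, []).append(l.prev_idx)

        new_open: dict[int, int] = {}
        handled_cur: set[int] = set()

        # bipartite components of the link relation
        bi = nx.Graph()
        bi.add_edges_from((("p", l.prev_idx), ("c", l.cur_idx)) for l in links)
        for comp in nx.connected_components(bi):
            pis = sorted(i for side, i in comp if side == "p")
            cjs = sorted(j for side, j in comp if side == "c")
            if len(pis) == 1 and len(cjs) == 1:
                # rule (iii): exclusive link extends the tracklet
                tid = self._open[pis[0]]
                tr = self.graph.tracklet(tid)
                tr.blobs.append(blobs_cur[cjs[0]])
                tr.end_frame = t
                new_open[cjs[0]] = tid
            else:
                # rule (iv): branching closes all prev, opens all cur, adds edges
                new_ids = {j: self._open_tracklet(t, blobs_cur[j]) for j in cjs}
                for l in links:
                    if l.prev_idx in pis and l.cur_idx in cjs:
                        self.graph.add_edge(self._open[l.prev_idx], new_ids[l.cur_idx])
                new_open.update(new_ids)
            handled_cur.update(cjs)

        # rule (i): unlinked current blobs open tracklets
        for j, b in enumerate(blobs_cur):
            if j not in handled_cur:
                new_open[j] = self._open_tracklet(t, b)
        # rule (ii): unlinked previous blobs close implicitly (dropped from _open)
        self._open = new_open
        self.graph.n_frames = t + 1

    def finalize(self, boundary_margin: float = 12.0) -> TrackletGraph:
        """Set boundary flags and return the finished graph."""
        g = self.graph
        for tr in g.tracklets:
            if g.open_boundary:
                if not g.predecessors(tr.tracklet_id) and tr.blobs and tr.blobs[0].touches_boundary:
                    tr.starts_open = True
                if not g.successors(tr.tracklet_id) and tr.blobs and tr.blobs[-1].touches_boundary:
                    tr.ends_open = True
        g.assert_valid()
        return g


def update_tracklets(builder: GraphBuilder, t: int, blobs_cur, links) -> None:
    """Functional alias for one tracklet-update step (see GraphBuilder.step)."""
    builder.step(t, blobs_cur, links)


# --------------------------------------------------------------------------
# Full pipeline over a frame sequence
# --------------------------------------------------------------------------


def build_graph(
    frames,
    config: RunConfig,
    roi_mask: np.ndarray | None = None,
    open_boundary: bool = False,
    bg: "BackgroundModel | None" = None,
    return_blobs: bool = False,
):
    """Run segmentation + linking + tracklet maintenance over all frames.

    ``frames`` is any indexable sequence of (H, W, 3) uint8 frames.
    Returns the :class:`TrackletGraph` (and optionally per-frame blob lists).
    """
    config.validate()
    if bg is None:
        bg = estimate_background(frames, n_samples=config.bg_samples)
    builder = GraphBuilder(open_boundary=open_boundary)
    prev_blobs: list[Blob] = []
    prev_frame = None
    all_blobs = []
    for t in range(len(frames)):
        try:
            frame = np.asarray(frames[t])
        except Exception as exc:  # pragma: no cover - IO failure path
            raise RuntimeError(f"unreadable frame at index {t}") from exc
        blobs = segment_frame(
            frame,
            bg,
            threshold=config.threshold,
            min_area=config.effective_min_area,
            roi_mask=roi_mask,
            crop_px=config.crop_px,
            store_crops=config.store_crops,
            frame_index=t,
        )
        if t == 0:
            links: list[Link] = []
        else:
            links = link_blobs(
                prev_blobs,
                blobs,
                prev_frame,
                frame,
                support_min=config.support_min,
                search_margin=config.link_search_margin_px,
                flow_radius=config.flow_radius,
                single_area_ref=config.expected_body_area_px,
            )
        builder.step(t, blobs, links)
        if return_blobs:
            all_blobs.append(blobs)
        prev_blobs, prev_frame = blobs, frame
    graph = builder.finalize(boundary_margin=config.boundary_margin_px)
    if return_blobs:
        return graph, all_blobs
    return graph
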