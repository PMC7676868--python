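"""Greedy iterative ID propagation on the tracklet graph.

Each node carries a dynamic set of *assigned* IDs (proven present) and
*possible* IDs (not yet excluded). Starting from classifier seeds ranked
by confidence, IDs are propagated until a fixpoint:

R1 (positive-vertical)  an assigned ID must continue to some successor and
    come from some predecessor; when exactly one neighbor can still carry
    it, the ID is assigned there. Several candidates = ambiguity = no move.
R2 (negative-vertical)  an ID is removed from a node's possible set when no
    predecessor (or no successor) can carry it.
R3 (horizontal)         an ID assigned to a node is excluded from every
    time-overlapping node.
R4 (capacity/coverage)  a node must host at least as many IDs as its blobs
    contain animals (1; 2 for known-multi): when the possible set shrinks
    to that lower bound, all remaining IDs are forced. In a closed arena
    each ID must be somewhere in every frame: an ID with exactly one
    covering candidate node at some frame is assigned there. The coverage
    rule is disabled when the graph has detection gaps (nodes opening or
    closing mid-video without edges), since the ID could then be hiding in
    an undetected blob.
R5 (boundary)           tracklets entering/leaving an open ROI boundary are
    exempt from the vertical and coverage requirements on that side.

Only non-ambiguous propagation is performed. A contradiction (an ID forced
where it is excluded, a vanishing continuation, an emptied possible set)
rolls back everything derived from the current seed and records the seed
as contradicted — the lower-confidence seed loses.

An exhaustive oracle (:func:`oracle_solve`) enumerates every complete
consistent composition of a small closed-ROI graph and returns the
assignments common to all of them; the greedy solver is sound iff its
output is a subset of that forced set.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .classification import TrackletClassification
from .tracklet_graph import Tracklet, TrackletGraph

__all__ = [
    "IDState",
    "Solution",
    "Contradiction",
    "init_states",
    "rank_seeds",
    "propagate",
    "solve",
    "oracle_solve",
    "random_composition_graph",
    "random_seeds",
]


class Contradiction(Exception):
    """Raised internally when a propagation step contradicts the state."""

    def __init__(self, node: int, id_label: str, reason: str):
        super().__init__(f"node {node}, ID {id_label}: {reason}")
        self.node = node
        self.id_label = id_label
        self.reason = reason


@dataclass
class IDState:
    """Per-node assigned/possible ID sets plus assignment provenance."""

    ids: tuple[str, ...]
    possible: dict[int, set[str]]
    assigned: dict[int, set[str]]
    provenance: dict[tuple[int, str], str] = field(default_factory=dict)

    def check_invariants(self) -> None:
        for v in self.possible:
            if not self.assigned[v] <= self.possible[v]:
                raise AssertionError(f"assigned not subset of possible at node {v}")


@dataclass
class Solution:
    """Final propagation result."""

    states: IDState
    contradicted: list[tuple[int, str]] = field(default_factory=list)
    n_mutations: int = 0
    seeds_applied: int = 0

    @property
    def assignments(self) -> list[tuple[int, str, str]]:
        out = []
        for v in sorted(self.states.assigned):
            for i in sorted(self.states.assigned[v]):
                out.append((v, i, self.states.provenance.get((v, i), "propagated")))
        return out


def init_states(graph: TrackletGraph, ids: Sequence[str]) -> IDState:
    """All nodes possible for all IDs, nothing assigned."""
    if len(ids) == 0:
        raise ValueError("ids must be non-empty")
    ids = tuple(ids)
    return IDState(
        ids=ids,
        possible={v: set(ids) for v in graph.node_ids},
        assigned={v: set() for v in graph.node_ids},
    )


def rank_seeds(
    classifications: Iterable[TrackletClassification],
) -> list[tuple[int, str, float]]:
    """Labeled single-animal tracklets by descending confidence.

    Ties break by earlier start frame, then lower tracklet id, so the seed
    order is deterministic.
    """
    seeds = [
        (c.tracklet_id, c.label, c.confidence, c.start_frame)
        for c in classifications
        if c.kind == "single" and c.label is not None
    ]
    seeds.sort(key=lambda s: (-s[2], s[3], s[0]))
    return [(tid, lab, conf) for tid, lab, conf, _ in seeds]


# --------------------------------------------------------------------------
# Rule engine
# --------------------------------------------------------------------------

_CAP = {"single": (1, 1), "multi": (2, None), "unknown": (1, None)}


class _Engine:
    """Precomputed graph structure + journaled rule application."""

    def __init__(self, graph: TrackletGraph, states: IDState):
        self.graph = graph
        self.st = states
        n_ids = len(states.ids)
        self.nodes = graph.node_ids
        self.order = sorted(self.nodes, key=lambda v: (graph.tracklet(v).start_frame, v))
        self.succs = {v: graph.successors(v) for v in self.nodes}
        self.preds = {v: graph.predecessors(v) for v in self.nodes}
        self.span = {
            v: (graph.tracklet(v).start_frame, graph.tracklet(v).end_frame)
            for v in self.nodes
        }
        last = graph.n_frames - 1
        self.cap_lo, self.cap_hi = {}, {}
        self.start_exempt, self.end_exempt = {}, {}
        gap_free = True
        # optional per-animal blob-area bound: a blob of area U holds at
        # least ceil(U / area_per_animal) animals when no single animal's
        # blob can exceed area_per_animal
        area_cap = getattr(graph, "area_per_animal", None)
        for v in self.nodes:
            tr = graph.tracklet(v)
            lo, hi = _CAP.get(tr.kind, (1, None))
            if area_cap and tr.blobs:
                u_max = max(b.area_px for b in tr.blobs)
                lo = max(lo, int(np.ceil(u_max / area_cap)))
            self.cap_lo[v] = min(lo, n_ids)
            self.cap_hi[v] = n_ids if hi is None else hi
            s_gap = not self.preds[v] and tr.start_frame > 0 and not tr.starts_open
            e_gap = not self.succs[v] and tr.end_frame < last and not tr.ends_open
            gap_free = gap_free and not (s_gap or e_gap)
            self.start_exempt[v] = tr.start_frame == 0 or tr.starts_open or not self.preds[v]
            self.end_exempt[v] = tr.end_frame == last or tr.ends_open or not self.succs[v]
        self.closed = not graph.open_boundary
        self.coverage_enabled = self.closed and gap_free

        # time-overlap adjacency via sweep over start frames
        by_start = sorted(self.nodes, key=lambda v: self.span[v][0])
        starts = [self.span[v][0] for v in by_start]
        self.overlap: dict[int, list[int]] = {v: [] for v in self.nodes}
        for v in self.nodes:
            s, e = self.span[v]
            hi_idx = bisect_right(starts, e)
            for u in by_start[:hi_idx]:
                if u != v and self.span[u][1] >= s:
                    self.overlap[v].append(u)

        # coverage lists at event frames (starts of nodes)
        if self.coverage_enabled:
            ev = sorted({self.span[v][0] for v in self.nodes})
            cover: dict[int, list[int]] = {t: [] for t in ev}
            for v in self.order:
                s, e = self.span[v]
                k = bisect_right(ev, e)
                j = bisect_right(ev, s) - 1
                for t in ev[max(j, 0) : k]:
                    if s <= t <= e:
                        cover[t].append(v)
            self.event_frames = ev
            self.cover = cover

        self.journal: list[tuple[str, int, str]] = []
        self.n_mutations = 0

    # -- journaled primitives ---------------------------------------------

    def assign(self, v: int, i: str, provenance: str = "propagated") -> bool:
        st = self.st
        if i in st.assigned[v]:
            return False
        if i not in st.possible[v]:
            raise Contradiction(v, i, "assigning an excluded ID")
        if len(st.assigned[v]) + 1 > self.cap_hi[v]:
            raise Contradiction(v, i, "capacity exceeded")
        st.assigned[v].add(i)
        st.provenance[(v, i)] = provenance
        self.journal.append(("assign", v, i))
        self.n_mutations += 1
        # R3: horizontal exclusion
        for u in self.overlap[v]:
            self.exclude(u, i)
        # capacity saturation
        if len(st.assigned[v]) >= self.cap_hi[v]:
            for j in sorted(st.possible[v] - st.assigned[v]):
                self.exclude(v, j)
        return True

    def exclude(self, v: int, i: str) -> bool:
        st = self.st
        if i not in st.possible[v]:
            return False
        if i in st.assigned[v]:
            raise Contradiction(v, i, "excluding an assigned ID")
        st.possible[v].remove(i)
        self.journal.append(("exclude", v, i))
        self.n_mutations += 1
        if len(st.possible[v]) < self.cap_lo[v]:
            raise Contradiction(v, i, "fewer possible IDs than animals in the node")
        return True

    def rollback(self, mark: int) -> None:
        st = self.st
        while len(self.journal) > mark:
            op, v, i = self.journal.pop()
            if op == "assign":
                st.assigned[v].discard(i)
                st.provenance.pop((v, i), None)
            else:
                st.possible[v].add(i)

    # -- rules -------------------------------------------------------------

    def _rule_vertical_positive(self) -> bool:
        changed = False
        for v in self.order:
            for i in sorted(self.st.assigned[v]):
                for nbrs, exempt in ((self.succs, self.end_exempt), (self.preds, self.start_exempt)):
                    if exempt[v]:
                        continue
                    ns = nbrs[v]
                    if any(i in self.st.assigned[u] for u in ns):
                        continue
                    cands = [u for u in ns if i in self.st.possible[u]]
                    if not cands:
                        raise Contradiction(v, i, "assigned ID has no continuation")
                    if len(cands) == 1:
                        changed |= self.assign(cands[0], i)
        return changed

    def _rule_vertical_negative(self) -> bool:
        changed = False
        for v in self.order:
            for nbrs, exempt in ((self.preds, self.start_exempt), (self.succs, self.end_exempt)):
                if exempt[v]:
                    continue
                reachable: set[str] = set()
                for u in nbrs[v]:
                    reachable |= self.st.possible[u]
                for i in sorted(self.st.possible[v] - reachable):
                    changed |= self.exclude(v, i)
        return changed

    def _rule_lower_bound(self) -> bool:
        if not self.closed:
            return False
        changed = False
        for v in self.order:
            poss = self.st.possible[v]
            if len(poss) == self.cap_lo[v] and self.st.assigned[v] != poss:
                for i in sorted(poss - self.st.assigned[v]):
                    changed |= self.assign(v, i)
        return changed

    def _rule_coverage(self) -> bool:
        if not self.coverage_enabled:
            return False
        changed = False
        for t in self.event_frames:
            cover = self.cover[t]
            for i in self.st.ids:
                if any(i in self.st.assigned[v] for v in cover):
                    continue
                cands = [v for v in cover if i in self.st.possible[v]]
                if not cands:
                    raise Contradiction(-1, i, f"no node can host the ID at frame {t}")
                if len(cands) == 1:
                    changed |= self.assign(cands[0], i)
        return changed

    def fixpoint(self) -> None:
        while True:
            changed = False
            changed |= self._rule_vertical_positive()
            changed |= self._rule_vertical_negative()
            changed |= self._rule_lower_bound()
            if not changed:
                changed |= self._rule_coverage()
            if not changed:
                return


# --------------------------------------------------------------------------
# Public solver API
# --------------------------------------------------------------------------


def propagate(
    graph: TrackletGraph,
    states: IDState,
    seed_assignment: tuple[int, str],
    engine: "_Engine | None" = None,
    provenance: str = "classifier",
) -> tuple[bool, IDState]:
    """Apply one seed and propagate to a fixpoint; roll back on contradiction.

    Returns ``(applied, states)`` where ``applied`` is False when the seed
    (or anything it implied) contradicted the current state and was undone.
    """
    v, i = seed_assignment
    if v not in states.possible:
        raise ValueError(f"seed references unknown node {v}")
    if i not in states.ids:
        raise ValueError(f"seed references unknown ID {i!r}")
    eng = engine or _Engine(graph, states)
    mark = len(eng.journal)
    try:
        eng.assign(v, i, provenance=provenance)
        eng.fixpoint()
        return True, states
    except Contradiction:
        eng.rollback(mark)
        return False, states


def solve(
    graph: TrackletGraph,
    classifications: Iterable[TrackletClassification],
    ids: Sequence[str],
    use_propagation: bool = True,
) -> Solution:
    """Seed in confidence order, propagate each, iterate to a global fixpoint.

    With ``use_propagation=False`` only the classifier seeds themselves are
    applied (the "without graph propagation" reference condition).
    """
    states = init_states(graph, ids)
    seeds = rank_seeds(classifications)
    sol = Solution(states=states)

    if not use_propagation:
        for v, i, _conf in seeds:
            states.assigned[v].add(i)
            states.provenance[(v, i)] = "classifier"
            sol.seeds_applied += 1
        return sol

    eng = _Engine(graph, states)
    for v, i, _conf in seeds:
        if i in states.assigned[v]:
            sol.seeds_applied += 1
            continue
        if i not in states.possible[v]:
            sol.contradicted.append((v, i))
            continue
        ok, _ = propagate(graph, states, (v, i), engine=eng)
        if ok:
            sol.seeds_applied += 1
        else:
            sol.contradicted.append((v, i))
    # final structural pass (covers the no-seed case too)
    mark = len(eng.journal)
    try:
        eng.fixpoint()
    except Contradiction:  # pragma: no cover - defensive; rules are sound
        eng.rollback(mark)
    sol.n_mutations = len(eng.journal)  # net mutations; monotone in the state
    states.check_invariants()
    return sol


# --------------------------------------------------------------------------
# Exhaustive oracle (closed-ROI, small graphs)
# --------------------------------------------------------------------------


class InconsistentFixture(ValueError):
    """No complete composition satisfies the constraints and seeds."""


def _enumerate_routes(graph: TrackletGraph) -> list[frozenset[int]]:
    """All full-duration chains: start-frame-0 node -> end-frame-T node."""
    last = graph.n_frames - 1
    routes: list[frozenset[int]] = []
    sources = [v for v in graph.node_ids if graph.tracklet(v).start_frame == 0]

    def extend(v: int, path: list[int]) -> None:
        if graph.tracklet(v).end_frame == last:
            routes.append(frozenset(path))
            return
        for s in graph.successors(v):
            extend(s, path + [s])

    for src in sources:
        extend(src, [src])
    return routes


def oracle_solve(
    graph: TrackletGraph,
    seeds: Sequence[tuple[int, str]],
    ids: Sequence[str],
    n_animals: int | None = None,
) -> set[tuple[int, str]]:
    """Forced assignments common to every complete consistent composition.

    Each ID traces one full route (a chain of edge-connected tracklets
    covering every frame), single-animal nodes carry exactly one ID,
    known-multi nodes at least two, and every node carries at least one.
    Only closed-ROI graphs are supported (every oracle fixture in the test
    suite is closed). Raises :class:`InconsistentFixture` when no complete
    composition exists.
    """
    if graph.open_boundary:
        raise NotImplementedError("oracle enumeration is defined for closed ROIs")
    ids = list(ids)
    if n_animals is None:
        n_animals = len(ids)
    routes = _enumerate_routes(graph)
    if not routes:
        raise InconsistentFixture("graph has no full-duration route")
    seed_map: dict[str, set[int]] = {}
    for v, i in seeds:
        seed_map.setdefault(i, set()).add(v)
    cands = {
        i: [r for r in routes if seed_map.get(i, set()) <= r] for i in ids
    }
    if any(not c for c in cands.values()):
        raise InconsistentFixture("a seeded ID has no admissible route")

    nodes = graph.node_ids
    cap_lo = {}
    cap_hi = {}
    for v in nodes:
        lo, hi = _CAP.get(graph.tracklet(v).kind, (1, None))
        cap_lo[v] = min(lo, len(ids))
        cap_hi[v] = len(ids) if hi is None else hi

    forced: set[tuple[int, str]] | None = None
    load = {v: 0 for v in nodes}

    def rec(k: int, chosen: list[frozenset[int]]) -> None:
        nonlocal forced
        if k == len(ids):
            if any(load[v] < cap_lo[v] for v in nodes):
                return
            comp = {(v, ids[j]) for j, r in enumerate(chosen) for v in r}
            forced = comp if forced is None else forced & comp
            return
        for r in cands[ids[k]]:
            if any(load[v] + 1 > cap_hi[v] for v in r):
                continue
            for v in r:
                load[v] += 1
            rec(k + 1, chosen + [r])
            for v in r:
                load[v] -= 1

    rec(0, [])
    if forced is None:
        raise InconsistentFixture("no consistent complete composition")
    return forced


# --------------------------------------------------------------------------
# Randomized composition graphs (fixture generator for soundness testing)
# --------------------------------------------------------------------------


def random_composition_graph(
    ids: Sequence[str],
    n_frames: int,
    rng: np.random.Generator,
    p_event: float = 0.35,
    max_nodes: int = 12,
) -> tuple[TrackletGraph, dict[int, frozenset[str]]]:
    """Generate a closed-ROI tracklet graph from a hidden true composition.

    IDs live in groups (tracklets); at random frames two groups merge or a
    group splits, closing the involved tracklets and opening new ones with
    the proper edges, exactly as the frame-by-frame tracker would. Returns
    the graph and the true composition of every node.
    """
    ids = list(ids)
    graph = TrackletGraph(n_frames=n_frames, open_boundary=False)
    truth: dict[int, frozenset[str]] = {}
    next_id = 0

    def open_node(start: int, members: frozenset[str]) -> int:
        nonlocal next_id
        tid = next_id
        next_id += 1
        kind = "single" if len(members) == 1 else "multi"
        graph.add_tracklet(Tracklet(tid, start_frame=start, end_frame=start, kind=kind))
        truth[tid] = members
        return tid

    # random initial partition
    k0 = int(rng.integers(1, len(ids) + 1))
    assign0 = rng.integers(0, k0, len(ids))
    groups: dict[int, frozenset[str]] = {}
    for g in range(k0):
        members = frozenset(ids[j] for j in range(len(ids)) if assign0[j] == g)
        if members:
            groups[open_node(0, members)] = members

    for t in range(1, n_frames - 1):
        if len(truth) + 2 > max_nodes or rng.random() >= p_event:
            continue
        mergeable = len(groups) >= 2
        splittable = [tid for tid, m in groups.items() if len(m) >= 2]
        do_merge = mergeable and (not splittable or rng.random() < 0.5)
        if do_merge:
            a, b = rng.choice(sorted(groups), size=2, replace=False)
            for tid in (a, b):
                graph.tracklet(tid).end_frame = t - 1
            merged = groups[a] | groups[b]
            new = open_node(t, merged)
            graph.add_edge(a, new)
            graph.add_edge(b, new)
            del groups[a], groups[b]
            groups[new] = merged
        elif splittable:
            tid = int(rng.choice(splittable))
            members = sorted(groups[tid])
            cut = int(rng.integers(1, len(members)))
            part = set(rng.choice(members, size=cut, replace=False))
            left = frozenset(part)
            right = frozenset(members) - left
            graph.tracklet(tid).end_frame = t - 1
            del groups[tid]
            for half in (left, right):
                new = open_node(t, half)
                graph.add_edge(tid, new)
                groups[new] = half

    for tid in groups:
        graph.tracklet(tid).end_frame = n_frames - 1
    graph.assert_valid()
    return graph, truth


def random_seeds(
    truth: dict[int, frozenset[str]],
    graph: TrackletGraph,
    rng: np.random.Generator,
    max_seeds: int = 4,
) -> list[TrackletClassification]:
    """Draw classifier seeds from the true compositions of single nodes."""
    singles = sorted(tid for tid, m in truth.items() if len(m) == 1)
    if not singles:
        return []
    k = int(rng.integers(1, min(max_seeds, len(singles)) + 1))
    chosen = rng.choice(singles, size=k, replace=False)
    out = []
    for tid in sorted(int(c) for c in chosen):
        (label,) = truth[tid]
        out.append(
            TrackletClassification(
                tracklet_id=tid,
                start_frame=graph.tracklet(tid).start_frame,
                kind="single",
                label=label,
                confidence=float(rng.uniform(0.5, 1.0)),
            )
        )
    return out
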