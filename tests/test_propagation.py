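"""ID propagation: rules, seeds, contradiction handling, oracle soundness."""

import numpy as np
import pytest

from tagtrax import (
    init_states,
    oracle_solve,
    propagate,
    random_composition_graph,
    random_seeds,
    rank_seeds,
    solve,
)
from tagtrax.classification import TrackletClassification
from tagtrax.propagation import InconsistentFixture
from tagtrax.tracklet_graph import Tracklet, TrackletGraph

from conftest import abstract_motif


def _cl(tid, label, conf, start=0, kind="single"):
    return TrackletClassification(tid, start, kind, label, conf)


def _chain(n=3, n_frames=9, kind="single"):
    g = TrackletGraph(n_frames=n_frames, open_boundary=False)
    step = n_frames // n
    for i in range(n):
        end = (i + 1) * step - 1 if i < n - 1 else n_frames - 1
        g.add_tracklet(Tracklet(i, i * step, end, kind=kind))
        if i:
            g.add_edge(i - 1, i)
    return g


class TestBasics:
    def test_init_states_all_possible_nothing_assigned(self):
        g = abstract_motif()
        st = init_states(g, ["r", "b", "g"])
        assert all(st.possible[v] == {"r", "b", "g"} for v in g.node_ids)
        assert all(not st.assigned[v] for v in g.node_ids)
        st.check_invariants()

    def test_init_empty_graph_and_empty_ids(self):
        g = TrackletGraph(n_frames=5)
        assert init_states(g, ["r"]).possible == {}
        with pytest.raises(ValueError):
            init_states(g, [])

    def test_rank_seeds_order_and_ties(self):
        cls = [_cl(0, "r", 0.9, start=5), _cl(1, "b", 0.5), _cl(2, "g", 0.99)]
        assert [t for t, _, _ in rank_seeds(cls)] == [2, 0, 1]
        tie = [_cl(0, "r", 0.7, start=9), _cl(1, "b", 0.7, start=2)]
        assert [t for t, _, _ in rank_seeds(tie)] == [1, 0]
        assert rank_seeds([]) == []
        # multi/unlabeled tracklets never seed
        assert rank_seeds([_cl(0, None, 0.9), _cl(1, "r", 0.9, kind="multi")]) == []

    def test_forced_chain(self):
        # two parallel single-animal chains so that both IDs have a home;
        # seeding red at the head of one chain forces it down that chain
        g = TrackletGraph(n_frames=9, open_boundary=False)
        for i in range(3):
            g.add_tracklet(Tracklet(i, 3 * i, 3 * i + 2, kind="single"))
            g.add_tracklet(Tracklet(i + 3, 3 * i, 3 * i + 2, kind="single"))
            if i:
                g.add_edge(i - 1, i)
                g.add_edge(i + 2, i + 3)
        st = init_states(g, ["red", "blue"])
        ok, st = propagate(g, st, (0, "red"))
        assert ok
        assert all("red" in st.assigned[v] for v in (0, 1, 2))
        assert all("red" not in st.possible[v] for v in (3, 4, 5))

    def test_seed_validation(self):
        g = _chain(2)
        st = init_states(g, ["red"])
        with pytest.raises(ValueError):
            propagate(g, st, (99, "red"))
        with pytest.raises(ValueError):
            propagate(g, st, (0, "mauve"))


class TestMotif:
    IDS = ["red", "blue"]

    def test_two_seeds_resolve_everything(self):
        g = abstract_motif()
        sol = solve(g, [_cl(0, "red", 0.9), _cl(3, "red", 0.8, start=20)], self.IDS)
        got = {(v, i) for v, i, _ in sol.assignments}
        assert got == {
            (0, "red"), (1, "blue"), (2, "red"), (2, "blue"), (3, "red"), (4, "blue"),
        }
        forced = oracle_solve(g, [(0, "red"), (3, "red")], self.IDS)
        assert got == forced

    def test_wrong_low_confidence_seed_is_contradicted(self):
        g = abstract_motif()
        cls = [
            _cl(0, "red", 0.9),
            _cl(3, "red", 0.8, start=20),
            _cl(4, "red", 0.5, start=20),  # classifier error, lowest confidence
        ]
        sol = solve(g, cls, self.IDS)
        assert (4, "red") in sol.contradicted
        got = {(v, i) for v, i, _ in sol.assignments}
        assert got == oracle_solve(g, [(0, "red"), (3, "red")], self.IDS)

    def test_consistent_three_seed_set_is_not_contradicted(self):
        # red: tau1 -> tau3 -> tau5, blue: tau2 -> tau3 -> tau4 is a valid
        # composition, so none of these seeds may be rejected
        g = abstract_motif()
        cls = [
            _cl(0, "red", 0.9),
            _cl(4, "red", 0.8, start=20),
            _cl(3, "blue", 0.5, start=20),
        ]
        sol = solve(g, cls, self.IDS)
        assert sol.contradicted == []
        got = {(v, i) for v, i, _ in sol.assignments}
        assert got == oracle_solve(g, [(0, "red"), (4, "red"), (3, "blue")], self.IDS)


class TestEightNodeFixture:
    """Three IDs, eight tracklets, two merge and two split events; three
    single-animal seeds fully resolve the composition of every node."""

    IDS = ["r", "b", "g"]

    @staticmethod
    def build():
        g = TrackletGraph(n_frames=20, open_boundary=False)
        spans = {
            0: (0, 4, "single"),   # a   (r)
            1: (0, 4, "single"),   # b   (b)
            2: (0, 9, "single"),   # c   (g)
            3: (5, 9, "multi"),    # M1  {r,b}
            4: (10, 14, "multi"),  # d   {r,g}
            5: (10, 19, "single"), # e   (b)
            6: (15, 19, "single"), # f   (g)
            7: (15, 19, "single"), # g2  (r)
        }
        for tid, (s, e, k) in spans.items():
            g.add_tracklet(Tracklet(tid, s, e, kind=k))
        for u, v in [(0, 3), (1, 3), (3, 4), (3, 5), (2, 4), (4, 6), (4, 7)]:
            g.add_edge(u, v)
        return g

    def test_three_seeds_fully_resolve(self):
        g = self.build()
        cls = [_cl(0, "r", 0.95), _cl(5, "b", 0.9, start=10), _cl(6, "g", 0.85, start=15)]
        sol = solve(g, cls, self.IDS)
        got = {(v, i) for v, i, _ in sol.assignments}
        expected = {
            (0, "r"), (1, "b"), (2, "g"), (3, "r"), (3, "b"),
            (4, "r"), (4, "g"), (5, "b"), (6, "g"), (7, "r"),
        }
        assert got == expected
        assert got == oracle_solve(g, [(0, "r"), (5, "b"), (6, "g")], self.IDS)
        # fully resolved: possible collapsed onto assigned everywhere
        assert all(
            sol.states.possible[v] == sol.states.assigned[v] for v in g.node_ids
        )


class TestOracle:
    def test_single_node_single_seed(self):
        g = TrackletGraph(n_frames=5)
        g.add_tracklet(Tracklet(0, 0, 4, kind="single"))
        assert oracle_solve(g, [(0, "r")], ["r"]) == {(0, "r")}

    def test_ambiguous_split_left_unresolved(self):
        g = abstract_motif()
        forced = oracle_solve(g, [(0, "red")], ["red", "blue"])
        # downstream of the merge nothing is forced for either ID
        assert not any(v in (3, 4) for v, _ in forced)
        assert (0, "red") in forced and (1, "blue") in forced

    def test_inconsistent_seeds_detected(self):
        g = _chain(2)
        with pytest.raises(InconsistentFixture):
            # two IDs seeded into the same single-animal chain
            oracle_solve(g, [(0, "r"), (0, "b")], ["r", "b"])


class TestRandomizedSoundness:
    def test_solver_is_sound_against_exhaustive_oracle(self):
        """On 200 random small graphs with truthful seeds, every assignment
        the greedy solver makes is forced in all consistent completions."""
        rng = np.random.default_rng(20240901)
        violations = 0
        n_assigned = 0
        for _ in range(200):
            ids = [f"id{j}" for j in range(int(rng.integers(2, 5)))]
            graph, truth = random_composition_graph(ids, int(rng.integers(8, 21)), rng)
            seeds = random_seeds(truth, graph, rng)
            sol = solve(graph, seeds, ids)
            forced = oracle_solve(
                graph, [(c.tracklet_id, c.label) for c in seeds], ids
            )
            for v, i, _prov in sol.assignments:
                n_assigned += 1
                violations += (v, i) not in forced
                assert i in truth[v], "assignment contradicts the hidden truth"
            # monotone state and termination bound
            assert sol.n_mutations <= 2 * len(graph) * len(ids)
            sol.states.check_invariants()
            # per-frame exclusivity
            for i in ids:
                nodes_i = [v for v in graph.node_ids if i in sol.states.assigned[v]]
                for a in range(len(nodes_i)):
                    for b in range(a + 1, len(nodes_i)):
                        ta, tb = graph.tracklet(nodes_i[a]), graph.tracklet(nodes_i[b])
                        assert not ta.overlaps(tb)
        assert violations == 0
        assert n_assigned > 200  # the check is not vacuous

    def test_corrupted_seed_rolls_back_cleanly(self):
        """A wrong seed may be contradicted and rolled back, after which the
        state must match a run without that seed."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(100):
            ids = [f"id{j}" for j in range(int(rng.integers(2, 4)))]
            graph, truth = random_composition_graph(ids, int(rng.integers(8, 16)), rng)
            seeds = random_seeds(truth, graph, rng)
            if not seeds:
                continue
            bad = seeds[-1]
            wrong = [i for i in ids if i != bad.label]
            bad.label = wrong[0]
            bad.confidence = 0.01  # strictly the lowest rank
            sol = solve(graph, seeds, ids)
            if (bad.tracklet_id, bad.label) in sol.contradicted:
                ref = solve(graph, seeds[:-1], ids)
                assert sol.states.assigned == ref.states.assigned
                assert sol.states.possible == ref.states.possible
                checked += 1
        assert checked > 5


class TestNoSeeds:
    def test_no_classifications_no_assignments(self):
        # a graph with at least two covering nodes at every frame and more
        # IDs than any capacity bound: without seeds nothing is deducible.
        # (On fixtures where a node is ever the sole cover, or where a
        # known-multi node's capacity meets the ID count, the closed-arena
        # rules correctly assign IDs even without seeds.)
        g = TestEightNodeFixture.build()
        ids = ["r", "b", "g", "y"]
        sol = solve(g, [], ids)
        assert sol.assignments == []
        assert all(sol.states.possible[v] == set(ids) for v in g.node_ids)

    def test_without_propagation_only_seeds_apply(self):
        g = abstract_motif()
        cls = [_cl(0, "red", 0.9), _cl(3, "red", 0.8, start=20)]
        sol = solve(g, cls, ["red", "blue"], use_propagation=False)
        assert {(v, i) for v, i, _ in sol.assignments} == {(0, "red"), (3, "red")}
        assert all(p == "classifier" for _, _, p in sol.assignments)
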