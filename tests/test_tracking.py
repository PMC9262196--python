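"""Graph tracking: linking, gap bridging, conjoint merging, pruning, metrics.

Includes an independent brute-force reference for the pass-1 assignment:
the greedy rule is characterised as the feasible matching whose sorted
pair-key sequence is lexicographically best, which a recursive enumerator
computes without sharing any code with the implementation.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from chronotrap.tracking import (DictScorer, TrackerConfig, Tuboid,
                                 bridge_gaps, build_graph, conjoint,
                                 evaluate_tracking, extract_tuboids,
                                 link_contiguous, mean_cross_score,
                                 merge_conjoint, track)
from conftest import StubInstance

H = 3600.0


def make_frames(counts, dt_s=1200.0, spread=50.0):
    """counts[i] = number of instances in frame i; centroids spread out."""
    frames = []
    for fi, c in enumerate(counts):
        frames.append([StubInstance(time=fi * dt_s, centroid=(k * spread, 0.0))
                       for k in range(c)])
    return frames


def scorer_from(frames, score_map, default=0.0):
    scores = {}
    for (fi, i, fj, j), s in score_map.items():
        scores[((fi, i), (fj, j))] = s
    return DictScorer(scores, default)


class TestLinkContiguous:
    def test_single_edge_above_threshold(self):
        frames = make_frames([1, 1])
        sc = scorer_from(frames, {(0, 0, 1, 0): 0.7})
        g = link_contiguous(frames, sc)
        assert g.has_edge((0, 0), (1, 0))

    def test_best_below_threshold_no_edge(self):
        frames = make_frames([1, 1])
        sc = scorer_from(frames, {(0, 0, 1, 0): 0.4})
        g = link_contiguous(frames, sc)
        assert g.number_of_edges() == 0

    def test_argmax_candidate_chosen(self):
        frames = make_frames([1, 2])
        sc = scorer_from(frames, {(0, 0, 1, 0): 0.6, (0, 0, 1, 1): 0.9})
        g = link_contiguous(frames, sc)
        assert list(g.out_edges((0, 0))) == [((0, 0), (1, 1))]

    def test_conflict_resolved_by_descending_score(self):
        # both m0 and m1 prefer n0; higher pair wins, loser takes its
        # remaining candidate
        frames = make_frames([2, 2])
        sc = scorer_from(frames, {(0, 0, 1, 0): 0.9, (0, 1, 1, 0): 0.8,
                                  (0, 1, 1, 1): 0.7})
        g = link_contiguous(frames, sc)
        assert g.has_edge((0, 0), (1, 0))
        assert g.has_edge((0, 1), (1, 1))

    def test_unsorted_frames_rejected(self):
        frames = make_frames([1, 1])
        frames[1][0].time = -5.0
        with pytest.raises(ValueError):
            link_contiguous(frames, scorer_from(frames, {}))

    def test_degree_invariants_hold(self):
        rng = np.random.default_rng(0)
        frames = make_frames([3, 3, 3, 3])
        scores = {}
        for fi in range(3):
            for i in range(3):
                for j in range(3):
                    scores[(fi, i, fi + 1, j)] = float(rng.uniform(0, 1))
        g = link_contiguous(frames, scorer_from(frames, scores))
        assert all(g.in_degree(v) <= 1 and g.out_degree(v) <= 1 for v in g)


# ---------------------------------------------------------------------------
# Brute-force oracle for the pass-1 rule
# ---------------------------------------------------------------------------

def brute_force_pass1(frames, scorer, k=0.5):
    """Reference pass-1 matching by exhaustive enumeration.

    For each frame transition, enumerate every degree-feasible subset of
    threshold-passing pairs; among them pick the matching whose pair keys
    (score desc, centroid distance asc, ids asc), listed best-first, are
    lexicographically best.  This is the declarative description of the
    greedy conflict rule.
    """
    edges = set()
    for fi in range(len(frames) - 1):
        cand = []
        for m in frames[fi]:
            for n in frames[fi + 1]:
                s = scorer(m, n)
                if s >= k:
                    d = float(np.hypot(m.centroid[0] - n.centroid[0],
                                       m.centroid[1] - n.centroid[1]))
                    cand.append(((-s, d, m.vid, n.vid), m.vid, n.vid))
        best_key, best_match = None, []
        for r in range(len(cand) + 1):
            for combo in itertools.combinations(cand, r):
                ms = [c[1] for c in combo]
                ns = [c[2] for c in combo]
                if len(set(ms)) != len(ms) or len(set(ns)) != len(ns):
                    continue
                key = sorted(c[0] for c in combo)
                # lexicographic comparison with "absent pair" ranked worst
                padded = key + [(np.inf,)] * (len(cand) - len(key))
                if best_key is None or padded < best_key:
                    best_key = padded
                    best_match = [(c[1], c[2]) for c in combo]
        edges.update(best_match)
    return edges


class TestPassOneOracle:
    def run_battery(self, n_cases, max_frames=4, max_per_frame=3, seed=0):
        rng = np.random.default_rng(seed)
        for case in range(n_cases):
            n_frames = int(rng.integers(2, max_frames + 1))
            counts = [int(rng.integers(0, max_per_frame + 1))
                      for _ in range(n_frames)]
            if sum(counts) == 0:
                counts[0] = 1
            frames = make_frames(counts, spread=float(rng.uniform(5, 60)))
            scores = {}
            grid = [0.0, 0.2, 0.4, 0.5, 0.6, 0.6, 0.8, 0.8, 1.0]  # dup ties
            for fi in range(n_frames - 1):
                for i in range(counts[fi]):
                    for j in range(counts[fi + 1]):
                        scores[(fi, i, fi + 1, j)] = float(rng.choice(grid))
            sc = scorer_from(frames, scores)
            g = link_contiguous(frames, sc)
            greedy_edges = set(g.edges())
            oracle_edges = brute_force_pass1(frames, sc)
            assert greedy_edges == oracle_edges, (
                f"case {case}: greedy {greedy_edges} != oracle {oracle_edges}")

    def test_random_battery_small(self):
        self.run_battery(120, max_frames=4, max_per_frame=3, seed=1)

    def test_battery_with_larger_transitions(self):
        self.run_battery(30, max_frames=3, max_per_frame=4, seed=2)


class TestBridgeGaps:
    def _linked(self, frames, scores):
        sc = scorer_from(frames, scores)
        g = link_contiguous(frames, sc)
        return g, sc

    def test_bridge_across_gap(self):
        # tuboid A: frames 0-1; tuboid B: frames 4-5; gap 3 frames, < 12 h
        frames = make_frames([1, 1, 0, 0, 1, 1])
        scores = {(0, 0, 1, 0): 0.9, (4, 0, 5, 0): 0.9}
        g, sc = self._linked(frames, scores)
        sc.scores[((1, 0), (4, 0))] = 0.8
        g = bridge_gaps(g, sc)
        assert g.has_edge((1, 0), (4, 0))

    def test_no_bridge_beyond_twelve_hours(self):
        frames = make_frames([1, 1, 0, 1, 1], dt_s=4.0 * H)  # gap = 8 h ok
        scores = {(0, 0, 1, 0): 0.9, (3, 0, 4, 0): 0.9}
        g, sc = self._linked(frames, scores)
        sc.scores[((1, 0), (3, 0))] = 0.9
        g13 = bridge_gaps(g.copy(), sc)
        assert g13.has_edge((1, 0), (3, 0))

        frames2 = make_frames([1, 1, 0, 1, 1], dt_s=6.5 * H)  # gap = 13 h
        g2, sc2 = self._linked(frames2, scores)
        sc2.scores[((1, 0), (3, 0))] = 0.9
        g2 = bridge_gaps(g2, sc2)
        assert not g2.has_edge((1, 0), (3, 0))

    def test_highest_pair_connected_first_then_restart(self):
        # one tail, two candidate heads at 0.7 and 0.9; after the 0.9 head
        # is taken by a competing tail, the 0.7 pairing is re-evaluated
        frames = make_frames([1, 1, 0, 1, 1])
        frames.append([StubInstance(time=5 * 1200.0, centroid=(200.0, 0))])
        scores = {(0, 0, 1, 0): 0.9}
        g, sc = self._linked(frames, scores)
        # tails: (1,0); heads: (3,0), (4,0) start tuboids of their own
        sc.scores[((1, 0), (3, 0))] = 0.9
        sc.scores[((1, 0), (4, 0))] = 0.7
        g = bridge_gaps(g, sc)
        assert g.has_edge((1, 0), (3, 0))
        assert not g.has_edge((1, 0), (4, 0))

    def test_contiguous_frames_not_bridged(self):
        frames = make_frames([1, 1])
        g, sc = self._linked(frames, {})
        sc.scores[((0, 0), (1, 0))] = 0.9
        g = bridge_gaps(g, sc)
        assert g.number_of_edges() == 0      # frame gap must exceed 1


class TestConjoint:
    def _tuboid(self, times, x=0.0, tid=0):
        return Tuboid(tid, [StubInstance(time=t, centroid=(x, 0.0), vid=(int(t), tid))
                            for t in times])

    def test_interleaved_no_common_times(self):
        p = self._tuboid([1, 3, 5])
        q = self._tuboid([2, 4, 6], tid=1)
        assert conjoint(p, q)

    def test_coincident_frame_not_conjoint(self):
        p = self._tuboid([1, 2, 3])
        q = self._tuboid([3, 4, 5], tid=1)
        assert not conjoint(p, q)

    def test_disjoint_intervals_not_conjoint(self):
        p = self._tuboid([1, 2])
        q = self._tuboid([5, 6], tid=1)
        assert not conjoint(p, q)


class TestMergeConjoint:
    def _graph_two_tuboids(self, times_p, times_q, cross_score):
        frames = []
        all_times = sorted(set(times_p) | set(times_q))
        for fi, t in enumerate(all_times):
            row = []
            if t in times_p:
                row.append(StubInstance(time=float(t), centroid=(0.0, 0.0)))
            if t in times_q:
                row.append(StubInstance(time=float(t), centroid=(5.0, 0.0)))
            frames.append(row)
        g = build_graph(frames)
        sc = DictScorer({}, default=cross_score)
        # chain each tuboid internally
        vid_p = [i.vid for row in frames for i in row if i.centroid[0] == 0.0]
        vid_q = [i.vid for row in frames for i in row if i.centroid[0] == 5.0]
        for a, b in zip(vid_p[:-1], vid_p[1:]):
            g.add_edge(a, b)
        for a, b in zip(vid_q[:-1], vid_q[1:]):
            g.add_edge(a, b)
        return g, sc

    def test_interleaved_tuboids_merge_at_threshold(self):
        g, sc = self._graph_two_tuboids([1, 3, 5], [2, 4, 6], 0.3)
        g = merge_conjoint(g, sc, TrackerConfig())
        assert nx.number_weakly_connected_components(g) == 1
        (t,) = extract_tuboids(g, TrackerConfig(min_vertices=4))
        assert len(t) == 6

    def test_below_threshold_not_merged(self):
        g, sc = self._graph_two_tuboids([1, 3, 5], [2, 4, 6], 0.2)
        g = merge_conjoint(g, sc, TrackerConfig())
        assert nx.number_weakly_connected_components(g) == 2

    def test_neighbour_pair_mean_hand_computed(self):
        # K for {1,3,5} x {2,4,6} = {1-2, 2-3, 3-4, 4-5, 5-6}: N = 5
        p = Tuboid(0, [StubInstance(time=t, centroid=(0, 0), vid=(t, 0))
                       for t in (1.0, 3.0, 5.0)])
        q = Tuboid(1, [StubInstance(time=t, centroid=(5, 0), vid=(t, 1))
                       for t in (2.0, 4.0, 6.0)])
        g = nx.DiGraph()
        for inst in p.instances + q.instances:
            g.add_node(inst.vid, inst=inst)
        calls = []

        class Counting:
            def __call__(self, a, b):
                calls.append((a.time, b.time))
                return 0.3

        assert mean_cross_score(p, q, Counting(), g) == pytest.approx(0.3)
        assert len(calls) == 5

    def test_highest_pair_merged_first_then_reevaluated(self):
        # three mutually conjoint chains; AB scores best and merges first,
        # then (AB) and C are re-examined as one pair
        frames = []
        times = {0: [1, 4, 7], 1: [2, 5, 8], 2: [3, 6, 9]}
        for t in range(1, 10):
            which = (t - 1) % 3
            frames.append([StubInstance(time=float(t),
                                        centroid=(which * 5.0, 0.0))])
        g = build_graph(frames)
        vids = {w: [((t - 1), 0) for t in times[w]] for w in times}
        for w, vs in vids.items():
            for a, b in zip(vs[:-1], vs[1:]):
                g.add_edge(a, b)

        class PairwiseScorer:
            def __call__(self, a, b):
                xs = {a.centroid[0], b.centroid[0]}
                if xs == {0.0, 5.0}:
                    return 0.9          # A-B
                if xs == {5.0, 10.0}:
                    return 0.3          # B-C
                return 0.3              # A-C
        g = merge_conjoint(g, PairwiseScorer(), TrackerConfig())
        assert nx.number_weakly_connected_components(g) == 1

    def test_merged_graph_keeps_degree_invariants(self):
        g, sc = self._graph_two_tuboids([1, 3, 5, 7], [2, 4, 6], 0.5)
        g = merge_conjoint(g, sc, TrackerConfig())
        assert all(g.in_degree(v) <= 1 and g.out_degree(v) <= 1 for v in g)


class TestExtractTuboids:
    def _graph_chain(self, n, t0=0.0):
        frames = make_frames([1] * n)
        g = build_graph(frames)
        vids = [(i, 0) for i in range(n)]
        for a, b in zip(vids[:-1], vids[1:]):
            g.add_edge(a, b)
        return g

    def test_three_vertex_component_dropped(self):
        assert extract_tuboids(self._graph_chain(3)) == []

    def test_four_vertex_component_kept(self):
        (t,) = extract_tuboids(self._graph_chain(4))
        assert len(t) == 4

    def test_empty_graph(self):
        assert extract_tuboids(nx.DiGraph()) == []

    def test_stable_ordering_by_start_time(self):
        frames = make_frames([2] * 4)
        g = build_graph(frames)
        for k in (0, 1):
            for fi in range(3):
                g.add_edge((fi, k), (fi + 1, k))
        tubs = extract_tuboids(g)
        assert [t.tuboid_id for t in tubs] == [0, 1]
        assert tubs[0].instances[0].vid <= tubs[1].instances[0].vid


class TestEvaluateTracking:
    def _tuboid(self, tid, labels, t0=0.0):
        return Tuboid(tid, [StubInstance(time=t0 + k, truth_id=lab,
                                         vid=(int(t0 + k), tid))
                            for k, lab in enumerate(labels)])

    def test_perfect_tracking(self):
        tubs = [self._tuboid(0, [1] * 5), self._tuboid(1, [2] * 4, t0=100)]
        ev = evaluate_tracking(tubs)
        assert ev.purity == 1.0 and ev.completeness == 1.0
        assert ev.id_switches == 0 and ev.n_splits == 0 and ev.n_merges == 0

    def test_split_track_halves_completeness(self):
        tubs = [self._tuboid(0, [1] * 4), self._tuboid(1, [1] * 4, t0=100)]
        ev = evaluate_tracking(tubs)
        assert ev.completeness == pytest.approx(0.5)
        assert ev.n_splits == 1

    def test_fused_tracks_reduce_purity(self):
        tubs = [self._tuboid(0, [1, 1, 2, 2, 2])]
        ev = evaluate_tracking(tubs)
        assert ev.purity == pytest.approx(3 / 5)
        assert ev.n_merges == 1
        assert ev.id_switches == 1


class TestEndToEndTrackingPasses:
    def test_occlusion_gap_bridged_into_single_tuboid(self):
        # insect visible frames 0-2, occluded 3-4, visible 5-7
        frames = make_frames([1, 1, 1, 0, 0, 1, 1, 1])
        scores = {}
        for fi in (0, 1, 5, 6):
            scores[(fi, 0, fi + 1, 0)] = 0.9
        sc = scorer_from(frames, scores)
        sc.scores[((2, 0), (5, 0))] = 0.8
        tubs, g = track(frames, sc)
        assert len(tubs) == 1
        assert len(tubs[0]) == 6

    def test_pass2_and_pass3_never_link_coincident_times(self):
        frames = make_frames([2, 2, 2, 2, 2])
        sc = DictScorer({}, default=0.9)
        tubs, g = track(frames, sc)
        for a, b in g.edges():
            assert g.nodes[a]["inst"].time < g.nodes[b]["inst"].time

    def test_deterministic_partition(self):
        rng = np.random.default_rng(5)
        frames = make_frames([3, 3, 3, 3, 3, 3])
        scores = {}
        for fi in range(5):
            for i in range(3):
                for j in range(3):
                    scores[(fi, i, fi + 1, j)] = float(rng.choice(
                        [0.1, 0.55, 0.6, 0.9]))
        t1, _ = track(frames, scorer_from(frames, scores))
        frames2 = make_frames([3, 3, 3, 3, 3, 3])
        t2, _ = track(frames2, scorer_from(frames2, scores))
        assert [[i.vid for i in t.instances] for t in t1] == \
               [[i.vid for i in t.instances] for t in t2]
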