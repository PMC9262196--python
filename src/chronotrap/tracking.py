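"""Three-pass graph tracking of detections into tuboids.

Detections become vertices of a directed graph (edges point forward in
time); every vertex has in- and out-degree at most one, so each weakly
connected component is a chain — a *tuboid*, the multi-frame record of one
trapped insect.  The graph is built in three passes:

1. **Contiguous linking** — between consecutive frames, an instance is
   connected to its highest-scoring candidate in the next frame provided
   the score reaches ``k_link`` (default 0.5).  The argmax rule alone can
   send two earlier instances to the same later one; conflicts are
   resolved by processing all candidate pairs of a frame transition in
   descending score, accepting a pair only when both endpoints are still
   free (ties broken by smaller centroid distance, then smaller vertex id).
2. **Gap bridging** — tuboid tails (out-degree 0) are matched to tuboid
   heads (in-degree 0) across gaps of more than one frame but less than
   ``max_gap`` (default 12 h), repeatedly taking the single
   highest-scoring admissible pair at or above ``k_link`` and restarting,
   until none remain.  This reconnects insects that were temporarily
   occluded or undetected.
3. **Conjoint merging** — two tuboids are *conjoint* iff they overlap in
   time but share no coincident frame (interleaved detections of the same
   insect).  Their mean cross score is averaged over each vertex paired
   with its immediately preceding and succeeding vertex from the other
   tuboid; conjoint pairs with mean score at or above ``k_merge`` (default
   0.25) are merged highest-first, to a fixpoint.

Finally components with fewer than ``min_vertices`` (default 4) vertices
are dropped — short chains are overwhelmingly segmentation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from chronotrap.matching import assemble_features, match_score

__all__ = [
    "TrackerConfig",
    "Tuboid",
    "PairScorer",
    "build_graph",
    "link_contiguous",
    "bridge_gaps",
    "conjoint",
    "merge_conjoint",
    "extract_tuboids",
    "track",
    "evaluate_tracking",
    "TrackingEval",
]


@dataclass(frozen=True)
class TrackerConfig:
    k_link: float = 0.5
    k_merge: float = 0.25
    max_gap_h: float = 12.0
    min_vertices: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.k_merge <= self.k_link < 1.0):
            raise ValueError("thresholds must satisfy 0 < k_merge <= k_link < 1")
        if self.max_gap_h <= 0:
            raise ValueError("max_gap must be positive")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class PairScorer:
    """Matching-score provider for the tracker.

    Wraps the frames, descriptor backend and decision head; candidate
    pairs farther apart than ``gate_px`` (centroid distance) are scored 0
    without computing appearance features — trapped insects move by a few
    pixels, so a loose gate only removes hopeless pairs.  Scores are
    cached by instance-id pair.
    """

    def __init__(self, frames, head, backend, gate_px: float = 150.0):
        self.frames = frames                  # list of images, frame-indexed
        self.head = head
        self.backend = backend
        self.gate_px = gate_px
        self._cache: dict = {}

    def __call__(self, m, n) -> float:
        key = (id(m), id(n))
        if key in self._cache:
            return self._cache[key]
        cm, cn = m.centroid, n.centroid
        if np.hypot(cm[0] - cn[0], cm[1] - cn[1]) > self.gate_px:
            score = 0.0
        else:
            fi = getattr(m, "frame_index", m.frame_id)
            fj = getattr(n, "frame_index", n.frame_id)
            f = assemble_features(m, n, self.frames[fi], self.frames[fj],
                                  self.backend)
            score = match_score(f, self.head)
        self._cache[key] = score
        return score


class DictScorer:
    """Test/fixture scorer: looks up M from a dict keyed by (m_id, n_id)."""

    def __init__(self, scores: dict, default: float = 0.0):
        self.scores = scores
        self.default = default

    def __call__(self, m, n) -> float:
        return self.scores.get((m.vid, n.vid), self.default)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _vid(inst) -> tuple:
    v = getattr(inst, "vid", None)
    return v if v is not None else (inst.frame_id, id(inst))


def build_graph(frames_instances) -> nx.DiGraph:
    """Empty tracking graph over time-ordered per-frame detection lists.

    Assigns each instance a vertex id ``(frame_index, index_in_frame)``
    (stored as ``inst.vid``) and checks the frames are time-sorted.
    """
    g = nx.DiGraph()
    last_t = -np.inf
    for fi, dets in enumerate(frames_instances):
        if dets:
            t = dets[0].time
            if t < last_t:
                raise ValueError("frames must be sorted by time")
            last_t = t
        for k, inst in enumerate(dets):
            inst.vid = (fi, k)
            inst.frame_index = fi
            g.add_node(inst.vid, inst=inst)
    return g


def _degree_ok(g: nx.DiGraph) -> bool:
    return all(g.in_degree(v) <= 1 and g.out_degree(v) <= 1 for v in g)


def link_contiguous(frames_instances, scorer, cfg: TrackerConfig | None = None,
                    graph: nx.DiGraph | None = None) -> nx.DiGraph:
    """Pass 1: link instances between consecutive frames (greedy argmax)."""
    cfg = cfg or TrackerConfig()
    g = graph if graph is not None else build_graph(frames_instances)
    for fi in range(len(frames_instances) - 1):
        cur, nxt = frames_instances[fi], frames_instances[fi + 1]
        pairs = []
        for m in cur:
            for n in nxt:
                s = scorer(m, n)
                if s >= cfg.k_link:
                    cm, cn = m.centroid, n.centroid
                    d = float(np.hypot(cm[0] - cn[0], cm[1] - cn[1]))
                    pairs.append((s, d, m.vid, n.vid))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
        used_m, used_n = set(), set()
        for s, _, mv, nv in pairs:
            if mv in used_m or nv in used_n:
                continue
            g.add_edge(mv, nv, score=s)
            used_m.add(mv)
            used_n.add(nv)
    assert _degree_ok(g)
    return g


def bridge_gaps(g: nx.DiGraph, scorer, cfg: TrackerConfig | None = None) -> nx.DiGraph:
    """Pass 2: recursively connect tuboid tails to later tuboid heads.

    Admissible pairs have frame gap > 1, time gap in (0, max_gap), tail
    out-degree 0 and head in-degree 0; the single best pair (score >=
    k_link) is connected, then admissibility is recomputed.
    """
    cfg = cfg or TrackerConfig()
    max_gap_s = cfg.max_gap_h * 3600.0
    while True:
        tails = [v for v in g if g.out_degree(v) == 0]
        heads = [v for v in g if g.in_degree(v) == 0]
        best = None
        for tv in tails:
            m = g.nodes[tv]["inst"]
            for hv in heads:
                n = g.nodes[hv]["inst"]
                if n.frame_index - m.frame_index <= 1:
                    continue
                dt = n.time - m.time
                if dt <= 0 or dt >= max_gap_s:
                    continue
                s = scorer(m, n)
                if s < cfg.k_link:
                    continue
                cm, cn = m.centroid, n.centroid
                d = float(np.hypot(cm[0] - cn[0], cm[1] - cn[1]))
                cand = (-s, d, tv, hv)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, tv, hv = best
        g.add_edge(tv, hv, score=-best[0], bridged=True)
    assert _degree_ok(g)
    return g


# ---------------------------------------------------------------------------
# Tuboids and conjoint merging
# ---------------------------------------------------------------------------

@dataclass
class Tuboid:
    """Time-ordered chain of detections for one tracked insect."""

    tuboid_id: int
    instances: list

    def __post_init__(self) -> None:
        self.instances = sorted(self.instances, key=lambda i: i.time)
        times = [i.time for i in self.instances]
        if len(set(times)) != len(times):
            raise ValueError("tuboid has coincident frame times")

    @property
    def start_time(self) -> float:
        return self.instances[0].time

    @property
    def end_time(self) -> float:
        return self.instances[-1].time

    @property
    def times(self) -> list:
        return [i.time for i in self.instances]

    def __len__(self) -> int:
        return len(self.instances)


def conjoint(p: Tuboid, q: Tuboid) -> bool:
    """True iff p and q overlap in time but share no coincident frame."""
    tp, tq = set(p.times), set(q.times)
    if not tp or not tq:
        raise ValueError("conjoint requires non-empty tuboids")
    if tp & tq:
        return False
    return (p.start_time <= q.start_time <= p.end_time or
            q.start_time <= p.start_time <= q.end_time)


def _neighbour_pairs(p: Tuboid, q: Tuboid):
    """K: each vertex with its immediate predecessor/successor in the other tuboid."""
    pairs = set()
    for a, b in ((p, q), (q, p)):
        bt = np.array(b.times)
        for v in a.instances:
            before = bt[bt < v.time]
            after = bt[bt > v.time]
            if before.size:
                w = b.instances[int(np.argmax(bt == before.max()))]
                pairs.add((min(v.vid, w.vid), max(v.vid, w.vid)))
            if after.size:
                w = b.instances[int(np.argmax(bt == after.min()))]
                pairs.add((min(v.vid, w.vid), max(v.vid, w.vid)))
    return pairs


def mean_cross_score(p: Tuboid, q: Tuboid, scorer, g: nx.DiGraph) -> float:
    """Mean matching score over the neighbouring pairs of two tuboids."""
    pairs = _neighbour_pairs(p, q)
    vals = []
    for va, vb in pairs:
        a, b = g.nodes[va]["inst"], g.nodes[vb]["inst"]
        if b.time < a.time:
            a, b = b, a
        vals.append(scorer(a, b))
    return float(np.mean(vals)) if vals else 0.0


def _components_as_tuboids(g: nx.DiGraph):
    comps = []
    for comp in nx.weakly_connected_components(g):
        insts = [g.nodes[v]["inst"] for v in comp]
        comps.append(Tuboid(-1, insts))
    comps.sort(key=lambda t: (t.start_time, t.instances[0].vid))
    for i, t in enumerate(comps):
        t.tuboid_id = i
    return comps


def merge_conjoint(g: nx.DiGraph, scorer, cfg: TrackerConfig | None = None) -> nx.DiGraph:
    """Pass 3: iteratively merge conjoint tuboids with mean score >= k_merge.

    The highest-scoring conjoint pair is merged first (its vertices
    re-chained in time order), then all pairs are recomputed, until no
    pair reaches the threshold (fixpoint).
    """
    cfg = cfg or TrackerConfig()
    while True:
        tuboids = _components_as_tuboids(g)
        best = None
        for i in range(len(tuboids)):
            for j in range(i + 1, len(tuboids)):
                p, q = tuboids[i], tuboids[j]
                if not conjoint(p, q):
                    continue
                mbar = mean_cross_score(p, q, scorer, g)
                if mbar < cfg.k_merge:
                    continue
                cand = (-mbar, p.instances[0].vid, q.instances[0].vid, i, j)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, _, i, j = best
        merged = sorted(tuboids[i].instances + tuboids[j].instances,
                        key=lambda inst: inst.time)
        vids = [inst.vid for inst in merged]
        # re-chain: drop old intra-component edges, add time-ordered chain
        for comp in (tuboids[i], tuboids[j]):
            cv = [inst.vid for inst in comp.instances]
            g.remove_edges_from([(a, b) for a, b in g.edges(cv)])
        for a, b in zip(vids[:-1], vids[1:]):
            g.add_edge(a, b, merged=True)
    assert _degree_ok(g)
    return g


def extract_tuboids(g: nx.DiGraph, cfg: TrackerConfig | None = None):
    """Weakly connected components as tuboids, dropping those with < 4 vertices.

    Stable ordering by first timestamp, then vertex id.
    """
    cfg = cfg or TrackerConfig()
    return [t for t in _components_as_tuboids(g) if len(t) >= cfg.min_vertices]


def track(frames_instances, scorer, cfg: TrackerConfig | None = None):
    """All three passes plus pruning; returns (tuboids, graph)."""
    cfg = cfg or TrackerConfig()
    g = link_contiguous(frames_instances, scorer, cfg)
    g = bridge_gaps(g, scorer, cfg)
    g = merge_conjoint(g, scorer, cfg)
    return extract_tuboids(g, cfg), g


# ---------------------------------------------------------------------------
# Evaluation against synthetic ground truth
# ---------------------------------------------------------------------------

@dataclass
class TrackingEval:
    purity: float           # instance-weighted majority-truth fraction
    completeness: float     # instance-weighted largest-tuboid fraction
    id_switches: int
    n_splits: int
    n_merges: int
    per_tuboid_purity: dict
    per_truth_completeness: dict


def evaluate_tracking(tuboids, truth_of=None) -> TrackingEval:
    """Identity-preservation metrics on detections carrying truth ids.

    ``truth_of`` maps an instance to its ground-truth track id (defaults
    to the instance's ``truth_id`` attribute).  Purity is the fraction of
    each tuboid's instances belonging to its majority truth track;
    completeness is, per truth track, the fraction of its detected
    instances captured by its single largest tuboid.  Both are aggregated
    weighted by instance counts.
    """
    truth_of = truth_of or (lambda inst: inst.truth_id)
    from collections import Counter, defaultdict

    truth_counts = defaultdict(Counter)   # truth -> Counter(tuboid)
    majority_sum, total = 0, 0
    per_tub = {}
    switches = 0
    for t in tuboids:
        labels = [truth_of(i) for i in t.instances]
        c = Counter(labels)
        top = c.most_common(1)[0][1]
        per_tub[t.tuboid_id] = top / len(labels)
        majority_sum += top
        total += len(labels)
        switches += sum(1 for a, b in zip(labels[:-1], labels[1:]) if a != b)
        for lab, cnt in c.items():
            truth_counts[lab][t.tuboid_id] += cnt
    per_truth = {}
    largest_sum, truth_total = 0, 0
    n_splits = 0
    for lab, c in truth_counts.items():
        n = sum(c.values())
        big = c.most_common(1)[0][1]
        per_truth[lab] = big / n
        largest_sum += big
        truth_total += n
        n_splits += len(c) - 1
    n_merges = sum(1 for t in tuboids
                   if len(set(truth_of(i) for i in t.instances)) > 1)
    return TrackingEval(
        purity=majority_sum / total if total else 1.0,
        completeness=largest_sum / truth_total if truth_total else 1.0,
        id_switches=switches, n_splits=n_splits, n_merges=n_merges,
        per_tuboid_purity=per_tub, per_truth_completeness=per_truth)
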