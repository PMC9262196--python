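"""End-to-end pipeline on synthetic or on-disk trap series.

Glues the stages together — simulate (optional) → detect → match/track →
classify → chronoecology — with per-stage artifacts and a manifest
recording the config hash, seeds and package version.  The synthetic
path is fully self-contained and is what the test-suite and the
reproduction script exercise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from chronotrap import __version__
from chronotrap.chrono import WztParams, wzt_hours
from chronotrap.classify import (ClassifierHead, LabelScheme, RadialHuEmbedder,
                                 classify, fuse, sample_frames)
from chronotrap.detection import BlobSegmenter, detect_frame
from chronotrap.io import Manifest, write_detections_json, write_truth_json, \
    write_tuboids_json
from chronotrap.matching import LogisticMatchHead, MatchHead, NccDescriptor, \
    assemble_features
from chronotrap.synthetic import (BehaviourConfig, DielShape, SceneConfig,
                                  TaxonSpec, render_series,
                                  simulate_capture_times)
from chronotrap.tracking import PairScorer, TrackerConfig, evaluate_tracking, track

logger = logging.getLogger(__name__)

__all__ = [
    "default_taxa",
    "default_wzt",
    "SyntheticSeries",
    "simulate_series",
    "detect_series",
    "assign_truth",
    "harvest_pairs",
    "train_matcher_on_series",
    "classify_tuboids",
    "run_synthetic_experiment",
    "run_pipeline",
]


def default_wzt() -> WztParams:
    """Equinox-like reference day: sunrise 06:00 UTC, 12 h day."""
    return WztParams(sunrise_frac=0.25, day_frac=0.5)


def default_taxa():
    """A small synthetic community spanning the classic diel niches.

    One diurnal taxon (peak at solar noon, WZT 6), one nocturnal (solar
    midnight, WZT 18) and one crepuscular (dawn + dusk, WZT 0 and 12);
    marginal rates of ~0.1 captures/hour per taxon give a realistic few
    dozen insects per trap-week.  Sizes and gray levels differ so the
    desk-scale classifier has something to separate.
    """
    return [
        TaxonSpec("diurnalis", 0.12,
                  DielShape(peaks=((6.0, 1.8, 6.0),), floor=0.15),
                  size_px=(58.0, 5.0), intensity=45),
        TaxonSpec("nocturna", 0.12,
                  DielShape(peaks=((18.0, 1.8, 6.0),), floor=0.15),
                  size_px=(92.0, 7.0), intensity=115),
        TaxonSpec("crepuscula", 0.10,
                  DielShape(peaks=((0.0, 1.2, 4.0), (12.0, 1.2, 4.0)), floor=0.1),
                  size_px=(42.0, 4.0), intensity=75),
    ]


@dataclass
class SyntheticSeries:
    device: str
    events: list
    frame_times: np.ndarray
    frames: list
    tracks: list
    wzt: WztParams
    frame_interval_min: float


def simulate_series(duration_h: float = 168.0, seed: int = 0,
                    taxa=None, device: str = "trap01",
                    start: float = 1_600_000_000.0 // 86400 * 86400,
                    frame_interval_min: float = 20.0,
                    scene: SceneConfig | None = None,
                    behaviour: BehaviourConfig | None = None,
                    wzt: WztParams | None = None) -> SyntheticSeries:
    """Simulate capture events and render the image series with truth."""
    taxa = taxa or default_taxa()
    wzt = wzt or default_wzt()
    events = simulate_capture_times(taxa, start, duration_h, wzt, seed=seed)
    frame_times, frames, tracks = render_series(
        events, start, duration_h, taxa, frame_interval_min,
        scene=scene or SceneConfig(), behaviour=behaviour or BehaviourConfig(
            escape_per_frame=0.001),
        seed=seed + 1)
    return SyntheticSeries(device, events, frame_times, frames, tracks, wzt,
                           frame_interval_min)


def detect_series(frames, frame_times, segmenter=None, layout=None):
    """Run frame-level detection over a series; frame_id = frame index."""
    segmenter = segmenter or BlobSegmenter()
    out = []
    for fi, (img, t) in enumerate(zip(frames, frame_times)):
        out.append(detect_frame(img, segmenter, layout, frame_id=fi,
                                time=float(t)))
    return out


def assign_truth(frames_instances, tracks, tol_px: float = 10.0) -> None:
    """Attach ground-truth track ids to detections by centroid proximity."""
    by_frame: dict = {}
    for tr in tracks:
        for f in tr.frames:
            if f.visible:
                by_frame.setdefault(f.frame_idx, []).append((tr.track_id, f.centroid))
    for fi, dets in enumerate(frames_instances):
        cands = by_frame.get(fi, [])
        for inst in dets:
            cx, cy = inst.centroid
            best, best_d = None, tol_px
            for tid, (tx, ty) in cands:
                d = float(np.hypot(cx - tx, cy - ty))
                if d < best_d:
                    best, best_d = tid, d
            inst.truth_id = best


def harvest_pairs(frames_instances, frames, backend, seed: int = 0,
                  max_gap_frames: int = 12, gate_px: float = 150.0,
                  max_pairs: int = 4000):
    """Labelled match-feature pairs from truth-annotated detections.

    Positives pair the same ground-truth insect across 1..``max_gap_frames``
    frames (covering both contiguous links and occlusion bridges);
    negatives pair distinct insects within the distance gate.  Returns
    (X, y) with X the (n, 5) feature matrix.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    n_frames = len(frames_instances)
    for fi in range(n_frames - 1):
        for gap in (1, int(rng.integers(2, max_gap_frames + 1))):
            fj = fi + gap
            if fj >= n_frames:
                continue
            for m in frames_instances[fi]:
                for n in frames_instances[fj]:
                    if m.truth_id is None and n.truth_id is None:
                        continue
                    cm, cn = m.centroid, n.centroid
                    if np.hypot(cm[0] - cn[0], cm[1] - cn[1]) > gate_px:
                        continue
                    label = int(m.truth_id is not None and m.truth_id == n.truth_id)
                    # keep all positives, subsample abundant negatives
                    if label == 0 and rng.uniform() > 0.5:
                        continue
                    f = assemble_features(m, n, frames[fi], frames[fj], backend)
                    X.append(f.as_array())
                    y.append(label)
                    if len(y) >= max_pairs:
                        return np.asarray(X), np.asarray(y)
    return np.asarray(X), np.asarray(y)


def train_matcher_on_series(series: SyntheticSeries | None = None, seed: int = 0,
                            head_kind: str = "logistic", backend=None,
                            frames_instances=None):
    """Train a matching head on a (short) truth-annotated synthetic series."""
    backend = backend or NccDescriptor()
    if series is None:
        taxa = [TaxonSpec(t.name, t.base_rate * 4, t.diel, t.size_px, t.intensity)
                for t in default_taxa()]
        series = simulate_series(duration_h=30.0, seed=seed + 100, taxa=taxa)
    if frames_instances is None:
        frames_instances = detect_series(series.frames, series.frame_times)
        assign_truth(frames_instances, series.tracks)
    X, y = harvest_pairs(frames_instances, series.frames, backend, seed=seed)
    head = LogisticMatchHead() if head_kind == "logistic" else MatchHead(seed=seed)
    head.fit(X, y, seed=seed)
    return head, backend, (X, y)


def label_tuboids_from_truth(tuboids, tracks) -> list:
    """Majority ground-truth taxon per tuboid ('Background objects' if none)."""
    from collections import Counter

    taxon_of = {tr.track_id: tr.taxon for tr in tracks}
    labels = []
    for t in tuboids:
        c = Counter(taxon_of.get(i.truth_id, "Background objects")
                    for i in t.instances)
        labels.append(c.most_common(1)[0][0])
    return labels


def classify_tuboids(tuboids, head: ClassifierHead, embedder=None,
                     seed: int = 0):
    """Predict a label per tuboid via 6-frame median fusion."""
    import pandas as pd

    embedder = embedder or RadialHuEmbedder()
    rows = []
    for k, t in enumerate(tuboids):
        chosen = sample_frames(t, seed=seed + k)
        scale = max(i.max_side for i in t.instances)
        feat = fuse(chosen, embedder, scale)
        probs, label = classify(feat, head)
        rows.append({"tuboid_id": t.tuboid_id, "label": label,
                     "probability": probs[label],
                     "start_time": t.start_time, "n_frames": len(t)})
    return pd.DataFrame(rows)


def tuboid_features(tuboids, embedder=None, seed: int = 0):
    embedder = embedder or RadialHuEmbedder()
    feats = []
    for k, t in enumerate(tuboids):
        chosen = sample_frames(t, seed=seed + k)
        scale = max(i.max_side for i in t.instances)
        feats.append(fuse(chosen, embedder, scale))
    return feats


@dataclass
class ExperimentResult:
    series: SyntheticSeries
    frames_instances: list
    tuboids: list
    tracking_eval: "object"
    detection_eval: "object"
    predictions: "object"               # DataFrame
    classifier_eval: "object"
    classifier_accuracy: float
    events_wzt_by_taxon: dict


def run_synthetic_experiment(seed: int = 0, duration_h: float = 168.0,
                             taxa=None, train_seed_offset: int = 1000,
                             cfg: TrackerConfig | None = None) -> ExperimentResult:
    """One full desk-scale experiment: simulate a device-week and analyse it.

    The matcher head and the classifier head are trained on an
    *independent* synthetic series (different seed) so the evaluation
    series is held out.  Returns tracking/detection/classification
    diagnostics plus per-taxon WZT capture times for chronoecology.
    """
    from chronotrap.detection import evaluate_detection
    from chronotrap.classify import evaluate_classifier

    taxa = taxa or default_taxa()
    cfg = cfg or TrackerConfig()
    backend = NccDescriptor()

    # --- training series (held out from evaluation) -----------------------
    train_taxa = [TaxonSpec(t.name, t.base_rate * 4, t.diel, t.size_px, t.intensity)
                  for t in taxa]
    train_series = simulate_series(duration_h=30.0, seed=seed + train_seed_offset,
                                   taxa=train_taxa)
    train_dets = detect_series(train_series.frames, train_series.frame_times)
    assign_truth(train_dets, train_series.tracks)
    head, backend, _ = train_matcher_on_series(train_series, seed=seed,
                                               backend=backend,
                                               frames_instances=train_dets)
    train_scorer = PairScorer(train_series.frames, head, backend)
    train_tuboids, _ = track(train_dets, train_scorer, cfg)
    scheme = LabelScheme(tuple(sorted({t.name for t in taxa}
                                      | {"Background objects"})))
    clf_head = ClassifierHead(scheme, seed=seed)
    train_labels = label_tuboids_from_truth(train_tuboids, train_series.tracks)
    clf_head.fit(tuboid_features(train_tuboids, seed=seed), train_labels)

    # --- evaluation series -------------------------------------------------
    series = simulate_series(duration_h=duration_h, seed=seed, taxa=taxa)
    dets = detect_series(series.frames, series.frame_times)
    assign_truth(dets, series.tracks)

    # frame-level detection quality on a sample of frames
    from chronotrap.detection import DetectionInstance
    det_evals = []
    step = max(1, len(series.frames) // 40)
    for fi in range(0, len(series.frames), step):
        truth_insts = []
        for tr in series.tracks:
            m = tr.mask_at(fi, series.frames[fi].shape)
            if m is None or not m.any():
                continue
            ys, xs = np.nonzero(m)
            bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
            truth_insts.append(DetectionInstance(
                fi, float(series.frame_times[fi]), bbox,
                mask=m[bbox[1]:bbox[3], bbox[0]:bbox[2]]))
        det_evals.append(evaluate_detection(dets[fi], truth_insts))
    n_p = sum(e.n_predicted for e in det_evals)
    n_t = sum(e.n_truth for e in det_evals)
    n_m = sum(e.n_matched for e in det_evals)
    det_summary = {"precision": n_m / n_p if n_p else 1.0,
                   "recall": n_m / n_t if n_t else 1.0,
                   "n_frames_checked": len(det_evals)}

    scorer = PairScorer(series.frames, head, backend)
    tuboids, _ = track(dets, scorer, cfg)
    trk_eval = evaluate_tracking(
        tuboids, truth_of=lambda i: i.truth_id if i.truth_id is not None else -1)

    preds = classify_tuboids(tuboids, clf_head, seed=seed)
    truth_labels = label_tuboids_from_truth(tuboids, series.tracks)
    clf_eval = evaluate_classifier(list(preds["label"]), truth_labels, scheme)

    # chronoecology inputs: classified tuboid start times in WZT hours
    events_wzt: dict = {}
    for label, t0 in zip(preds["label"], preds["start_time"]):
        w = wzt_hours((t0 / 86400.0) % 1.0, series.wzt)
        events_wzt.setdefault(label, []).append(float(w))

    return ExperimentResult(series, dets, tuboids, trk_eval, det_summary,
                            preds, clf_eval, clf_eval.accuracy, events_wzt)


# ---------------------------------------------------------------------------
# File-based pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir, seed: int = 0) -> Path:
    """Run the synthetic pipeline end-to-end and persist per-stage artifacts.

    ``config`` keys (all optional): ``duration_h``, ``device``,
    ``frame_interval_min``, ``tracker`` (k_link, k_merge, max_gap_h,
    min_vertices).  Writes detections, tuboids, predictions, diel events
    and a manifest; returns the results directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config=config, seed=seed, version=__version__)
    cfg = TrackerConfig(**config.get("tracker", {}))

    res = run_synthetic_experiment(seed=seed,
                                   duration_h=float(config.get("duration_h", 168.0)),
                                   cfg=cfg)
    manifest.record("simulate", n_events=len(res.series.events),
                    n_frames=len(res.series.frames))
    write_truth_json(res.series.tracks, out / "truth.json")
    write_detections_json(res.frames_instances, out / "detections.json")
    manifest.record("detect",
                    n_instances=sum(len(f) for f in res.frames_instances),
                    **res.detection_eval)
    write_tuboids_json(res.tuboids, out / "tuboids.json")
    manifest.record("track", n_tuboids=len(res.tuboids),
                    purity=res.tracking_eval.purity,
                    completeness=res.tracking_eval.completeness)
    res.predictions.to_csv(out / "predictions.csv", index=False)
    manifest.record("classify", accuracy=res.classifier_accuracy,
                    n_tuboids=len(res.predictions))
    rows = [{"taxon": k, "wzt_h": v} for k, vs in res.events_wzt_by_taxon.items()
            for v in vs]
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "events_wzt.csv", index=False)
    manifest.record("chrono", n_events=len(rows))
    manifest.write(out / "manifest.json")
    return out
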