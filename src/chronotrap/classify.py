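"""Per-tuboid taxonomic classification by multi-frame feature fusion.

A tracked insect (tuboid) is classified from several of its frames rather
than one: the first frame plus five frames sampled at random from the
first day of data are embedded independently, the element-wise median of
the six vectors is taken (robust to transient occlusions or segmentation
glitches in single frames), the object's physical scale is appended, and
a flat label head produces a probability over the label scheme.

The per-frame embedder is a pluggable contract (crops are padded to
square and rescaled to 224x224 px first).  The shipped default is a
training-free radial-intensity + Hu-moment descriptor sufficient for
synthetic blobs; a deep backbone attaches through the same contract.
The default label scheme has 18 flat classes including "Background
objects" and "Undefined insects"; those two can be merged into one,
leaving 17 informative classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from chronotrap.units import PX_PER_MM, px_to_mm

__all__ = [
    "LabelScheme",
    "default_scheme",
    "FusedFeature",
    "RadialHuEmbedder",
    "prepare_crop",
    "sample_frames",
    "fuse",
    "ClassifierHead",
    "classify",
    "merge_labels",
    "evaluate_classifier",
    "ClassifierEval",
]

EMBEDDER_INPUT_PX = 224


# ---------------------------------------------------------------------------
# Label scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelScheme:
    """Ordered flat label list with optional merge rules."""

    labels: tuple
    merges: tuple = ()         # ((source, target), ...)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        for src, dst in self.merges:
            if src not in self.labels or dst not in self.labels + tuple(
                    d for _, d in self.merges):
                raise ValueError(f"merge rule {src}->{dst} references unknown label")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_json(self) -> str:
        return json.dumps({"labels": list(self.labels),
                           "merges": [list(m) for m in self.merges]})

    @classmethod
    def from_json(cls, text: str) -> "LabelScheme":
        d = json.loads(text)
        return cls(tuple(d["labels"]), tuple(tuple(m) for m in d.get("merges", [])))


def default_scheme() -> LabelScheme:
    """18 flat classes for berry-field sticky-trap communities."""
    labels = (
        "Background objects", "Undefined insects", "Macropsis fuscula",
        "Drosophila suzukii males", "Other Drosophilidae", "Typhlocybinae",
        "Figitidae", "Sciaridae", "Psychodidae", "Culicidae",
        "Anthonomus rubi", "Psyllobora vigintimaculata", "Coccinellidae",
        "Other Coleoptera", "Syrphidae", "Lasioglossum laevissimum",
        "Calyptratae", "Lepidoptera",
    )
    merges = (("Undefined insects", "Background objects"),)
    return LabelScheme(labels, merges)


# ---------------------------------------------------------------------------
# Frame sampling and fusion
# ---------------------------------------------------------------------------

def sample_frames(tuboid, horizon_h: float = 24.0, n_random: int = 5,
                  seed: int = 0):
    """Pick the classification frames of a tuboid: first + 5 random in day 1.

    The first frame is always included; the remaining ``n_random`` are
    drawn uniformly without replacement from the tuboid's other frames
    within ``horizon_h`` of its start.  Tuboids with fewer than
    ``n_random`` eligible frames fall back to sampling with replacement
    (tuboids are only guaranteed >= 4 vertices).  Reproducible under seed.
    """
    insts = getattr(tuboid, "instances", tuboid)
    if not len(insts):
        raise ValueError("empty tuboid")
    t0 = insts[0].time
    eligible = [i for i in insts[1:] if i.time - t0 <= horizon_h * 3600.0]
    rng = np.random.default_rng(seed)
    if not eligible:
        chosen = [insts[0]] * n_random
    elif len(eligible) < n_random:
        chosen = [eligible[k] for k in rng.integers(0, len(eligible), n_random)]
    else:
        idx = rng.choice(len(eligible), n_random, replace=False)
        chosen = [eligible[k] for k in sorted(idx)]
    return [insts[0]] + chosen


def prepare_crop(crop: np.ndarray, size: int = EMBEDDER_INPUT_PX) -> np.ndarray:
    """Pad a crop to square and rescale to the embedder input size."""
    from skimage.transform import resize

    img = crop.astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape
    side = max(h, w)
    pad_y, pad_x = side - h, side - w
    img = np.pad(img, ((pad_y // 2, pad_y - pad_y // 2),
                       (pad_x // 2, pad_x - pad_x // 2)))
    return resize(img, (size, size), anti_aliasing=True, preserve_range=True)


class RadialHuEmbedder:
    """Training-free per-frame embedder (embedder contract).

    Concatenates a radial mean-intensity profile (16 rings), a 16-bin
    intensity histogram and the 7 log-scaled Hu moment invariants —
    rotation-insensitive descriptors that separate blobs differing in
    size, darkness or shape.
    """

    n_rings = 16
    n_hist = 16
    embedding_dim = n_rings + n_hist + 7

    def embed(self, crop: np.ndarray) -> np.ndarray:
        from skimage.measure import moments_central, moments_hu, moments_normalized

        img = prepare_crop(crop)
        size = img.shape[0]
        yy, xx = np.mgrid[:size, :size]
        r = np.hypot(yy - size / 2, xx - size / 2)
        r_edges = np.linspace(0, size / 2, self.n_rings + 1)
        rings = np.empty(self.n_rings)
        for k in range(self.n_rings):
            m = (r >= r_edges[k]) & (r < r_edges[k + 1])
            rings[k] = img[m].mean() if m.any() else 0.0
        hist, _ = np.histogram(img, bins=self.n_hist, range=(0, 255))
        hist = hist / hist.sum() if hist.sum() else hist.astype(float)
        fg = img < img.mean() if img.std() > 0 else img > -1
        mu = moments_central(fg.astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            hu = moments_hu(moments_normalized(mu))
            hu = np.nan_to_num(-np.sign(hu) * np.log10(np.abs(hu) + 1e-30))
        return np.concatenate([rings / 255.0, hist, hu / 30.0])


@dataclass
class FusedFeature:
    """Per-frame embeddings, their element-wise median, and the object scale."""

    per_frame: np.ndarray        # (n_frames, dim)
    fused: np.ndarray            # (dim,)
    scale_mm: float

    @property
    def with_scale(self) -> np.ndarray:
        return np.concatenate([self.fused, [self.scale_mm]])


def fuse(instances, embedder, scale_px: float,
         px_per_mm: float = PX_PER_MM) -> FusedFeature:
    """Element-wise median of per-frame embeddings, scale appended after.

    The scale (max bbox side, converted to mm) is constant over a tuboid,
    so appending it once after the median is equivalent to augmenting each
    per-frame vector and simpler.
    """
    vecs = []
    for inst in instances:
        crop = inst.crop if getattr(inst, "crop", None) is not None else inst
        vecs.append(np.asarray(embedder.embed(crop), float))
    dims = {v.shape for v in vecs}
    if len(dims) != 1:
        raise ValueError(f"embedding dimension mismatch across frames: {dims}")
    per_frame = np.stack(vecs)
    fused = np.median(per_frame, axis=0)
    return FusedFeature(per_frame, fused, px_to_mmscale(scale_px, px_per_mm))


def px_to_mmscale(scale_px: float, px_per_mm: float = PX_PER_MM) -> float:
    return px_to_mm(float(scale_px), px_per_mm)


# ---------------------------------------------------------------------------
# Label head
# ---------------------------------------------------------------------------

class ClassifierHead:
    """Flat softmax label head over fused features (+ scale)."""

    def __init__(self, scheme: LabelScheme, seed: int = 0):
        self.scheme = scheme
        self.seed = seed
        self._clf = None
        self._classes: list = []

    def fit(self, features, labels):
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler
        from sklearn.pipeline import make_pipeline

        X = np.stack([f.with_scale if isinstance(f, FusedFeature) else np.asarray(f)
                      for f in features])
        for lab in labels:
            if lab not in self.scheme.labels:
                raise ValueError(f"label {lab!r} outside scheme")
        self._clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=self.seed))
        self._clf.fit(X, list(labels))
        self._classes = list(self._clf.classes_)
        return self

    def predict_proba(self, feature) -> dict:
        if self._clf is None:
            raise RuntimeError("classifier head not trained")
        x = feature.with_scale if isinstance(feature, FusedFeature) else np.asarray(feature)
        p = self._clf.predict_proba(x[None, :])[0]
        out = {lab: 0.0 for lab in self.scheme.labels}
        for lab, pi in zip(self._classes, p):
            out[lab] = float(pi)
        return out


def classify(feature: FusedFeature, head: ClassifierHead,
             scheme: LabelScheme | None = None, merge: bool = False):
    """Label distribution and argmax label for one fused feature.

    With ``merge=True`` the scheme's merge rules are applied (e.g.
    background + undefined pooled into one class) and the distribution is
    re-expressed over the merged labels; probabilities still sum to 1.
    """
    scheme = scheme or head.scheme
    probs = head.predict_proba(feature)
    if merge:
        probs = merge_labels(probs, scheme)
    label = max(probs, key=probs.get)
    return probs, label


def merge_labels(probs: dict, scheme: LabelScheme) -> dict:
    merged = dict(probs)
    for src, dst in scheme.merges:
        if src in merged:
            merged[dst] = merged.get(dst, 0.0) + merged.pop(src)
    return merged


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassifierEval:
    accuracy: float
    per_label: "object"              # DataFrame: precision, recall, f1, support
    confusion: "object"              # DataFrame: rows = truth, cols = predicted


def evaluate_classifier(predictions, truth, scheme: LabelScheme) -> ClassifierEval:
    """Per-label precision/recall/F1 and the confusion matrix.

    Rows of the confusion matrix are true labels, columns predictions.
    Raises on labels outside the scheme.
    """
    import pandas as pd
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

    for lab in list(predictions) + list(truth):
        if lab not in scheme.labels:
            raise ValueError(f"label {lab!r} outside scheme")
    labels = [l for l in scheme.labels if l in set(truth) | set(predictions)]
    cm = confusion_matrix(truth, predictions, labels=labels)
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predictions, labels=labels, zero_division=0)
    per_label = pd.DataFrame({"precision": prec, "recall": rec, "f1": f1,
                              "support": support}, index=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 1.0
    return ClassifierEval(acc, per_label, confusion)
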