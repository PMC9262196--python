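"""Siamese-style pairwise matching of insect detections across frames.

The matching score ``M(m, n) in [0, 1]`` between two detections combines
appearance similarity with explicit geometric/temporal statistics:

* ``S(m, n)`` — *naive similarity*: descriptor similarity between m's
  masked crop in its frame and n's masked crop in its frame;
* ``Q(m, n)`` — *delayed self-similarity*: similarity between m's masked
  crop and the same pixel region (same mask) in the later frame — high Q
  means the insect has in fact not moved;
* the centroid distance ``d(C(m), C(n))``, the absolute log area ratio
  ``|log(A_m / A_n)|``, and ``log(dt + 1)`` with dt in hours.

These five features feed a small fully connected decision head
(dimensions 5-4-3-1, ReLU after the first two layers, sigmoid output).
The appearance descriptor is a pluggable contract: crops are scaled to
105x105 px before embedding; the shipped default is a deterministic
normalised cross-correlation descriptor that needs no training.  Training
follows a three-phase schedule (pretrain the similarity branch; train the
head only; joint fine-tune) with the negative class resampled to 50% per
batch under binary cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from chronotrap.detection import DetectionInstance

__all__ = [
    "MatchFeatures",
    "NccDescriptor",
    "MatchHead",
    "LogisticMatchHead",
    "TrainingSchedule",
    "naive_similarity",
    "self_similarity",
    "assemble_features",
    "match_score",
    "fit_matcher",
    "save_model_bundle",
    "load_model_bundle",
]

DESCRIPTOR_INPUT_PX = 105


@dataclass(frozen=True)
class MatchFeatures:
    """The 5-element input to the matching head."""

    s: float
    q: float
    centroid_dist: float
    abs_log_area_ratio: float
    log_dt: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite match features: {v}")
        if self.centroid_dist < 0 or self.abs_log_area_ratio < 0 or self.log_dt < 0:
            raise ValueError(f"negative-definite feature: {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.q, self.centroid_dist,
                         self.abs_log_area_ratio, self.log_dt], float)


# ---------------------------------------------------------------------------
# Descriptor backend
# ---------------------------------------------------------------------------

def _to_input(crop: np.ndarray) -> np.ndarray:
    from skimage.transform import resize

    img = crop.astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    # masked crops carry exact zeros outside the instance mask; filling them
    # with the in-mask mean stops the silhouette from dominating the
    # correlation, so similarity reflects the visible texture
    m = img != 0
    if m.any() and not m.all():
        img = np.where(m, img, img[m].mean())
    return resize(img, (DESCRIPTOR_INPUT_PX, DESCRIPTOR_INPUT_PX),
                  anti_aliasing=True, preserve_range=True)


class NccDescriptor:
    """Deterministic appearance descriptor (descriptor-backend contract).

    Crops are converted to 105x105 grayscale; the embedding is the
    zero-mean, unit-norm downsampled image (default 32x32 = 1024 dims) and
    the similarity is normalised cross-correlation affinely rescaled from
    [-1, 1] to [0, 1].  Symmetric, D(x, x) = 1, and training-free.
    """

    embedding_dim = 1024

    def embed(self, crop: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        img = _to_input(crop)
        side = int(round(self.embedding_dim ** 0.5))
        small = resize(img, (side, side), anti_aliasing=True,
                       preserve_range=True).ravel()
        small = small - small.mean()
        nrm = np.linalg.norm(small)
        return small / nrm if nrm > 0 else small

    def similarity(self, crop_a: np.ndarray, crop_b: np.ndarray) -> float:
        a, b = _to_input(crop_a), _to_input(crop_b)
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 1.0 if np.allclose(crop_a.mean(), crop_b.mean()) else 0.5
        ncc = float((a * b).sum() / (na * nb))
        return (ncc + 1.0) / 2.0


# ---------------------------------------------------------------------------
# Similarity features
# ---------------------------------------------------------------------------

def naive_similarity(m: DetectionInstance, n: DetectionInstance,
                     frame_i: np.ndarray, frame_j: np.ndarray, backend) -> float:
    """S(m, n): similarity of the two masked crops in their own frames."""
    cm = m.masked_crop(frame_i)
    cn = n.masked_crop(frame_j)
    if not m.mask.any() or not n.mask.any():
        raise ValueError("empty mask in naive_similarity")
    return float(backend.similarity(cm, cn))


def self_similarity(m: DetectionInstance, frame_i: np.ndarray,
                    frame_j: np.ndarray, backend) -> float:
    """Q(m, n): m's masked crop vs the same region (mask A_m) in frame j."""
    x0, y0, x1, y1 = m.bbox
    if x0 < 0 or y0 < 0 or x1 > frame_j.shape[1] or y1 > frame_j.shape[0]:
        raise ValueError(f"mask footprint {m.bbox} outside frame {frame_j.shape}")
    cm = m.masked_crop(frame_i)
    cj = m.masked_crop(frame_j)       # same bbox + mask, later frame
    return float(backend.similarity(cm, cj))


def assemble_features(m: DetectionInstance, n: DetectionInstance,
                      frame_i: np.ndarray, frame_j: np.ndarray,
                      backend) -> MatchFeatures:
    """Compute the 5 matching features for an (earlier, later) pair."""
    if n.time < m.time:
        raise ValueError("pair must be time-ordered (t_j >= t_i)")
    if m.area <= 0 or n.area <= 0:
        raise ValueError("zero-area instance")
    s = naive_similarity(m, n, frame_i, frame_j, backend)
    q = self_similarity(m, frame_i, frame_j, backend)
    cm, cn = m.centroid, n.centroid
    dist = float(np.hypot(cm[0] - cn[0], cm[1] - cn[1]))
    ratio = abs(float(np.log(m.area / n.area)))
    dt_h = (n.time - m.time) / 3600.0
    return MatchFeatures(s, q, dist, ratio, float(np.log(dt_h + 1.0)))


# ---------------------------------------------------------------------------
# Decision heads
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class MatchHead:
    """Fully connected decision head with layer dimensions 5-4-3-1.

    ReLU activations after the first two layers, sigmoid at the output.
    Inputs are z-scored with statistics stored on the model.  Weights are
    plain numpy arrays so the head is deterministic and serialisable.
    """

    SIZES = (5, 4, 3, 1)

    def __init__(self, weights=None, norm_mean=None, norm_std=None, seed: int = 0):
        if weights is None:
            rng = np.random.default_rng(seed)
            weights = []
            for din, dout in zip(self.SIZES[:-1], self.SIZES[1:]):
                weights.append(rng.normal(0.0, np.sqrt(2.0 / din), (dout, din)))
                weights.append(np.zeros(dout))
        self.params = [np.asarray(w, float) for w in weights]
        self.norm_mean = np.zeros(5) if norm_mean is None else np.asarray(norm_mean, float)
        self.norm_std = np.ones(5) if norm_std is None else np.asarray(norm_std, float)

    # -- forward -----------------------------------------------------------
    def _normalise(self, X: np.ndarray) -> np.ndarray:
        return (X - self.norm_mean) / np.where(self.norm_std > 0, self.norm_std, 1.0)

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z = self._normalise(np.atleast_2d(X))
        W1, b1, W2, b2, W3, b3 = self.params
        h1 = _relu(Z @ W1.T + b1)
        h2 = _relu(h1 @ W2.T + b2)
        return _sigmoid(h2 @ W3.T + b3).ravel()

    def score(self, features: MatchFeatures) -> float:
        x = features.as_array()
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite feature vector")
        return float(self.forward(x)[0])

    # -- training ----------------------------------------------------------
    def _grads(self, X, y):
        """BCE gradients by manual backprop; returns (loss, grad list)."""
        Z = self._normalise(X)
        W1, b1, W2, b2, W3, b3 = self.params
        a1 = Z @ W1.T + b1
        h1 = _relu(a1)
        a2 = h1 @ W2.T + b2
        h2 = _relu(a2)
        a3 = (h2 @ W3.T + b3).ravel()
        p = _sigmoid(a3)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        n = X.shape[0]
        d3 = (p - y)[:, None] / n                       # (n,1)
        gW3 = d3.T @ h2
        gb3 = d3.sum(axis=0)
        d2 = (d3 @ W3) * (a2 > 0)
        gW2 = d2.T @ h1
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ W2) * (a1 > 0)
        gW1 = d1.T @ Z
        gb1 = d1.sum(axis=0)
        return loss, [gW1, gb1, gW2, gb2, gW3, gb3]

    def fit(self, X, y, rounds: int = 2000, batch: int = 128, lr: float = 0.05,
            seed: int = 0, balance: bool = True, reset_norm: bool = True):
        """Adam on BCE with per-round class rebalancing to 50% negatives.

        Returns the per-round loss history (training loss is expected to be
        non-increasing over a moving window, not monotonically).
        """
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training requires both positive and negative pairs")
        if reset_norm:
            self.norm_mean = X.mean(axis=0)
            self.norm_std = X.std(axis=0)
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        m = [np.zeros_like(p) for p in self.params]
        v = [np.zeros_like(p) for p in self.params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        history = []
        for t in range(1, rounds + 1):
            if balance:
                half = batch // 2
                bi = np.concatenate([
                    rng.choice(pos_idx, half, replace=True),
                    rng.choice(neg_idx, batch - half, replace=True)])
            else:
                bi = rng.integers(0, X.shape[0], batch)
            loss, grads = self._grads(X[bi], y[bi])
            history.append(loss)
            for k, g in enumerate(grads):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1 ** t)
                vh = v[k] / (1 - beta2 ** t)
                self.params[k] = self.params[k] - lr * mh / (np.sqrt(vh) + eps)
        return history

    def fit_continue(self, X, y, **kw):
        """Continue training with the stored normalisation statistics."""
        kw.setdefault("reset_norm", False)
        return self.fit(X, y, **kw)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {"kind": "mlp", "sizes": list(self.SIZES),
                "params": [p.tolist() for p in self.params],
                "norm_mean": self.norm_mean.tolist(),
                "norm_std": self.norm_std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MatchHead":
        return cls(weights=[np.asarray(p) for p in d["params"]],
                   norm_mean=d["norm_mean"], norm_std=d["norm_std"])


class LogisticMatchHead:
    """Logistic-regression fallback head on the 5 matching features.

    Convex and therefore robust at desk scale; exposes the same scoring
    interface as :class:`MatchHead`.
    """

    def __init__(self):
        self._clf = None
        self.norm_mean = np.zeros(5)
        self.norm_std = np.ones(5)

    def fit(self, X, y, seed: int = 0, **_ignored):
        from sklearn.linear_model import LogisticRegression

        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if np.unique(y).size < 2:
            raise ValueError("training requires both classes")
        self.norm_mean = X.mean(axis=0)
        self.norm_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self._clf = LogisticRegression(max_iter=1000, random_state=seed,
                                       class_weight="balanced")
        self._clf.fit((X - self.norm_mean) / self.norm_std, y)
        return []

    def forward(self, X) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("head not trained")
        Z = (np.atleast_2d(X) - self.norm_mean) / self.norm_std
        return self._clf.predict_proba(Z)[:, 1]

    def score(self, features: MatchFeatures) -> float:
        return float(self.forward(features.as_array())[0])

    def to_dict(self) -> dict:
        return {"kind": "logistic",
                "coef": self._clf.coef_.tolist(),
                "intercept": self._clf.intercept_.tolist(),
                "classes": self._clf.classes_.tolist(),
                "norm_mean": self.norm_mean.tolist(),
                "norm_std": self.norm_std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticMatchHead":
        from sklearn.linear_model import LogisticRegression

        obj = cls()
        clf = LogisticRegression()
        clf.coef_ = np.asarray(d["coef"])
        clf.intercept_ = np.asarray(d["intercept"])
        clf.classes_ = np.asarray(d["classes"])
        obj._clf = clf
        obj.norm_mean = np.asarray(d["norm_mean"])
        obj.norm_std = np.asarray(d["norm_std"])
        return obj


def match_score(features: MatchFeatures, head) -> float:
    """M(m, n): the head's sigmoid output for one feature vector."""
    return head.score(features)


# ---------------------------------------------------------------------------
# Training orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSchedule:
    """Three-phase schedule: similarity-branch pretrain, head-only, joint."""

    pretrain_rounds: int = 200
    head_rounds: int = 1500
    joint_rounds: int = 500
    batch: int = 128
    lr: float = 0.05


def fit_matcher(X, y, backend=None, head=None,
                schedule: TrainingSchedule | None = None, seed: int = 0):
    """Train the matching head (and backend, where trainable).

    ``X`` is the (n, 5) feature matrix of labelled pairs and ``y`` the
    binary labels (1 = same insect).  Phase 1 pretrains the descriptor
    backend if it exposes ``fit`` (the default NCC backend is
    training-free, so the phase is a no-op); phase 2 trains the head only;
    phase 3 jointly fine-tunes (for a fixed backend this continues head
    training).  Negatives are rebalanced to 50% per batch throughout.
    Deterministic under a fixed seed.
    """
    schedule = schedule or TrainingSchedule()
    head = head if head is not None else MatchHead(seed=seed)
    if backend is not None and hasattr(backend, "fit"):
        backend.fit(X, y, rounds=schedule.pretrain_rounds, seed=seed)
    hist = head.fit(X, y, rounds=schedule.head_rounds, batch=schedule.batch,
                    lr=schedule.lr, seed=seed)
    if isinstance(head, MatchHead) and schedule.joint_rounds:
        hist += head.fit_continue(X, y, rounds=schedule.joint_rounds,
                                  batch=schedule.batch, lr=schedule.lr / 5,
                                  seed=seed + 1)
    return head, hist


def save_model_bundle(head, directory, backend_name: str = "ncc") -> None:
    """Persist a matcher model bundle (head weights + metadata) as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = {"schema_version": 1, "backend": backend_name, "head": head.to_dict()}
    (directory / "matcher.json").write_text(json.dumps(bundle))


def load_model_bundle(directory):
    """Load a matcher bundle; returns (head, backend_name)."""
    d = json.loads((Path(directory) / "matcher.json").read_text())
    head_d = d["head"]
    head = (MatchHead.from_dict(head_d) if head_d["kind"] == "mlp"
            else LogisticMatchHead.from_dict(head_d))
    return head, d["backend"]
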