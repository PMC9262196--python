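"""Synthetic sticky-trap scenes with ground truth.

Emulates the statistical structure a trap pipeline assumes so every stage
is testable without field data: per-taxon arrival processes with
diel-modulated intensity (inhomogeneous Poisson, thinning), insects
rendered as textured elliptical blobs that stay on the card once trapped,
small positional jitter, transient occlusion (two-state Markov chain),
permanent escape, and a configurable frame interval (default 20 minutes).

The generator is deliberately not photorealistic: no weather, illumination
drift or predators.  Times are UTC epoch seconds throughout; Warped
Zeitgeber conversion happens only at analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from chronotrap.chrono import WztParams, wzt_hours

__all__ = [
    "DielShape",
    "TaxonSpec",
    "SceneConfig",
    "BehaviourConfig",
    "GroundTruthTrack",
    "TrackFrame",
    "SimulationError",
    "simulate_capture_times",
    "render_series",
    "events_to_csv",
]

SECONDS_PER_HOUR = 3600.0


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Taxon specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DielShape:
    """24 h-periodic intensity multiplier with mean 1 over the day.

    Wrapped-Gaussian bumps (peak phase in WZT hours, concentration = sd in
    hours) summed over one or two peaks plus a uniform floor; covers flat,
    unimodal and bimodal (crepuscular) patterns with three parameters per
    peak.
    """

    peaks: tuple = ()            # ((phase_h, sd_h, weight), ...)
    floor: float = 1.0

    def intensity(self, wzt_h):
        """Unnormalised intensity at WZT hour(s)."""
        w = np.mod(np.asarray(wzt_h, dtype=float), 24.0)
        out = np.full_like(w, float(self.floor))
        for phase, sd, weight in self.peaks:
            # wrap over +/- 2 periods; negligible mass beyond for sd << 24
            for k in (-24.0, 0.0, 24.0):
                out = out + weight * np.exp(-0.5 * ((w - phase + k) / sd) ** 2)
        return out

    def __call__(self, wzt_h):
        """Normalised multiplier: mean over the 24 h day equals 1."""
        grid = np.linspace(0.0, 24.0, 2881)[:-1]
        mean = float(self.intensity(grid).mean())
        if mean <= 0:
            raise ValueError("diel shape must have positive mean intensity")
        return np.asarray(self.intensity(wzt_h)) / mean

    @property
    def max_multiplier(self) -> float:
        grid = np.linspace(0.0, 24.0, 2881)[:-1]
        vals = self(grid)
        return float(vals.max())


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated taxon: arrival rate, diel pattern, size and look."""

    name: str
    base_rate: float                       # expected captures per hour (marginal)
    diel: DielShape = field(default_factory=DielShape)
    size_px: tuple = (60.0, 8.0)           # body length mean, sd (px)
    intensity: int = 60                    # mean blob gray level (dark on light card)

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_rate) or self.base_rate < 0:
            raise ValueError(f"base_rate must be finite and >= 0, got {self.base_rate}")
        if self.size_px[0] <= 0:
            raise ValueError("size mean must be positive")


# ---------------------------------------------------------------------------
# Capture-time simulation
# ---------------------------------------------------------------------------

def simulate_capture_times(taxa, start: float, duration_h: float,
                           wzt_params: WztParams | None = None,
                           seed: int = 0):
    """Draw capture events from per-taxon inhomogeneous Poisson processes.

    Intensity of a taxon is ``base_rate * diel(WZT(t))`` (the diel
    multiplier has mean 1, so ``base_rate`` is the marginal rate).  Events
    are generated by thinning a homogeneous process at the diel maximum.
    Returns a time-sorted list of ``(taxon_name, time_epoch_s)``;
    bit-identical under a fixed seed.
    """
    if duration_h <= 0:
        raise ValueError(f"duration must be positive, got {duration_h}")
    if wzt_params is None:
        wzt_params = WztParams(sunrise_frac=0.25, day_frac=0.5)
    rng = np.random.default_rng(seed)
    events = []
    for taxon in taxa:
        if taxon.base_rate == 0:
            continue
        lam_max = taxon.base_rate * taxon.diel.max_multiplier
        n_cand = rng.poisson(lam_max * duration_h)
        t_cand = np.sort(rng.uniform(0.0, duration_h, n_cand))
        abs_t = start + t_cand * SECONDS_PER_HOUR
        day_frac = (abs_t / 86400.0) % 1.0
        mult = taxon.diel(wzt_hours(day_frac, wzt_params))
        accept = rng.uniform(0.0, 1.0, n_cand) * lam_max <= taxon.base_rate * mult
        events.extend((taxon.name, float(t)) for t in abs_t[accept])
    events.sort(key=lambda e: (e[1], e[0]))
    return events


def events_to_csv(events, device_id: str, path) -> None:
    """Write an event list as CSV (taxon, arrival_iso8601, device_id)."""
    import pandas as pd

    df = pd.DataFrame(events, columns=["taxon", "t"])
    df["arrival_iso8601"] = pd.to_datetime(df.pop("t"), unit="s", utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    df["device_id"] = device_id
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    width: int = 1280
    height: int = 960
    background: float = 210.0        # light sticky card
    noise_sd: float = 4.0
    placement_margin: int = 12       # min px between new blob bbox and others
    max_place_retries: int = 200


@dataclass(frozen=True)
class BehaviourConfig:
    jitter_sd_px: float = 1.2
    jitter_max_px: float = 5.0
    occlusion_on: float = 0.01       # P(visible -> occluded) per frame
    occlusion_off: float = 0.6       # P(occluded -> visible) per frame
    escape_per_frame: float = 0.0    # P(permanent escape) per frame


@dataclass
class TrackFrame:
    frame_idx: int
    time: float
    centroid: tuple                  # (x, y) px
    visible: bool


@dataclass
class GroundTruthTrack:
    """Per-insect ground truth: taxon, arrival, and per-frame state."""

    track_id: int
    taxon: str
    arrival_time: float
    half_axes: tuple                 # (semi-major, semi-minor) px
    angle: float                     # radians
    frames: list = field(default_factory=list)

    @property
    def length_px(self) -> float:
        return 2.0 * self.half_axes[0]

    def frame_at(self, frame_idx: int) -> TrackFrame | None:
        for f in self.frames:
            if f.frame_idx == frame_idx:
                return f
        return None

    def mask_at(self, frame_idx: int, shape) -> np.ndarray | None:
        """Boolean full-frame mask of the blob at a given frame, else None."""
        f = self.frame_at(frame_idx)
        if f is None or not f.visible:
            return None
        cx, cy = f.centroid
        rr, cc = draw_ellipse(cy, cx, self.half_axes[1], self.half_axes[0],
                              shape=shape, rotation=self.angle)
        m = np.zeros(shape, bool)
        m[rr, cc] = True
        return m

    def to_record(self) -> dict:
        return {
            "track_id": self.track_id, "taxon": self.taxon,
            "arrival_time": self.arrival_time,
            "half_axes": list(self.half_axes), "angle": self.angle,
            "frames": [
                {"frame_idx": f.frame_idx, "time": f.time,
                 "centroid": list(f.centroid), "visible": f.visible}
                for f in self.frames
            ],
        }


class _Blob:
    """Internal render state: a textured elliptical patch pasted per frame."""

    def __init__(self, track: GroundTruthTrack, taxon: TaxonSpec, rng):
        a, b = track.half_axes
        pad = 2
        h = int(2 * max(a, b)) + 2 * pad
        rr, cc = draw_ellipse(h / 2, h / 2, b, a, shape=(h, h),
                              rotation=track.angle)
        self.mask = np.zeros((h, h), bool)
        self.mask[rr, cc] = True
        # stable per-insect speckle texture -> high self-similarity over time
        tex = taxon.intensity + rng.normal(0.0, 18.0, (h, h))
        self.patch = np.clip(tex, 5, 250)
        self.anchor = h / 2.0
        self.pos = None                       # float (x, y) of centroid
        self.occluded = False
        self.escaped = False

    def paste(self, img: np.ndarray) -> None:
        h = self.mask.shape[0]
        x0 = int(round(self.pos[0] - self.anchor))
        y0 = int(round(self.pos[1] - self.anchor))
        ys0, xs0 = max(0, -y0), max(0, -x0)
        ye = min(h, img.shape[0] - y0)
        xe = min(h, img.shape[1] - x0)
        if ye <= ys0 or xe <= xs0:
            return
        sub = img[y0 + ys0:y0 + ye, x0 + xs0:x0 + xe]
        m = self.mask[ys0:ye, xs0:xe]
        sub[m] = self.patch[ys0:ye, xs0:xe][m]

    def int_centroid(self):
        """Centroid implied by the rounded paste position (exact truth)."""
        x0 = round(self.pos[0] - self.anchor) + self.anchor
        y0 = round(self.pos[1] - self.anchor) + self.anchor
        return (float(x0), float(y0))


def render_series(events, start: float, duration_h: float,
                  taxa, frame_interval_min: float = 20.0,
                  scene: SceneConfig | None = None,
                  behaviour: BehaviourConfig | None = None,
                  seed: int = 0):
    """Render an image series for a capture-event stream, with ground truth.

    One uint8 grayscale frame per interval; each visible insect is a filled
    textured ellipse.  Trapped insects jitter around their landing spot
    (clipped at ``jitter_max_px``), may be transiently occluded, and may
    permanently escape.  Returns ``(frame_times, frames, tracks)`` where
    the rendered blob centroid agrees with the recorded truth within 1 px.

    Raises :class:`SimulationError` (naming the frame) if a new insect
    cannot be placed without overlapping existing ones after the retry
    limit.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval must be positive")
    scene = scene or SceneConfig()
    behaviour = behaviour or BehaviourConfig()
    taxa_by_name = {t.name: t for t in taxa}
    rng = np.random.default_rng(seed)

    n_frames = int(np.floor(duration_h * 60.0 / frame_interval_min)) + 1
    frame_times = start + np.arange(n_frames) * frame_interval_min * 60.0
    max_len = max((t.size_px[0] + 4 * t.size_px[1] for t in taxa), default=0)
    if max_len >= min(scene.width, scene.height) - 2 * scene.placement_margin:
        raise ValueError("image too small to hold the largest blob")

    queue = sorted(events, key=lambda e: e[1])
    tracks, blobs = [], []
    frames = []
    occ = np.zeros((scene.height, scene.width), bool)   # occupied px (home pos)

    def stamp(blob, grid, value=True):
        h = blob.mask.shape[0]
        x0 = int(round(blob.home[0] - blob.anchor))
        y0 = int(round(blob.home[1] - blob.anchor))
        ys0, xs0 = max(0, -y0), max(0, -x0)
        ye, xe = min(h, grid.shape[0] - y0), min(h, grid.shape[1] - x0)
        if ye > ys0 and xe > xs0:
            grid[y0 + ys0:y0 + ye, x0 + xs0:x0 + xe][blob.mask[ys0:ye, xs0:xe]] = value

    qi = 0
    for fi, ft in enumerate(frame_times):
        # admit insects that arrived since the previous frame
        while qi < len(queue) and queue[qi][1] <= ft:
            name, at = queue[qi]
            qi += 1
            if at < start:
                continue
            taxon = taxa_by_name[name]
            length = float(np.clip(rng.normal(*taxon.size_px), 8.0, None))
            a = length / 2.0
            b = max(2.0, 0.4 * a)
            angle = float(rng.uniform(0, np.pi))
            track = GroundTruthTrack(len(tracks), name, float(at), (a, b), angle)
            blob = _Blob(track, taxon, rng)
            placed = False
            half = blob.anchor
            margin = scene.placement_margin
            h = blob.mask.shape[0]
            for _ in range(scene.max_place_retries):
                pos = (rng.uniform(half, scene.width - half),
                       rng.uniform(half, scene.height - half))
                x0 = int(round(pos[0] - half))
                y0 = int(round(pos[1] - half))
                region = occ[max(0, y0 - margin):y0 + h + margin,
                             max(0, x0 - margin):x0 + h + margin]
                if not region.any():
                    blob.pos = pos
                    blob.home = pos
                    placed = True
                    break
            if not placed:
                raise SimulationError(
                    f"could not place insect arriving at frame {fi} (overcrowded)")
            tracks.append(track)
            blobs.append(blob)
            blob.track = track
            stamp(blob, occ, True)

        # advance behaviour state and record truth
        img = np.clip(rng.normal(scene.background, scene.noise_sd,
                                 (scene.height, scene.width)), 0, 255)
        for blob in blobs:
            if blob.escaped:
                continue
            track = blob.track
            if track.frames:     # jitter only after the first rendered frame
                if rng.uniform() < behaviour.escape_per_frame:
                    blob.escaped = True
                    stamp(blob, occ, False)
                    continue
                if blob.occluded:
                    if rng.uniform() < behaviour.occlusion_off:
                        blob.occluded = False
                else:
                    if rng.uniform() < behaviour.occlusion_on:
                        blob.occluded = True
                jit = rng.normal(0.0, behaviour.jitter_sd_px, 2)
                jit = np.clip(jit, -behaviour.jitter_max_px, behaviour.jitter_max_px)
                newx = float(np.clip(blob.home[0] + jit[0], blob.anchor,
                                     scene.width - blob.anchor))
                newy = float(np.clip(blob.home[1] + jit[1], blob.anchor,
                                     scene.height - blob.anchor))
                blob.pos = (newx, newy)
            visible = not blob.occluded
            if visible:
                blob.paste(img)
            track.frames.append(TrackFrame(fi, float(ft), blob.int_centroid(),
                                           visible))
        frames.append(img.astype(np.uint8))

    return frame_times, frames, tracks
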