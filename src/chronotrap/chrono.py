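"""Chronoecology statistics for capture-event series.

This module turns per-frame insect counts, or the start times of tracked
insects ("tuboids"), into the standard chronobiology quantities used for
sticky-trap time series:

* **Warped Zeitgeber time (WZT)** — a piecewise-linear rescaling of
  Zeitgeber time (hours since sunrise) such that sunrise maps to 0 and
  sunset always maps to half a day, making days of unequal length
  comparable.  With day length ``d`` (as a day fraction) the map is
  ``W(z) = a z`` for ``z <= d`` and ``W(z) = a' z + b'`` otherwise, where
  ``a = 1/(2d)``, ``a' = 1/(2(1-d))`` and ``b' = 1 - a'``.
* **Low-pass filtering** of laboratory count series: a running median
  (k = 5) on raw counts followed by a uniform moving average (k = 5) on the
  instantaneous capture rate dN/dt; at 20-minute sampling this acts as a
  low-pass filter with a span of about 100 minutes.
* **Rhythmicity** — lag-24 h autocorrelation of the capture-rate series per
  replicate, with a one-sample t-test of the replicate ACF values against 0.
* **Diel profiles** — mean +/- SE capture rate per WZT-hour bin across
  replicates (device x week).
* **Temporal-niche MDS** — pairwise dissimilarity between taxa derived
  from the Pearson correlation of their hourly profiles, embedded in 2-D by
  metric MDS, with bootstrap replicates (resampling capture instances per
  taxon), Procrustes-aligned and summarised by 95% bivariate-t ellipses.
* **Diel-window fractions** — observed share of captures inside a set of
  WZT windows versus the uniform null (window length / 24), with a
  percentile bootstrap CI.
* **Trap-saturation test** — per-taxon OLS of the first-half capture share
  N[0,3d]/N[0,6d] against total trap load, testing intercept = 1/2 and
  slope = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WztParams",
    "wzt",
    "wzt_inverse",
    "wzt_hours",
    "sun_times",
    "CaptureSeries",
    "rate_series",
    "lowpass",
    "filter_span_minutes",
    "RhythmicityResult",
    "rhythmicity",
    "DielProfile",
    "diel_profile",
    "WindowFractionResult",
    "window_fraction",
    "profile_distance_matrix",
    "NicheMdsResult",
    "niche_mds",
    "saturation_test",
]


# ---------------------------------------------------------------------------
# Warped Zeitgeber time
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WztParams:
    """Parameters of the Warped Zeitgeber time map.

    Parameters
    ----------
    sunrise_frac : float
        Time of sunrise as a fraction of the day since midnight (UTC or
        local — the caller's convention, applied consistently).
    day_frac : float
        Day length ``d`` as a fraction of the 24 h day, strictly in (0, 1).
    """

    sunrise_frac: float
    day_frac: float

    def __post_init__(self) -> None:
        if not (0.0 < self.day_frac < 1.0):
            raise ValueError(f"day fraction must be in (0, 1), got {self.day_frac}")

    @property
    def a(self) -> float:
        """Slope of the daytime branch: 1 / (2 d)."""
        return 1.0 / (2.0 * self.day_frac)

    @property
    def a_prime(self) -> float:
        """Slope of the nighttime branch: 1 / (2 (1 - d))."""
        return 1.0 / (2.0 * (1.0 - self.day_frac))

    @property
    def b_prime(self) -> float:
        """Intercept of the nighttime branch: 1 - a'."""
        return 1.0 - self.a_prime


def wzt(t_frac, p: WztParams):
    """Map absolute time-of-day to Warped Zeitgeber time (day fractions).

    ``t_frac`` is the time of day as a fraction of the day since midnight
    (scalar or array).  Zeitgeber time is ``z = (t - s) mod 1`` with ``s``
    the sunrise; the piecewise-linear warp then sends sunrise to 0, sunset
    (``z = d``) to 1/2 and midnight-before-sunrise back to 1.

    Returns WZT in [0, 1).
    """
    t = np.asarray(t_frac, dtype=float)
    z = np.mod(t - p.sunrise_frac, 1.0)
    day = z <= p.day_frac
    w = np.where(day, p.a * z, p.a_prime * z + p.b_prime)
    w = np.mod(w, 1.0)
    return w if w.ndim else float(w)


def wzt_inverse(w_frac, p: WztParams):
    """Inverse of :func:`wzt`: WZT day fraction back to time of day."""
    w = np.mod(np.asarray(w_frac, dtype=float), 1.0)
    day = w <= 0.5
    z = np.where(day, w / p.a, (w - p.b_prime) / p.a_prime)
    t = np.mod(z + p.sunrise_frac, 1.0)
    return t if t.ndim else float(t)


def wzt_hours(t_frac, p: WztParams):
    """Convenience: :func:`wzt` scaled to hours in [0, 24)."""
    return np.multiply(wzt(t_frac, p), 24.0)


def sun_times(latitude: float, longitude: float, day_of_year: int) -> WztParams:
    """Sunrise and day length from the standard sunrise equation.

    Uses the NOAA-style closed form: solar declination
    ``delta = -23.44 deg * cos(2 pi (N + 10) / 365)``, hour angle
    ``cos(omega0) = -tan(phi) tan(delta)``, plus the three-term equation of
    time.  Times are UTC day fractions.  Adequate to a few minutes, which
    is ample for hour-binned capture data; polar day/night raises.
    """
    phi = math.radians(latitude)
    delta = math.radians(-23.44) * math.cos(2.0 * math.pi * (day_of_year + 10) / 365.0)
    x = -math.tan(phi) * math.tan(delta)
    if not (-1.0 < x < 1.0):
        raise ValueError("polar day or night: sunrise equation has no solution")
    omega0 = math.acos(x)  # radians
    day_frac = omega0 / math.pi
    b = 2.0 * math.pi * (day_of_year - 81) / 365.0
    eot_min = 9.87 * math.sin(2 * b) - 7.53 * math.cos(b) - 1.5 * math.sin(b)
    solar_noon = 0.5 - longitude / 360.0 - eot_min / 1440.0
    sunrise = (solar_noon - day_frac / 2.0) % 1.0
    return WztParams(sunrise_frac=sunrise, day_frac=day_frac)


# ---------------------------------------------------------------------------
# Capture-rate series
# ---------------------------------------------------------------------------

@dataclass
class CaptureSeries:
    """A per-replicate capture series, either raw counts or a rate.

    ``times`` are bin/frame midpoints in epoch seconds (uniformly spaced);
    ``values`` are counts (kind='counts') or capture rates in insects per
    hour (kind='rate').
    """

    times: np.ndarray
    values: np.ndarray
    bin_minutes: float
    kind: str = "counts"
    device: str = ""
    replicate: str = ""
    taxon: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind == "counts" and np.any(self.values < 0):
            raise ValueError("counts must be non-negative")


def rate_series(
    event_times=None,
    *,
    counts=None,
    frame_times=None,
    start: float | None = None,
    end: float | None = None,
    bin_minutes: float = 60.0,
    **series_kw,
) -> CaptureSeries:
    """Build a :class:`CaptureSeries` from event times or per-frame counts.

    Exactly one of ``event_times`` (tuboid start times, epoch seconds) or
    ``counts`` + ``frame_times`` must be given.  Event times are binned and
    divided by the bin width, yielding a rate in insects/hour; per-frame
    counts are returned as a 'counts' series (to be turned into a rate by
    :func:`lowpass`).
    """
    if (event_times is None) == (counts is None):
        raise ValueError("provide exactly one of event_times or counts")
    if counts is not None:
        if frame_times is None:
            raise ValueError("counts require frame_times")
        ft = np.asarray(frame_times, dtype=float)
        if np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        return CaptureSeries(ft, np.asarray(counts, float), bin_minutes, "counts", **series_kw)

    ev = np.sort(np.asarray(event_times, dtype=float))
    if start is None:
        start = float(ev[0]) if ev.size else 0.0
    if end is None:
        end = float(ev[-1]) + 1.0 if ev.size else start + bin_minutes * 60.0
    width = bin_minutes * 60.0
    n_bins = max(1, int(np.ceil((end - start) / width)))
    edges = start + width * np.arange(n_bins + 1)
    hist, _ = np.histogram(ev, bins=edges)
    centers = edges[:-1] + width / 2.0
    rate = hist / (bin_minutes / 60.0)
    return CaptureSeries(centers, rate, bin_minutes, "rate", **series_kw)


def filter_span_minutes(k: int = 5, frame_interval_minutes: float = 20.0) -> float:
    """Approximate temporal span of a width-k running filter, in minutes."""
    return k * frame_interval_minutes


def lowpass(series: CaptureSeries, k_median: int = 5, k_uniform: int = 5):
    """Low-pass filter a raw count series and derive the capture rate.

    Counts are median-filtered (running median, width ``k_median``), the
    instantaneous rate dN/dt (insects/hour) is taken as the first
    difference per unit time, and the rate is smoothed with a centred
    uniform moving average of width ``k_uniform``.  Window edges shrink at
    the boundaries.  Series shorter than the window are returned
    unfiltered with ``flag='too-short'`` after a warning.

    Returns ``(filtered_counts: CaptureSeries, rate: CaptureSeries)``.
    """
    if series.kind != "counts":
        raise ValueError("lowpass expects a raw 'counts' series")
    n = series.values.size
    if n < max(k_median, k_uniform):
        warnings.warn("series shorter than filter width; filtering skipped")
        rate = CaptureSeries(series.times, np.zeros(n), series.bin_minutes, "rate",
                             device=series.device, replicate=series.replicate,
                             taxon=series.taxon)
        rate.flag = "too-short"  # type: ignore[attr-defined]
        return series, rate

    s = pd.Series(series.values)
    med = s.rolling(k_median, center=True, min_periods=1).median().to_numpy()
    dt_h = np.diff(series.times) / 3600.0
    dndt = np.concatenate([[0.0], np.diff(med) / dt_h])
    smoothed = (
        pd.Series(dndt).rolling(k_uniform, center=True, min_periods=1).mean().to_numpy()
    )
    filtered = CaptureSeries(series.times, med, series.bin_minutes, "counts",
                             device=series.device, replicate=series.replicate,
                             taxon=series.taxon)
    rate = CaptureSeries(series.times, smoothed, series.bin_minutes, "rate",
                         device=series.device, replicate=series.replicate,
                         taxon=series.taxon)
    return filtered, rate


# ---------------------------------------------------------------------------
# Rhythmicity
# ---------------------------------------------------------------------------

@dataclass
class RhythmicityResult:
    acf: np.ndarray          # per-series lag ACF
    lag_bins: int
    lag_hours: float
    mean: float
    t_stat: float
    p_value: float
    n: int


def _acf_at_lag(x: np.ndarray, lag: int) -> float:
    """Pearson autocorrelation of ``x`` at integer lag over the overlap."""
    if lag <= 0 or lag >= x.size:
        raise ValueError(f"lag {lag} outside series span {x.size}")
    a, b = x[:-lag], x[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rhythmicity(series_group, lag_hours: float = 24.0) -> RhythmicityResult:
    """Lag-24 h autocorrelation rhythmicity with a one-sample group t-test.

    ``series_group`` is a sequence of rate :class:`CaptureSeries`, one per
    replicate (device x week).  The ACF is the Pearson correlation of each
    rate series with itself shifted by the number of bins closest to
    ``lag_hours``; the group test is a two-sided one-sample t-test of the
    per-series ACF values against zero (needs >= 2 series).
    """
    series_group = list(series_group)
    if len(series_group) < 2:
        raise ValueError("rhythmicity group test needs at least 2 series")
    acfs = []
    lag_bins = None
    for s in series_group:
        if s.kind != "rate":
            raise ValueError("rhythmicity expects rate series")
        lb = int(round(lag_hours * 60.0 / s.bin_minutes))
        lag_bins = lb if lag_bins is None else lag_bins
        acfs.append(_acf_at_lag(s.values, lb))
    acfs = np.asarray(acfs)
    t_stat, p = stats.ttest_1samp(acfs, 0.0)
    return RhythmicityResult(acfs, int(lag_bins), lag_hours, float(acfs.mean()),
                             float(t_stat), float(p), len(acfs))


# ---------------------------------------------------------------------------
# Diel profiles
# ---------------------------------------------------------------------------

@dataclass
class DielProfile:
    """Mean +/- SE capture rate per WZT-hour bin across replicates."""

    taxon: str
    bin_edges: np.ndarray        # 25 edges over [0, 24]
    mean: np.ndarray             # insects / hour, length 24
    se: np.ndarray
    n_replicates: int
    per_replicate: pd.DataFrame = field(repr=False, default=None)

    @property
    def peak_hour(self) -> int:
        """WZT-hour bin with the highest mean capture rate."""
        return int(np.argmax(self.mean))


def diel_profile(
    events_wzt_hours,
    replicate_keys,
    *,
    taxon: str = "",
    exposure_days,
    n_bins: int = 24,
) -> DielProfile:
    """Average diel capture-rate profile over WZT-hour bins.

    Parameters
    ----------
    events_wzt_hours : array-like
        WZT of each capture event, in hours [0, 24).
    replicate_keys : array-like
        Replicate (device x week) label per event.
    exposure_days : mapping
        Days each replicate was observed (each WZT-hour bin of a replicate
        is exposed once per day); converts counts to rates in insects/hour.
    """
    w = np.mod(np.asarray(events_wzt_hours, dtype=float), 24.0)
    keys = np.asarray(replicate_keys)
    if w.shape != keys.shape:
        raise ValueError("events and replicate keys must align")
    edges = np.linspace(0.0, 24.0, n_bins + 1)
    bin_h = 24.0 / n_bins
    reps = sorted(set(exposure_days))
    rows = {}
    for r in reps:
        mask = keys == r
        hist, _ = np.histogram(w[mask], bins=edges)
        rows[r] = hist / (exposure_days[r] * bin_h)
    per_rep = pd.DataFrame(rows).T  # replicates x bins
    mean = per_rep.mean(axis=0).to_numpy()
    n = len(reps)
    se = per_rep.std(axis=0, ddof=1).to_numpy() / np.sqrt(n) if n > 1 else np.zeros(n_bins)
    return DielProfile(taxon, edges, mean, se, n, per_rep)


# ---------------------------------------------------------------------------
# Diel-window fractions
# ---------------------------------------------------------------------------

def _merge_windows(windows):
    """Normalise WZT-hour windows to merged, non-wrapping intervals."""
    flat = []
    for lo, hi in windows:
        lo, hi = float(lo) % 24.0, float(hi)
        if hi != 24.0:
            hi = hi % 24.0
        if hi < lo:          # wraps midnight: split
            flat.extend([(lo, 24.0), (0.0, hi)])
        else:
            flat.append((lo, hi))
    flat.sort()
    merged = []
    for lo, hi in flat:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


@dataclass
class WindowFractionResult:
    observed: float
    null: float
    ci_low: float
    ci_high: float
    n_events: int
    n_boot: int
    windows: list


def window_fraction(events_wzt_hours, windows, n_boot: int = 10_000,
                    seed: int = 0) -> WindowFractionResult:
    """Fraction of captures inside a set of WZT windows vs the uniform null.

    The null expectation under time-uniform captures is the total merged
    window length divided by 24 (e.g. the daytime window WZT < 12 gives
    exactly 50%).  The CI is a percentile bootstrap over events resampled
    with replacement.
    """
    merged = _merge_windows(windows)
    null = sum(hi - lo for lo, hi in merged) / 24.0
    w = np.mod(np.asarray(events_wzt_hours, dtype=float), 24.0)
    if not merged or w.size == 0:
        return WindowFractionResult(0.0, null, 0.0, 0.0, int(w.size), 0, merged)
    inside = np.zeros(w.shape, dtype=bool)
    for lo, hi in merged:
        inside |= (w >= lo) & (w < hi)
    obs = float(inside.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, w.size, size=(n_boot, w.size))
    boot = inside[idx].mean(axis=1)
    lo_ci, hi_ci = np.percentile(boot, [2.5, 97.5])
    return WindowFractionResult(obs, null, float(lo_ci), float(hi_ci),
                                int(w.size), n_boot, merged)


# ---------------------------------------------------------------------------
# Temporal-niche MDS
# ---------------------------------------------------------------------------

def _hourly_profile(wzt_h: np.ndarray, n_bins: int = 24) -> np.ndarray:
    hist, _ = np.histogram(np.mod(wzt_h, 24.0), bins=np.linspace(0, 24, n_bins + 1))
    return hist.astype(float)


def profile_distance_matrix(profiles: dict, distance: str = "sqrt") -> pd.DataFrame:
    """Pairwise temporal-niche distance between taxa.

    The distance derives from the Pearson correlation ``r`` of the hourly
    activity profiles.  The default ``'sqrt'`` form,
    ``d = sqrt((1 - r) / 2)``, maps r in [-1, 1] onto [0, 1] and is a
    proper metric; ``'linear'`` uses ``d = (1 - r) / 2``.  Constant
    (zero-variance) profiles have undefined correlation and raise.
    """
    taxa = list(profiles)
    for t in taxa:
        if np.std(profiles[t]) == 0:
            raise ValueError(f"constant profile for taxon {t!r}: correlation undefined")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.corrcoef(profiles[taxa[i]], profiles[taxa[j]])[0, 1])
            if distance == "sqrt":
                dij = math.sqrt(max(0.0, (1.0 - r) / 2.0))
            elif distance == "linear":
                dij = (1.0 - r) / 2.0
            else:
                raise ValueError(f"unknown distance {distance!r}")
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=taxa, columns=taxa)


def _mds_2d(dmat: np.ndarray, seed: int) -> np.ndarray:
    from sklearn.manifold import MDS

    try:
        mds = MDS(n_components=2, metric="precomputed", random_state=seed,
                  n_init=4, init="random", normalized_stress=False)
    except TypeError:     # older scikit-learn API
        mds = MDS(n_components=2, dissimilarity="precomputed", random_state=seed,
                  n_init=4, normalized_stress=False)
    return mds.fit_transform(dmat)


def _procrustes_align(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Align X to ref by translation + rotation/reflection (no scaling)."""
    from scipy.linalg import orthogonal_procrustes

    Xc = X - X.mean(axis=0)
    Rc = ref - ref.mean(axis=0)
    R, _ = orthogonal_procrustes(Xc, Rc)
    return Xc @ R + ref.mean(axis=0)


@dataclass
class NicheMdsResult:
    taxa: list
    coords: pd.DataFrame                 # point-estimate 2-D embedding
    boot_coords: np.ndarray              # (n_boot, n_taxa, 2), aligned
    ellipses: dict                       # taxon -> (center(2,), cov(2,2), radius2)
    distance: pd.DataFrame
    excluded: list

    def ellipse_polygon(self, taxon: str, n_pts: int = 90):
        """95% ellipse boundary of a taxon's bootstrap cloud as a shapely Polygon."""
        from shapely.geometry import Polygon

        center, cov, r2 = self.ellipses[taxon]
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        circ = np.stack([np.cos(theta), np.sin(theta)], axis=1)
        pts = center + (circ * np.sqrt(vals * r2)) @ vecs.T
        return Polygon(pts)


def niche_mds(events_by_taxon: dict, n_boot: int = 500, seed: int = 0,
              distance: str = "sqrt", n_bins: int = 24) -> NicheMdsResult:
    """Bootstrap MDS map of taxa's temporal niches.

    ``events_by_taxon`` maps each taxon to the WZT (hours) of its capture
    events.  Hourly activity profiles give a Pearson-correlation distance
    matrix (see :func:`profile_distance_matrix`), embedded in 2-D by metric
    stress-majorisation MDS.  ``n_boot`` bootstrap replicates resample the
    capture instances with replacement independently per taxon; each
    replicate's MDS solution is aligned to the point estimate by orthogonal
    Procrustes before pooling.  Per-taxon 95% confidence ellipses assume a
    bivariate t (Hotelling) distribution of the bootstrap cloud.

    Taxa with constant profiles (correlation undefined) are excluded with a
    warning.  Requires >= 3 usable taxa.
    """
    rng = np.random.default_rng(seed)
    usable, excluded = {}, []
    for t, ev in events_by_taxon.items():
        ev = np.asarray(ev, dtype=float)
        if ev.size == 0 or np.std(_hourly_profile(ev, n_bins)) == 0:
            excluded.append(t)
            warnings.warn(f"taxon {t!r} excluded: constant or empty profile")
        else:
            usable[t] = ev
    taxa = list(usable)
    if len(taxa) < 3:
        raise ValueError("niche_mds needs at least 3 taxa with variable profiles")

    profiles = {t: _hourly_profile(usable[t], n_bins) for t in taxa}
    dmat = profile_distance_matrix(profiles, distance)
    ref = _mds_2d(dmat.to_numpy(), seed)

    boot = np.empty((n_boot, len(taxa), 2))
    for b in range(n_boot):
        prof_b = {}
        for t in taxa:
            ev = usable[t]
            prof_b[t] = _hourly_profile(ev[rng.integers(0, ev.size, ev.size)], n_bins)
        try:
            db = profile_distance_matrix(prof_b, distance).to_numpy()
        except ValueError:      # degenerate resample; rare — reuse point estimate
            db = dmat.to_numpy()
        sol = _mds_2d(db, seed + 1 + b)
        boot[b] = _procrustes_align(sol, ref)

    ellipses = {}
    nb = n_boot
    # Hotelling 95% region radius^2 for a bivariate sample of size nb
    r2 = 2.0 * (nb - 1) / (nb - 2) * stats.f.ppf(0.95, 2, nb - 2)
    for i, t in enumerate(taxa):
        cloud = boot[:, i, :]
        center = cloud.mean(axis=0)
        cov = np.cov(cloud.T)
        ellipses[t] = (center, cov, float(r2))

    coords = pd.DataFrame(ref, index=taxa, columns=["dim1", "dim2"])
    return NicheMdsResult(taxa, coords, boot, ellipses, dmat, excluded)


# ---------------------------------------------------------------------------
# Trap-saturation linearity test
# ---------------------------------------------------------------------------

def saturation_test(events: pd.DataFrame, trial_days: float = 6.0,
                    half_days: float = 3.0) -> pd.DataFrame:
    """Test whether previously captured insects depress later captures.

    ``events`` needs columns ``replicate`` (trap-week), ``taxon`` and
    ``day`` (event time in days since the start of that trap-week).  If
    capture is linear in time, each taxon's first-half share
    ``N[0,3d] / N[0,6d]`` should average 1/2 and be independent of the
    trap's total load.  Per taxon, the share is regressed by OLS on the
    total number of insects (all taxa) of that trap-week; reported are the
    intercept with its t-test against 0.5 and the slope with its t-test
    against 0.  Trap-weeks with no captures of a taxon are excluded (count
    reported per taxon as ``n_excluded``).

    Returns a tidy DataFrame indexed by taxon.
    """
    import statsmodels.api as sm

    req = {"replicate", "taxon", "day"}
    if not req.issubset(events.columns):
        raise ValueError(f"events must have columns {sorted(req)}")
    ev = events[events["day"] < trial_days]
    totals = ev.groupby("replicate").size()
    rows = []
    for taxon, grp in ev.groupby("taxon"):
        per_rep = grp.groupby("replicate")["day"]
        n_first = per_rep.apply(lambda d: (d < half_days).sum())
        n_total = per_rep.size()
        keep = n_total > 0
        n_excluded = int((~keep).sum())
        share = (n_first[keep] / n_total[keep]).astype(float)
        if share.size < 3:
            raise ValueError(f"taxon {taxon!r}: need >= 3 trap-weeks, got {share.size}")
        x = totals.reindex(share.index).astype(float)
        X = sm.add_constant(x.to_numpy())
        fit = sm.OLS(share.to_numpy(), X).fit()
        icpt, slope = fit.params
        se_i, se_s = fit.bse
        t_i = (icpt - 0.5) / se_i
        p_i = 2 * stats.t.sf(abs(t_i), fit.df_resid)
        rows.append({
            "taxon": taxon, "n_trap_weeks": int(share.size),
            "n_excluded": n_excluded,
            "intercept": float(icpt), "intercept_se": float(se_i),
            "p_intercept_vs_half": float(p_i),
            "slope": float(slope), "slope_se": float(se_s),
            "p_slope": float(fit.pvalues[1]),
        })
    return pd.DataFrame(rows).set_index("taxon")
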