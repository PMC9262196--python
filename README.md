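# chronotrap

**Time-lapse sticky-trap image analysis and insect community chronoecology.**

Camera-equipped sticky traps photograph their adhesive card every ~20
minutes.  Because trapped insects stay put, the *capture rate* — new
insects per unit time — is an observable proxy for the flight activity of
the surrounding population, and a multi-week image series becomes a
chronobiology experiment on a whole insect community.  `chronotrap`
implements the full desk-scale analysis chain for such series, plus a
synthetic trap simulator so that every stage is testable without field
data.

## The pipeline

1. **Detection** (`chronotrap.detection`).  Each frame is zero-padded by
   32 px and segmented on overlapping tiles (e.g. 12 tiles of 1024×1024 px
   in a 4×3 layout for a 2592×1944 px frame, leaving ≥ 500 px overlap).
   A candidate instance *B* is valid iff *J(Aᵢ, B) < 0.5* for every valid
   instance *Aᵢ* from neighbouring tiles (*J* = Jaccard index).  Objects
   smaller than 30 px or wider than 600 px are discarded.  The per-tile
   segmenter is a pluggable contract; the shipped default is a classical
   Otsu-threshold blob segmenter adequate for synthetic scenes.

2. **Matching** (`chronotrap.matching`).  The match score
   *M(m, n) ∈ [0, 1]* between detections in different frames is a small
   fully connected network (layer sizes 5-4-3-1, ReLU, sigmoid output)
   over five features:

   *I = {S(m,n), Q(m,n), d(C(m),C(n)), |log(A_m/A_n)|, log(Δt+1)}*

   where *S* is the appearance similarity of the two masked crops, *Q* the
   "delayed self-similarity" of *m*'s own footprint in the later frame
   (high *Q* ⇒ the insect has not moved), *d* the centroid distance, *A*
   the areas and *Δt* the time gap in hours.

3. **Tracking** (`chronotrap.tracking`).  Detections become vertices of a
   time-directed graph with in/out-degree ≤ 1; three passes — contiguous
   linking (threshold *k* = 0.5), gap bridging (tails to heads, gap < 12 h),
   and merging of *conjoint* tuboids (time-overlapping, no coincident
   frame; mean neighbour-pair score ≥ 0.25) — and components with < 4
   vertices are dropped.  Each remaining component is a **tuboid**: the
   multi-frame record of one trapped insect.

4. **Classification** (`chronotrap.classify`).  Six frames per tuboid (the
   first + 5 random within the first day) are embedded, fused by
   element-wise median, augmented with the object's physical scale, and
   labelled by a flat head (default scheme: 18 classes).

5. **Chronoecology** (`chronotrap.chrono`).  Tuboid start times become
   capture-rate series.  Times of day are mapped to **Warped Zeitgeber
   time**: with day length *d* (day fraction), *W(z) = az* for *z ≤ d* and
   *W(z) = a′z + b′* otherwise, where *a = 1/(2d)*, *a′ = 1/(2(1−d))*,
   *b′ = 1 − a′* — so sunrise ↦ 0 and sunset ↦ ½ day regardless of season.
   On top of this: running-median + uniform low-pass filtering of count
   series (k = 5 each, ≈ 100 min span at 20-min frames), lag-24 h
   autocorrelation rhythmicity with one-sample t-tests, diel profiles per
   WZT-hour bin, diel-window capture fractions against the uniform null
   with bootstrap CIs, temporal-niche MDS with the distance
   *d = √((1 − r)/2)* from the Pearson correlation *r* of hourly profiles
   (500 bootstrap replicates, Procrustes-aligned, 95% bivariate-t
   ellipses), and a trap-saturation linearity test (first-half share
   *N₍₀,₃d₎/N₍₀,₆d₎* regressed on trap load; intercept ½, slope 0 under
   linear capture).

The synthetic generator (`chronotrap.synthetic`) draws per-taxon capture
events from inhomogeneous Poisson processes with diel-modulated intensity
and renders textured elliptical blobs with positional jitter, transient
occlusion and permanent escape, returning ground-truth tracks alongside
the frames.

## Worked example

```python
from chronotrap.pipeline import run_synthetic_experiment

res = run_synthetic_experiment(seed=1)          # one simulated device-week
print(f"insects trapped : {len(res.series.tracks)}")
print(f"tuboids found   : {len(res.tuboids)}")
print(f"tracking purity : {res.tracking_eval.purity:.3f}")
print(f"completeness    : {res.tracking_eval.completeness:.3f}")
print(f"classifier acc  : {res.classifier_accuracy:.3f}")
```

prints, on this seed:

```
insects trapped : 51
tuboids found   : 51
tracking purity : 1.000
completeness    : 1.000
classifier acc  : 1.000
```

i.e. the 51 simulated insects are recovered as exactly 51 single-insect
tracks (no identity mixing, no fragmentation), and every tuboid is
assigned its true taxon.  The per-taxon WZT capture times in
`res.events_wzt_by_taxon` then feed the chronoecology stage, e.g.:

```python
from chronotrap.chrono import window_fraction
day = window_fraction(res.events_wzt_by_taxon["diurnalis"], [(0, 12)])
print(f"daytime fraction {day.observed:.2f} (null {day.null:.2f})")
```

A command-line interface mirrors the stages
(`chronotrap simulate|detect|track|chrono|run`).

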