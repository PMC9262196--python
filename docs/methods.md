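# Methods

This note documents the models, defaults and numerical choices behind
`chronotrap`, and what the synthetic benchmark does and does not show.

## Synthetic trap model

The simulator is the package's testbed: it emulates the *statistical*
structure of a camera sticky trap, not its optics.

**Arrivals.**  Each taxon captures as an inhomogeneous Poisson process
with intensity `base_rate × diel(WZT(t))`.  The diel multiplier is a sum
of wrapped-Gaussian bumps (peak phase in WZT hours, sd in hours, weight)
over a uniform floor, renormalised to mean 1 over the 24 h day so that
`base_rate` is the marginal rate in captures/hour.  One or two bumps
cover unimodal (diurnal/nocturnal/vespertine) and bimodal (crepuscular)
patterns with three parameters per peak.  Sampling is by thinning a
homogeneous process at the diel maximum; fixed seeds give bit-identical
event lists.

**Scene.**  Trapped insects are textured elliptical blobs (aspect 0.4,
per-insect speckle texture held fixed over time) on a light card
(background grey 210, Gaussian pixel noise sd 4).  The default scene is
1280×960 px — roughly a quarter of the reference 2592×1944 px card, with
the same ~15.4 px/mm scale, so a realistic card density of a few dozen
insects per device-week is preserved.  New arrivals are placed uniformly
at random subject to a 12 px clearance from existing insects (an
occupancy bitmap; overcrowding beyond the retry limit raises an error
naming the frame).

**Behaviour.**  Per frame, a trapped insect jitters around its landing
spot (Gaussian sd 1.2 px, clipped at ±5 px), toggles between visible and
occluded states via a two-state Markov chain (P(on) = 0.01,
P(off) = 0.6, i.e. rare occlusions lasting ~1–2 frames), and escapes
permanently with probability 10⁻³ per frame (~10% per device-week).
Field data do not quantify occlusion or escape frequencies; these
defaults are free parameters chosen to exercise gap bridging and track
termination, not calibrated claims.

**Clock.**  All times are UTC epoch seconds; Warped Zeitgeber conversion
happens only in analysis.  The default reference day is equinox-like
(sunrise 06:00, d = 0.5), under which WZT equals ordinary Zeitgeber time
— diel phases in the simulator are therefore unambiguous.

What the simulator deliberately omits: photometric drift, rain/dust
artefacts, partial insects at card edges, decomposition of specimens,
vertebrate predation, and visually similar neighbouring taxa.  Passing
the end-to-end suite therefore demonstrates the *mechanics* of the
pipeline (tiling, dedup, linking, bridging, merging, fusion, statistics)
under controlled noise, and says nothing about field-image segmentation
or real taxonomic discrimination, which require trained deep backends
and annotated data.

## Detection

Tile offsets are evenly spaced (`x_i = round(i(W−T)/(cols−1))`), first
tile at (0,0), last flush with the far edge; for the reference
2592×1944 / 1024 px / 4×3 case this leaves ≥ 500 px overlap so any insect
narrower than ~500 px is complete in at least one tile.  Candidates cut
by an *interior* tile edge are discarded before deduplication — the
overlap guarantees the complete instance appears in another tile, and a
clipped fragment can have Jaccard < 0.5 with its own complete twin.
Deduplication processes tiles row-major (earlier tiles get priority) and
keeps a candidate iff J < 0.5 against every valid instance from
neighbouring (extent-intersecting) tiles; Jaccard is computed on
rasterised masks at native resolution.  Size bounds [30, 600] px are
inclusive on both ends.  Pixel conventions: 0-based, x right / y down,
half-open boxes.

The default segmenter thresholds dark blobs with Otsu, labels connected
components, and splits strongly concave components (solidity < 0.75) by
watershed on the distance transform.  Two guards keep it sane on
object-free tiles: a foreground fraction above 40% (Otsu splitting pure
noise) rejects the tile, and components with contrast < 25 grey levels
against the background median are dropped.  Padding uses the image
median rather than zeros by default: a zero border is indistinguishable
from foreground for an intensity-threshold segmenter, while learned
backends that were trained with zero-padding can request `pad_value=0`
through the same interface.

Detection quality is evaluated by greedy one-to-one IoU matching
(threshold 0.5 — the matching criterion is our choice), with recall
additionally binned by truth area.  The pixel scale is exposed as
`units.PX_PER_MM = 1944/126 ≈ 15.43` rather than hard-coded in any rule.

## Matching

The five match features are computed exactly as defined in the package
README; Δt enters in hours because the bridging gate is expressed in
hours (the unit inside `log(Δt+1)` is otherwise a free choice).  Head
inputs are z-scored with training-set statistics stored on the model.

The default appearance backend is deterministic: masked crops are scaled
to 105×105 px grayscale and compared by normalised cross-correlation
mapped affinely to [0, 1].  Exact zeros in a masked crop mark the
masked-out background and are filled with the in-mask mean before
correlation; without this the shared silhouette dominates the score and
all insect pairs look alike.  Degenerate zero-variance crops compare as
1.0 when identical and 0.5 otherwise.  The embedding contract (unit
vector, default 1024-d) is satisfied by a 32×32 downsample.

The decision head (5-4-3-1, ReLU ×2, sigmoid) is trained with Adam on
binary cross-entropy, with the negative class resampled to 50% per
128-pair batch; the three-phase schedule (similarity-branch pretrain →
head-only → joint fine-tune) is honoured structurally — with the
training-free NCC backend phase 1 is a no-op and phase 3 continues head
training at a 5× lower rate.  A convex logistic-regression head on the
same five features is provided as the default for pipeline runs: at desk
scale it is as accurate and removes optimisation variance.  Trained
weights travel in a JSON model bundle (head weights, backend name,
normalisation constants, schema version).

## Tracking

The per-pair argmax rule can send two earlier instances to one later
instance, violating in-degree ≤ 1; the resolution (not specified by the
rule itself) processes all candidate pairs of a frame transition in
descending score, accepting a pair only when both endpoints are free.
Ties break by smaller centroid distance, then smaller vertex id, making
the partition deterministic.  The test-suite checks this greedy
resolution against an independent brute-force reference (lexicographic
optimum over all degree-feasible matchings) on every small fixture
shape.

Gap bridging applies the same 0.5 threshold as linking, restricted to
tail→head pairs with frame gap > 1 and time gap < 12 h, repeatedly
taking the single best admissible pair and re-evaluating.  Conjoint
merging averages the match score over each vertex paired with its
immediate predecessor and successor in the other tuboid (deduplicated,
both directions), merges the best pair at or above 0.25 by re-chaining
the union in time order, and iterates to a fixpoint — merged tuboids are
re-examined, since a single sweep could miss chains created by a merge.
Pruning (< 4 vertices) happens once, after all passes.

Candidate pairs farther than 150 px apart are scored 0 without computing
appearance features: trapped insects move a few pixels between frames,
so the gate only removes hopeless pairs while keeping the score cache
small.

Tracking is scored on synthetic truth by instance-weighted purity
(majority-truth fraction per tuboid) and completeness (largest-tuboid
fraction per truth track), with counts of identity switches, splits and
merges.

## Classification

Six frames per tuboid: the first, plus five drawn uniformly without
replacement from the remaining frames within 24 h of the start.  Tuboids
with fewer than five eligible frames (possible, as tuboids only
guarantee ≥ 4 vertices) fall back to sampling with replacement.  The
element-wise median over the six embeddings is robust to one or two
corrupted frames.  The object scale (max bbox side → mm) is appended
once *after* the median rather than to each per-frame vector — for a
scale constant over the tuboid the two placements are mathematically
identical, and post-median is simpler.  The default embedder (radial
intensity profile, intensity histogram, log-scaled Hu moments; 39-d) is
training-free; a deep backbone attaches through the same
`embed(crop) → vector` contract with 224×224 pad-and-rescale inputs.
The default label scheme has 18 flat classes including "Background
objects" and "Undefined insects"; merging those two pools their
probabilities onto 17 classes without renormalisation error.

## Chronoecology

**WZT.**  The map is continuous at the sunset knot (`W(d) = ½` from both
branches), strictly increasing, and bijective on [0, 1); the inverse is
provided and round-trips to 1e-9.  The orientation (0 = sunrise,
½ day = sunset) follows the formal definition; window definitions for
dawn/dusk analyses are explicit configuration, not constants.  Sunrise
and day length come either from a user table or from the closed-form
NOAA sunrise equation (declination + hour angle + 3-term equation of
time), accurate to a few minutes — ample for hour-binned data.

**Filtering.**  Median then uniform filters use centred windows that
shrink at the edges (`min_periods=1`), so a unit step in counts yields a
rate pulse integrating to exactly one insect.  Series shorter than the
window are passed through with a warning flag rather than filtered.

**Rhythmicity.**  The ACF at lag L is the Pearson correlation of the
rate series with its lagged self over the overlapping span, no tapering;
L is the bin count closest to 24 h (24 bins at 1 h bins for field data;
72 at 20-min frames for lab-style series).  The group test is a
two-sided one-sample t-test of per-replicate ACF values against zero —
two-sided as the conservative default.  On white noise the test's
empirical type-I error is checked to be ≈ 5% (1,000 simulations).

**Niche MDS.**  The distance from the Pearson correlation of hourly
profiles is `d = √((1 − r)/2)`, which maps r ∈ [−1, 1] onto [0, 1] and
is a proper metric (it is the Euclidean distance between the
standardised profiles up to a constant); a `distance="linear"` switch
gives `(1 − r)/2` for sensitivity analysis.  Constant profiles have
undefined correlation: the taxon is excluded with a warning.  Embedding
is metric stress-majorisation (SMACOF) in 2-D with fixed-seed restarts;
each of the 500 bootstrap replicates (events resampled with replacement
per taxon) is aligned to the point estimate by orthogonal Procrustes
(translation + rotation/reflection, no scaling) before pooling, since an
MDS solution is only defined up to isometry.  The 95% ellipse per taxon
is the Hotelling region of its bootstrap cloud,
`r² = 2(n−1)/(n−2) · F₀.₉₅(2, n−2)`, i.e. a bivariate-t assumption.

**Window fractions.**  Overlapping or midnight-wrapping windows are
merged first; the uniform null is exactly (merged length)/24 — ½ for the
12 h daytime window, ⅓ for 8 h of dawn+dusk windows.  CIs are percentile
bootstrap over events (default 10,000 replicates).

**Saturation.**  Per taxon, the first-half share N[0,3d]/N[0,6d] of each
trap-week is regressed by OLS on the trap-week's total insect count (all
taxa); reported are the intercept with a t-test against ½ and the slope
with a t-test against 0.  Note the intercept extrapolates to an empty
trap, so its standard error is wide when trap loads cluster far from
zero — the test accounts for this; point recovery is best judged at the
mean load.  Trap-weeks without captures of the taxon are excluded and
counted.

## Problem sizes and determinism

The shipped study conditions are: one device-week at 20-min frames
(505 frames, 1280×960 px, three taxa at ~0.1 captures/hour each → ~50
insects), a 30 h higher-rate training series for the matcher and
classifier heads (held out from evaluation), 1,000 white-noise
simulations for the type-I error check, 500 MDS bootstrap replicates,
and 200–500 OLS simulation runs — sizes at which the whole analysis runs
in minutes on one CPU while every statistical check retains power.  All
randomness flows through `numpy.random.default_rng` seeds; fixed seeds
give bit-identical events, frames, weights and statistics.

## Known limitations

- The classical blob segmenter assumes dark objects on a light card and
  will not segment field imagery; it exists so the pipeline's mechanics
  are testable end-to-end.  Real deployments plug a learned instance
  segmenter into the same per-tile contract.
- The NCC appearance descriptor cannot separate visually identical taxa;
  the matcher then leans on geometry, which suffices for trapped
  (near-stationary) insects but would not for moving ones.
- Tuboid start time is used as the capture time; an insect first
  detected late (e.g. long initial occlusion) biases its capture time
  right by the occlusion length.
- The bivariate-t ellipses summarise bootstrap dispersion, not
  small-sample posterior uncertainty; with < ~50 bootstrap replicates
  they are unstable.
- Period estimation beyond the lag-24 h autocorrelation (e.g. free-run
  period fitting) is out of scope.
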