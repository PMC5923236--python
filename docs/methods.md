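# Methods

## Input model and registration

The pipeline consumes per-window time series sampled along a cell's leading
edge: a velocity map (windows × frames, nm/s) and optional matched
fluorescence maps (arbitrary units). Defaults assume 5 s frames and ~500 nm
probing windows. Edge segmentation and window tracking are upstream of this
package; it starts from the maps.

Missing values (rare segmentation artifacts) are handled per series: a run
of more than 8 consecutive missing frames discards the series, otherwise
each missing value is the mean of up to 4 valid values before and 4 after.

Velocity is integrated to displacement with the cumulative trapezoid rule
and smoothed with a cubic smoothing spline. The smoothing parameter follows
the convention in which p = 1 interpolates and p → 0 approaches the
least-squares line; internally p maps to the penalized-spline weight
λ = (1 − p)/p with the abscissa in seconds (frame index × 5 s). The default
p = 0.01 is deliberately heavy: event detection should see the envelope of
edge motion, not frame-to-frame jitter. Because smoothing-spline parameters
are not comparable across software conventions, p is exposed in the
configuration.

Events are alternating minima/maxima of the smoothed displacement. Two
filters remove insignificant motion, in this order: (1) protrusion/
retraction switches shorter than 50 s are merged into their neighbours
(merging first prevents a long protrusion split by a blip from being
discarded piecewise); (2) events with net distance below 720 nm are dropped.
The distance filter is applied to protrusions and retractions symmetrically.
Events truncated by the end of the recording are kept; only their usable
post-onset length matters downstream.

Registered series are onset-aligned (onset = local displacement minimum,
t = 0 at column 5). The common post-onset length L* maximizes
(number of series with post length ≥ L) × L; with typical movie lengths this
lands near 51 frames, and the canonical analysis window is
5 + 51 = 56 frames. Series missing full pre-onset coverage are dropped when
the fixed-width matrix is assembled.

## Denoising (EMD + DFA)

Registered velocity is denoised in the displacement domain. EMD sifting is
the classic procedure: find extrema, interpolate upper/lower cubic-spline
envelopes, subtract the envelope mean, iterate. Numerical choices:

* envelope splines anchor on up to two extrema mirrored across each end of
  the series (boundary handling is not canonical in EMD; mirroring is the
  common choice and keeps envelopes from diverging at the ends);
* sifting of one IMF stops when the envelope-mean amplitude falls below
  1e−8 × input range or after 12 iterations (a small fixed cap as in
  standard implementations — completeness is unaffected because each IMF is
  an exact subtraction, so Σ IMFs + residue reconstructs the input to
  machine precision by construction);
* IMF extraction stops when the residue has fewer than 2 interior extrema;
  a monotone input yields zero IMFs.

Each IMF is scored with first-order DFA: the cumulative profile is split
into non-overlapping windows of ~10 log-spaced sizes between 4 and len/4,
each window is linearly detrended, and α is the slope of log RMS fluctuation
vs log window size. White noise gives α ≈ 0.5, integrated noise α ≈ 1.5.
IMFs with α below 0.33 are removed before reconstruction; the denoised
velocity is the first difference of the rebuilt displacement (length
preserved by repeating the first difference value). The direction of the
α rule is genuinely ambiguous in the source description, so
`keep_rule ∈ {drop-below, drop-above}` is exposed; drop-below is the default
and both directions are exercised in the tests. Degenerate IMFs on which
DFA is undefined (no fluctuation) are treated as trend-like and kept.

## Symbolization and dissimilarity

SAX: a Gaussian is fitted (moment fit) to all values pooled across series
and times; breakpoints sit at the M − 1 equiprobable quantiles (M = 4).
Each series is averaged over N = 16 equal time intervals; since 56 is not
divisible by 16, the piecewise-aggregate averaging weights each frame by its
fractional overlap with the interval, which is exact and deterministic. A
mean exactly on a breakpoint goes to the upper bin (the direction is
arbitrary but must be fixed). The 5 pre-onset frames are part of the
symbolized window.

Dissimilarity is the squared Euclidean distance between sample
autocorrelation vectors of the symbol sequences at lags 1…15 (the maximal
informative lag count for a 16-symbol word). A zero-variance word maps to
the zero ACF vector, so featureless series are mutually identical. d²_ACF
is a squared quantity: symmetry, non-negativity and zero diagonal hold, the
triangle inequality need not.

Ablation distances for benchmarking: plain Euclidean distance on the
(denoised) series, and the SAX lower-bounding distance (MINDIST) with an
8-symbol alphabet, whose cell rule assigns zero to symbols at most one level
apart; MINDIST provably lower-bounds the Euclidean distance.

## Density-peak clustering

ρᵢ is the Gaussian-kernel sum over all other samples with radius dc; δᵢ is
the distance to the nearest sample of strictly higher density (ties broken
by index so the ordering is total), and the global density maximum takes
δ = the largest pairwise distance. Centers are, by default, the top-k
samples by γ = ρ_norm × δ_norm (each min–max normalized; a constant factor
is dropped from γ since it carries no ranking information). Manual center
selection from the ρ–δ decision graph remains available, mirroring the
visual workflow the method was designed around. Non-centers inherit the
label of their nearest denser neighbour, walking down the density ordering.

dc selection. The published radii for the perturbation experiments are
available as presets (0.71 and 0.46, plus 0.61 for the no-SAX ablation), and
a neighbourhood-mass heuristic (`choose_dc`: distance-quantile grid, mean
kernel mass closest to 2% of the other samples) is provided. The pipeline's
default is a quality-driven grid search (`choose_dc_by_quality`): dc
candidates are log-spaced over the scale range of the positive distances —
a geometric grid, because with tight clusters the distance distribution is
lumpy and quantile grids skip exactly the dc band between the within- and
between-cluster scales — and each candidate (jointly with k when k is free)
is scored by the average silhouette of the labeling it induces, on the
metric (square-root) scale of d²_ACF. This is scale-equivariant and
unsupervised, and it operationalizes "search dc for a good density–distance
map" as an explicit criterion.

Cluster count. For a fixed dc, k is scanned (2…10 by default) and chosen by
majority vote of three criteria — minimal Davies–Bouldin (on the ACF
vectors), maximal average silhouette (on the dissimilarity), maximal
Calinski–Harabasz pseudo-F — with the silhouette breaking three-way ties,
since it is computed on the pipeline's native dissimilarity.

Validation views: the ordered dissimilarity map (samples grouped by label
and sorted by dissimilarity to the cluster medoid), classical Torgerson MDS,
t-SNE with the preset parameters (initial dimension 10, perplexity 20 on ACF
vectors; 30 and 50 on denoised velocities for the drug analysis), and
per-sample silhouettes (singleton clusters score 0). Ablation clusterers:
k-means (k = 7 in the published comparison) and Louvain modularity
maximization on an unweighted kNN graph of the dissimilarity; note the
neighbour count acts as the resolution knob and should be a sizable fraction
of the expected cluster size, as in the published runs (80–350 neighbours).

## Association analyses

Fluorescence is min–max scaled per window (× 1000) over the window's full
pre-registration trace; constant traces map to zeros and are flagged. (For
per-window Pearson correlations the scaling is a monotone affine map and
changes nothing; it matters wherever series are averaged across windows.)

Time-lag correlation: per window, Pearson r between velocity(t) and
intensity(t + lag) over post-onset frames only, for lags up to ±10 frames;
windows with fewer than 3 paired frames at a lag are masked, not
zero-filled. The mean curve over windows carries a 95% bootstrap CI with
windows (not frames) resampled, respecting within-series dependence.
Per-window maximum correlations are retained and compared between groups
with the two-sample two-tailed Kolmogorov–Smirnov test.

Time-specific correlation: for every pair (t₁, t₂), Pearson r across the
sample population between intensity at t₁ and velocity at t₂; p-values come
from the exact null distribution of r, and Benjamini–Hochberg FDR is applied
over the whole grid as one family (one significance boundary per panel).
An early/late summary correlates per-sample early-interval mean intensity
(frames 5–15, i.e. 0–50 s) with late-interval mean velocity (frames 35–55,
150–250 s) per cluster with a bootstrap CI; the interval bounds are
configuration, not results.

## Classification

Intensity series are z-scored per window (population sd; constant series
excluded with a warning). The majority class is randomly undersampled to
the minority size 10 times; each balanced set is split 67/33 per class and
reshuffled 10 times, giving 100 folds. Classifiers: random forest (100
trees), RBF-kernel SVM, and a small fully connected network (two hidden
layers of 64, early stopping) — the network architecture is this package's
default since no canonical one exists for the task. Accuracy and the
Matthews correlation coefficient are recorded per fold; MCC is 0 by
convention when its denominator vanishes.

## Perturbation statistics

Control and treated registered sets are pooled and clustered once, so both
conditions share cluster boundaries; labels are split back afterwards.

The proportion test resamples cells (not windows) with replacement within
each condition, B = 10,000 times by default; each replicate yields pooled
per-cluster proportions, CIs are the 2.5/97.5% replicate quantiles, and the
one-tailed p is the fraction of replicates contradicting the tested
direction, floored at 1/B. The tested tail is configurable: "greater" and
"less" are genuinely one-tailed (type-I error α; use these when the drug
effect is hypothesized in advance), while "observed" — picking the tail
from the observed difference — is the default for exploratory use but
doubles the effective level (it is exactly a two-sided test at 2α), which
its docstring states.

Drug-susceptible sub-clusters: Louvain communities on the kNN graph of the
denoised velocities of the target cluster are merged into exactly two groups
by the optimal 1-D two-partition (size-weighted SSE) of the community mean
velocities; sub-group 2 always has the higher mean velocity. An optional
sample mask can impose an embedding-region constraint; by default the split
is purely automatic, since hand-drawn region boundaries cannot be
reconstructed objectively.

Cross-condition Arp2/3 comparison uses the lamella normalization
I_norm = (I − I_b)/(I_la − I_b) from per-cell lamella and background means.

Spatial co-occurrence: per iteration (500 by default), 8 movies and 40
frames per movie are sampled; for each window gap k, same-frame window pairs
k apart accumulate a 5 × 5 occurrence matrix symmetrically (no direction
along the edge, no wraparound), normalized per conditioning cluster to
p_k(clᵢ | clⱼ), with means and 95% CIs over iterations.

## Synthetic data: what it emulates and what it does not

The generator provides the study conditions for every test. Five phenotype
templates over 56 frames (onset at frame 5, pre-onset frames drawn slightly
negative as a retraction tail, −5…−1 nm/s):

* fluctuating — 20 nm/s plateau; its within-phenotype variability is an
  AR(1) wobble whose innovation sd equals the noise level and whose memory
  is deliberately short (φ = 0.3, ~5 s correlation): the phenotype
  fluctuates on the fastest observable timescale, keeping its temporal
  signature distinct from the slow ramp and periodic shapes (a long-memory
  wobble would intermittently masquerade as those phenotypes);
* periodic-k (k = 1, 2, 3) — raised-cosine trains peaking at 40 nm/s;
* accelerating — linear ramp 5 → 60 nm/s.

White Gaussian noise (sd in nm/s) is added to the non-fluctuating
templates; noise fractions quoted in tests are relative to the 40 nm/s peak
amplitude. At zero noise every sample equals its template exactly, and all
generators are bit-reproducible under their seed.

Intensity channels follow I(t) = gain · sign · V(t − lag) + drift · t +
noise with edge padding — a linear coupling, adequate for testing lag and
sign recovery but not saturation or nonlinear recruitment kinetics. Raw
window maps compose raised-cosine displacement ramps per event over a slow
baseline retraction, for exercising the event filters; per-cell cluster
counts are multinomial draws.

Passing tests on these data show the machinery is correct and calibrated
under known ground truth; they do not certify performance on real movies,
whose phenotype geometry, noise structure (non-Gaussian, spatially
correlated) and cluster proportions are unknown here. In particular, the
published cluster proportions and drug p-values derive from unreleased
recordings and are not reproduced.

## Problem sizes used in the checks

The test suite and acceptance script use 100 series per phenotype for
recovery (500 total), 60 per class for the phase-randomized ablation, 100
generator seeds for lag recovery, 100 replicates of 60-sample null grids
for FDR, 200 replicates at 20 cells × 100 windows with B = 2000 for the
proportion-test calibration and power, 1000 random 56-frame series for EMD
completeness, and 100 series per phenotype for classification — sizes at
which every Monte-Carlo margin is comfortable on a single CPU.

## Known limitations

* The dc quality search optimizes average silhouette; a pathological
  dissimilarity landscape could favour a coarser k than the generative one.
* The data-driven ("observed") tail of the proportion test is exploratory,
  not confirmatory; its doubled level is documented rather than corrected.
* EMD has no ensemble variant here; mode mixing on strongly intermittent
  signals is possible.
* Louvain community detection depends on the neighbour count; no automatic
  resolution selection is attempted.
* The classifiers use default-scale hyperparameters; no grid search is run
  by default.
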