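# Methods

This note documents the models and procedures implemented in `fractopath`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the known limitations.

## Binarization

Measures operate on binary masks (foreground = nuclei = white, following the
0/255 convention of thresholded histology masks). Automatic thresholding
maximizes the sum of the Renyi entropies of the background (bins `0..t`) and
foreground (bins `t+1..255`) of the normalized gray histogram. Three entropy
orders are evaluated — α = 0.5, 1 (the Shannon limit) and 2 — and the three
maximizing thresholds are blended by the published weighting rule: weights
depend on whether the candidates fall within 5 gray levels of each other,
and on the probability mass ω between the outer two. The criterion is a
function of the histogram only, so the threshold is invariant under
transposition and rotation, and an exhaustive 256-candidate scan is exact
(there is no approximation). Binarization uses a strictly-greater-than
comparison everywhere; a constant image has no threshold and raises
`DegenerateInputError`. Color inputs are collapsed by ITU-R 601 luminance.

## Global Renyi dimensions

Box counts use a fixed grid anchored at the image origin, with edge cells
clipped. The default scale schedule is powers of 2 from 2 px to
`min(height, width)/4`, which keeps at least four scales on images a few
hundred pixels per side while avoiding saturated large boxes. D0 is the OLS
slope of log N(ε) on log (1/ε); D1 the slope of the occupancy entropy
−Σ p ln p (p = box mass / foreground count) on log (1/ε); D2 the slope of
log C(ε) on log ε with C(ε) = 2 g_ε / (M(M−1)) and g_ε the number of pixel
pairs at Euclidean distance strictly below ε (0-based pixel centers). When
the pair budget (default 2·10⁶) is exceeded, a seeded uniform subsample of
pixels is enumerated instead; on 64×64 fixtures the subsampled estimate
agrees with the all-pairs value within 0.05.

Grid placement sensitivity can be probed with an optional multi-offset mode
(minimum N(ε) over four shifted origins); it is off by default so results
are a deterministic function of the mask. A plateau-detection helper
(`best_fit_range`) reports the contiguous scale window maximizing the fit's
r², mirroring the practice of fitting inside the scaling plateau. Absolute
third-decimal agreement with values produced by other box-counting software
on the same image is not claimed: fit windows and grid conventions differ
between implementations.

## Local dimensions

For every foreground pixel, N(s) is counted over centered windows of odd
side s ∈ {3, 5, 9, 17, 33} (geometric growth, five fit points) and the LFD
is the OLS slope of log N(s) on log s. The LCFD restricts the count to the
8-connected component of the seed pixel within each window; connectivity is
recomputed per window because a component may leave and re-enter a smaller
window. Windows are clipped at the border; pixels whose largest window loses
more than half its area are excluded (clipping biases slopes low), and LCFD
seeds additionally need their full 8-neighborhood inside the image. The
per-pixel labeling is O(s²) per scale, so dense images are subsampled to a
seeded pixel budget (default 5000 for the LCFD) and the map is flagged
`sampled`. Summaries use the population SD (denominator n) and CV = SD/mean.

## Entropy and lacunarity

Shannon entropy pools the absolute differences of all horizontally and
vertically adjacent pixel pairs into one empirical symbol distribution and
reports its base-2 entropy. On binary images the alphabet is {0, 1}, so
H ≤ 1 bit; an all-background image (and any single-symbol image, such as a
checkerboard) has H = 0 exactly. The adjacency convention (4-neighbor pairs
pooled) is one of several defensible readings of "adjacent pixels"; it keeps
the binary entropy range consistent with reported per-class means
(0.56–0.95 bits) but per-case numeric identity with other conventions is not
expected. The entropy-versus-scale series fits the box-occupancy entropy
H(ε) as a linear function of log₂ ε; the negated slope is an alternative D1
estimator and cross-validates the direct one within 0.02 on monofractal
fixtures.

Lacunarity at box size r is λ(r) = (σ/μ)² over the box-mass distribution,
empty boxes included. The default sampling is the gliding box (stride 1,
overlapping boxes); a fixed non-overlapping grid (complete tiles only) is
kept for oracle tests, and the two agree exactly on patterns periodic with
period r. The per-image λ is the unweighted mean of λ(r) over the scanned
r values (powers of 2 up to `min(dim)/4`). Absolute λ depends strongly on
the r schedule; the contract is relative ordering across images measured
with the same schedule, not absolute identity with other tools.

## Stratification

The ROC between two score groups uses the pairwise-comparison AUC with ties
counted ½ (identical to the trapezoid area under the empirical curve), a
rank-sum normal-approximation p-value for reporting, and a Youden-index
optimal cut-off evaluated at midpoints between adjacent unique scores, with
ties resolved to the median tied midpoint — so a perfectly separating
cut-off lands mid-gap and is deterministic.

Re-stratification starts from ordered initial labels and iterates: compute
the adjacent-pair Youden cut-offs, move every case whose value falls outside
its class's cut-off interval one class toward the violated side, recompute.
At the fixed point classes are disjoint intervals, so every adjacent-class
AUC, sensitivity and specificity equal 1.0 exactly; re-application is a
no-op, and classifying each value against the final boundaries reproduces
the assignments. Because moves are symmetric single steps, a stray class is
absorbed by its neighbors rather than emptied; collapse handling (dropping
an emptied class and shrinking the boundary list) is retained defensively.
Values equal to a cut-off belong to the lower class. The six published D0
cut-offs ship as a fixed boundary set (`paper_boundaries()`), so cases can
be classified without re-estimation.

The aggressiveness tiers are strict conjunctions: low requires D0 < 1.5820,
LFD < 1.3, LCFD > 1.5, H < 0.7 and λ > 0.8; high requires D0 > 1.6980,
LFD > 1.7644, LCFD > 1.7051, H > 0.9 and λ < 0.7; every other combination
is intermediate.

## Clustering

Features are z-scored per dimension before any distance computation (the
dimensions live near 1.5–1.8 while entropy spans 0.5–1.0). k-means uses 25
randomized restarts (k-means++ initialization, best within-cluster sum of
squares wins) and relabels clusters by ascending centroid value on the first
feature dimension for stable reporting. The cluster count is chosen by
10-fold cross-validation: for each k, held-out points are scored by their
distance to the nearest trained centroid. Raw relative improvements of that
score cannot distinguish real cluster structure from the geometric gain of
adding centroids — splitting even a single Gaussian blob improves the score
by roughly 20% — so each improvement is corrected by the improvement the
identical procedure achieves on a seeded uniform reference sample over the
z-scored bounding box (the gap-statistic idea). The scan stops at the first
k whose corrected improvement falls below 5% and returns k−1. This recovers
k = 1 on a single blob, k = 3 on three separated blobs, and k = 3 on the
default synthetic cohort clustered on all five measures — the three
aggressiveness strata.

A strict *reduction* of the cluster count when going from (D0, LFD) to all
five measures is **not** reproduced on the synthetic cohort, and the
corresponding acceptance test is left failing by design. The cohort's
per-class D0 distributions abut exactly at the cut-offs (adjacent-class
AUC = 1.0 is a property of the interval definition, not of separation), so
along D0 the cases form a gap-free continuum: the two-measure data contains
no multi-cluster structure that an overfitting-robust selector can report,
and the corrected improvements support k = 1 there. Per-dimension one-way
ANOVA F values are computed directly (between-group over within-group mean
square), with F = 0 for a dimension identical across clusters and +inf for
perfect separation with zero within-group variance.

## Relations

`fit_linear` is ordinary least squares with Pearson r; a constant response
is fitted as a flat line with r = 0 by convention, and a constant predictor
is degenerate. The tri-linear λ(H) fit uses fixed breakpoints at H = 0.7 and
H = 0.9 (not estimated): boundary points go to the lower and upper segments
respectively, the middle interval is open, segments are fitted
independently, and a segment with fewer than two distinct H values is
flagged empty rather than extrapolated. The multifractal check reports the
margins (D0 − D1, D1 − D2) and passes when both exceed −tol, so monofractal
estimates pass at a small positive tolerance (0.03 covers estimator noise on
the fixtures used).

## Synthetic data

The generators define the conditions under which the pipeline is validated.

* **Analytic fractals.** The depth-d Sierpinski carpet has exactly 8^d
  foreground cells and D0 = log 8 / log 3 ≈ 1.8928; box counts at ε = 3^k
  reproduce 8^(d−k) exactly. The percolation fractal (b×b recursive
  subdivision, retention probability p) has expected dimension
  log(b²p)/log b; the estimate on b = 3, p = 0.9, 5 levels is within 0.1 of
  log 8.1 / log 3 averaged over 20 seeds. The multiplicative cascade splits
  mass 4-ways with weights (0.4, 0.3, 0.2, 0.1) randomly permuted per parent
  and samples 8000 pixels from the resulting measure on a 256² grid
  (analytic D0 = 2, D1 ≈ 1.846, D2 ≈ 1.737); the sampled raster reproduces
  D0 ≥ D1 ≥ D2 when scanned at scales above the mean inter-point spacing
  (ε ≥ 8), because finite sampling biases D0/D1 down and D2 up below it.
* **Tissue patterns.** The gland pattern places 12 non-overlapping rings of
  3-px nucleus dots (radius 28 px, jittered) on a 648×432 canvas — sparse,
  gland-like, ~3% nuclear coverage; the infiltrate pattern scatters 4000
  dots uniformly (~34% coverage), emulating high-grade images in which
  cells fill the available tissue space, with optional clumping and an
  optional foreground target for equal-density pairing. Under these
  defaults D0, mean LFD (gland < infiltrate) and λ (gland > infiltrate) are
  ordered consistently across seeds. At *equal* foreground density the λ
  ordering persists but the D0/LFD orderings do not: with the same mass,
  both morphologies pin the box counts at both ends of the scale scan and
  the slope difference vanishes — in real cohorts the dimension contrast
  between growth patterns is carried by cellularity differences, which the
  defaults emulate deliberately.
* **Cohorts.** Per-class D0 is drawn from a truncated normal confined to
  the class's cut-off interval (reference per-class means and SDs
  pre-truncation), making class membership exact by construction; D1 tracks
  D0 with 0.005 SD noise (corr ≥ 0.95); λ and H are generated from the
  linear couplings on D0/D1 with noise SDs 0.02 and 0.025, which lands the
  cohort-level |r| near 0.90–0.95; LFD/CV-LFD/LCFD/CV-LCFD/D2 are plain
  normal draws from the class statistics. Default class sizes total 208
  cases. The cohort emulates the *feature-space geometry* of a graded
  cohort, not image-level measurement error: features are drawn from the
  class model rather than measured from generated images, so cohort-level
  tests validate the stratification/clustering/relations stages, not the
  estimators (those are validated on the analytic fixtures).

All generators are bit-for-bit reproducible from their seed; every
stochastic call requires one.

## Numerical conventions

Dimension fits report slope, stderr and r²; a constant response (e.g. a
single pixel at all scales) is fitted as a flat line with slope 0 and r²
defined as 1. Scales with zero pair counts are dropped from the D2 fit;
fewer than three usable scales raise `InsufficientScalesError`. Lacunarity
scales whose complete-tile grid misses all foreground are NaN and excluded
from the per-image mean. Natural logs are used for dimension fits (slopes
are base-invariant); entropies are base-2 and reported in bits.

## Limitations

* Nuclei segmentation from stained color histology is out of scope; inputs
  are grayscale or pre-binarized masks.
* Absolute agreement with per-case values produced by other fractal-analysis
  software is not claimed — scale schedules, fit windows, window schedules,
  border rules and λ normalizations differ between tools. Analytic fixtures
  and orderings are the verifiable contract.
* The full multifractal spectrum (generalized Dq beyond q ∈ {0, 1, 2},
  f(α)) and rotation-sweep or gray-level lacunarity are not implemented.
* Survival, PSA and staging integration are out of scope; the aggressiveness
  tiers are geometric criteria only.
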