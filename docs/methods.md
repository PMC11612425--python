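# Methods

## Scope and model

`spatialhet` quantifies how mixed the cell types of a tissue sample are, at
sample scale and around individual cells, from segmented multiplexed images.
The pipeline has four stages:

1. **Abundance quantification.** Each protein channel is binarized against
   its local Gaussian-weighted mean (adaptive thresholding), and the
   abundance `A(c, p)` of protein `p` in cell `c` is the fraction of positive
   pixels inside the cell's segment.
2. **Cell typing.** Cell types are assigned iteratively: candidate
   (type, marker gene) pairs are ranked by a reference-derived spread score,
   a two-component Gaussian mixture decides whether a marker's abundance
   distribution is usably bimodal, and cells above `mu1 - 1.96*sigma1` of the
   upper component receive the type.
3. **Spatial graphs and scores.** Cell centroids of one sample are joined by
   the edges of their Delaunay triangulation; five scores are computed:
   global/local normalized Shannon entropy of type fractions, global/local
   homophily (monochromatic edge fraction), and egophily (own-type fraction
   of the r-hop neighborhood).
4. **Cohort statistics.** Score distributions are compared between
   conditions with two-sided Mann-Whitney U tests, Bonferroni-corrected
   within score families, plus permutation and subsampling robustness tests.

## Graph construction

Delaunay triangulation is used because it is parameter-free and always yields
a connected graph on >= 3 non-collinear points, so hop distance is
well-defined everywhere. No edge-length pruning is applied. Duplicate
centroid coordinates are rejected rather than merged, since they indicate an
upstream segmentation failure. For cocircular quadruples (e.g. the corners of
a square) any valid triangulation is accepted; the scores are insensitive to
the flipped diagonal, and oracle tests compare triangulations only up to
valid diagonal choices. Coordinates follow array indexing: `x` = column,
`y` = row, 0-based, pixel centers.

## Scores: conventions and numerics

* Entropies are normalized by `log |T|` where `T` is the **cohort-wide** type
  universe (all labels observed across samples, including "unknown"), fixed
  before scoring and recorded in the output metadata. A per-sample universe
  would make scores incomparable across samples. The universe is overridable.
* `0 * log 0 := 0`; with `|T| = 1` both entropies are defined as 0 (no
  heterogeneity is representable). The log base cancels in the
  normalization; natural log is used.
* Local homophily divides by the number of induced edges and is therefore a
  *missing value* (not an error) when the r-hop neighborhood induces none —
  possible only in externally supplied non-Delaunay graphs (e.g. isolated
  vertices). Missing values are dropped from downstream statistics with a
  logged count.
* Neighborhoods use unweighted shortest-path (hop) distance, never Euclidean
  distance, and include the center cell, so egophily is strictly positive.
* The vectorized implementation expands bounded reachability matrices by
  sparse boolean matrix products, stopping early once the reachable sets
  converge (radius beyond the graph diameter). Local homophily counts
  induced edges via elementwise products of reachability columns. Runtime at
  fixed radius grows quasi-linearly with cell count (measured log-log slope
  ~1.0 from 1k to 50k cells); memory grows with the number of
  (cell, within-r cell) pairs, so very large radii on very large samples are
  better served by the converged-to-global shortcut, which the code applies
  automatically.

## Adaptive thresholding

A pixel is positive iff its intensity **strictly exceeds** the
Gaussian-weighted mean of its `window x window` neighborhood (default 201,
odd) plus a constant offset, which defaults to the channel's global intensity
standard deviation and is recomputed per channel. Borders use symmetric
(reflected) padding. A constant channel therefore binarizes to all zeros.
The Gaussian bandwidth within the window is not uniquely determined by the
window size; we adopt the common kernel-size convention
`sigma = 0.3*((window-1)*0.5 - 1) + 0.8` and expose it as a parameter,
recording it in the abundance metadata. Because the offset rescales with the
channel, binarization is invariant to linear intensity rescaling when the
default offset is used.

## Membrane completion

When a nucleus has no detected membrane, its cell is reconstructed as a disc:
the ratio rho of cell to nucleus radius is the mean, over matched
nucleus-cell pairs, of their **equivalent-area radii** `sqrt(area/pi)` (the
only deterministic, scale-correct notion of "radius" for irregular pixel
regions); each orphan nucleus gets a disc of radius `rho * r_nucleus` around
its centroid. Pixels already claimed by detected cells are never overwritten;
pixels contested by two discs go to the nearer nucleus **centroid** (chosen
over nearest boundary for determinism and simplicity), with exact ties
resolved toward the lower nucleus label and logged. A nucleus overlapping
two detected cells is an error, as is a mask with no matched pair (rho would
be undefined).

## Cell typing

Reference expression is aggregated from cluster level to type level by a
cluster-size weighted mean. Spread scores are recomputed every iteration
because the remaining-type set shrinks; candidate ties are broken by a stable
sort on (type, gene) names. Mixture fits use two 1-D Gaussian components,
10 restarts, and a seed threaded from the caller, with components ordered by
mean; a fit whose component standard deviation collapses below 1e-6 is
treated as not bimodal. The 1.96 separation multiplier is exposed as a
parameter. Gene matching is exact and case-insensitive, optionally routed
through a user-supplied protein-to-gene synonym map; unmatched proteins are
dropped with a warning. The loop stops when no cells or types remain, when
no gene is usably bimodal, or when a single type remains (the spread score
needs at least two); survivors are labeled "unknown". Cells are processed in
canonical sorted order, so input row order cannot change the result. Note
that the assignment gate `A > mu1 - 1.96*sigma1` structurally leaves the
lower ~2.5% tail of a Gaussian-shaped upper mode unassigned; populations
whose positive fraction has bounded spread (see the generator below) are
recovered completely.

## Cohort statistics

The Mann-Whitney U test uses the exact null distribution for small untied
inputs (`n1*n2 <= 400`, no ties) and the tie-corrected normal approximation
otherwise. Bonferroni families follow the analysis layout: one family for
global scores (size = number of condition pairs) and one for local scores
(size = condition pairs x cell types x radii).

**Pooling caveat.** The default local-score test pools cells across samples
within a condition, mirroring the original cohort figures. Local scores of
cells in one sample are strongly positively correlated (their r-hop
neighborhoods overlap), so pooled observations are pseudo-replicated and the
theoretical MWU null is anti-conservative — the variance of the rank
statistic is understated by roughly the neighborhood size, independent of
cohort size. The package therefore provides:

* `aggregate="median"` in `test_scores`: one median per sample, valid under
  sample exchangeability. This variant is used wherever calibration against
  the theoretical null matters (the detection/null experiments below).
* sample-level permutation and subsampling tests, which preserve
  within-sample correlation and give the pooled statistic an honest
  reference distribution. Robustness outputs report raw p values
  (no Bonferroni), since they are compared against each other.

Permutation shuffles condition labels at sample level, preserving group
sizes. Subsampling draws k samples per condition without replacement
(k lowered to the smallest group with a warning if needed).

## Synthetic data generator

The generator emulates a three-condition skin cohort (default 3 x 20 samples
x 3000 cells; tests use reduced sizes). Centroids sit on a jittered grid
(spacing 14 px, jitter 15%), which keeps rendered discs disjoint. Labels come
from a cluster-center process: each cell adopts its nearest center's type
with probability `exp(-d / (beta * s))` (s = typical center spacing), else a
draw from the global frequencies; `beta = 0` gives fully random labels,
large `beta` near-total segregation. The focal type (default a T-cell-like
population at 15%) is *diffuse*: it never forms background territories.
Lesion-bearing conditions add disc-shaped lesions in which cells become focal
with probability 0.6 and the remaining occupants are uniformly mixed — focal
cells then simultaneously cluster together and sit in mixed surroundings,
which is the tissue signature the local scores target (elevated egophily and
elevated local entropy). The default background is strongly organized
(`beta = 3`) so that the lesion contrast is unambiguous at the sample level.

Channel rendering draws each cell as a disc with a contained nucleus disc;
the cell's own marker channel sets an exact count of disc pixels bright, with
the per-cell positive fraction uniform in `0.9 +- 0.05`. The bounded uniform
mode is deliberate: its 1.96-sigma gate covers the entire mode, so clean
renders are a ground truth for complete recovery, whereas Bernoulli per-pixel
rendering would make recovery structurally incomplete (see the typing note
above). Noise controls add false-positive background pixels, salt-and-pepper
outliers and Gaussian read noise. A configurable fraction of cells is
rendered without a membrane label (exercising completion) or without any
marker (planted "unknown" cells). The reference generator gives every type
1-3 clusters with one exclusive high gene, plus a reference-only type absent
from the tissue, mirroring real references that contain more types than get
assigned. All randomness flows from one master seed via `SeedSequence`
spawning; outputs are byte-identical across runs.

What the generator does **not** emulate: realistic tissue morphology and
cell shapes, spatially varying illumination, marker co-expression and
spillover, segmentation errors other than missing membranes, and patient
nesting (multiple samples per patient). Passing tests therefore demonstrate
correctness of the algorithms and calibration under the stated models, not
performance on real imaging data.

## Validation experiments (sizes and design)

* Score oracle: 100 random labeled graphs (<= 60 vertices, <= 5 types),
  vectorized vs naive per-cell BFS reference, tolerance 1e-12.
* Detection/calibration: two-condition cohorts, 12 samples x 500 cells,
  focal lesions in one condition; per-sample-median MWU on focal local
  entropy and egophily at r = 5 against the family cutoff
  0.05 / (1 pair x 5 types x 1 radius); 100 effect and 100 matched
  lesion-free cohorts. Problem sizes were chosen so one cohort scores in
  under a second while sample medians are stable.
* Robustness: one three-condition cohort (18 samples x 500 cells per
  condition, lesions in one condition), 100 label permutations and 100
  subsampling draws (k = 15).
* Typing recovery: one clean-channel sample of 400 cells with 5% planted
  markerless cells.
* Scaling: samples of 1k-50k cells at r = 5; CPU (process) time, minimum of
  3 measurements per size, log-log slope. CPU time is used because the
  property concerns the computation's cost, not machine load.

## Known limitations

* The pooled local-score test inherits the pseudo-replication caveat above;
  interpret its p values only together with the permutation reference, or
  use the median variant.
* Membrane completion reconstructs orphan cells as discs; abundances of
  completed cells are diluted where the disc misaligns with the true
  membrane, which can push borderline cells below the typing gate.
* Reachability matrices densify for radii near the graph diameter on large
  samples; the converged-matrix shortcut avoids the cost only beyond the
  diameter, not just below it.
* The exact MWU variant is limited to small untied inputs; score data are
  continuous so ties are rare, but heavily discretized scores (tiny
  neighborhoods) fall back to the asymptotic test.
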