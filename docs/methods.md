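# Methods

`cytodx` implements a computer-aided detection pipeline for malignant
cells in Papanicolaou-stained cytological pleural effusion (CPE) images.
The pipeline has seven stages: preprocessing, nuclei segmentation,
morphological refinement, overlapped-nuclei resolution, feature
extraction, feature selection, and classification.  This note records
the models and procedures each stage implements, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic data generator does and does not establish.

## Preprocessing

Images are resampled to a fixed 1024x1024 working resolution (bilinear,
anti-aliased on downscale; aspect is deliberately not preserved so all
downstream scale parameters have a single reference frame).  Each RGB
channel is then linearly stretched between its 1st and 99th intensity
percentiles (saturating the tails) and median-filtered independently
with a 3x3 window — the smallest window that removes impulse noise
without blurring nuclear edges.  The stretch percentiles and window are
configurable; a degenerate (constant) channel passes through unchanged.

## Hybrid SLIC/K-Means segmentation

Rather than clustering ~10^6 pixels, the image is first oversegmented
into ~500 compact SLIC superpixels (clustering in the joint
[l a b x y] space, compactness 10), each summarised by the
componentwise median of its CIELAB colors (D65).  K-Means (k = 2,
k-means++ with 10 restarts, explicit seed) separates the 500 median
colors; the cluster with the lower mean L* — nuclei are the darkest
objects in a Pap-stained smear — becomes the foreground.  The mask is
therefore a union of superpixels and inherits SLIC's boundary
adherence at a small fraction of the pixel-clustering cost.

One library detail matters: the SLIC connectivity cleanup must not
merge superpixels the size of a small nucleus into their neighbours.
We set the minimum superpixel size to a tenth of the nominal cell
(`min_size_factor=0.1`); with the library default (half the nominal
cell) whole small nuclei can disappear into background superpixels.

## Multiscale morphological refinement

False findings (blood cells, debris, noise) are removed by disk
opening, and boundaries smoothed by a paired closing with half the
opening radius.  No single radius suits both a small lymphocyte and a
large tumour nucleus, so the opening radius is chosen per connected
component: the element of {7, ..., 15} px closest to half the
component's equivalent radius sqrt(area/pi), clamped to the range.
Components that vanish at their own radius were false findings by
definition; surviving components below `min_area` (default 50 px) are
dropped.  The per-component radius rule is this package's resolution
of an otherwise underdetermined "process at several scales"
prescription: it is deterministic, local, and ties the scale directly
to the size of the object being tested.

## Overlapped-nuclei identification and splitting

Touching nuclei form a single component after segmentation.  Splitting
every component oversplits lone nuclei, so a gate runs first: an RBF
SVM over five standardized shape features (solidity, eccentricity,
equivalent diameter, major and minor axis length) labels each
component single or overlapped.  The shipped gate is trained on shapes
rendered by the scene generator (lone ellipses vs. fused pairs), which
is the training distribution the synthetic pipeline actually meets;
for real data the gate should be retrained on annotated shapes.

Flagged clumps are split by contour concavity analysis:

1. the closed boundary is traced and smoothed with a periodic Gaussian
   (sigma = 3 boundary samples);
2. concave points are curvature extrema that exceed the 90th
   percentile of the contour's curvature magnitude (with an absolute
   floor of 0.02 px^-1) and whose curvature sign points away from the
   region;
3. the contour is cut at the concave points; segments are greedily
   merged — any pair, not only adjacent segments, since the middle
   nucleus of a chain owns two opposite arcs — whenever the pooled
   direct least-squares ellipse fit has mean residual below 5% of the
   mean semi-axis and axis ratio below 4;
4. one ellipse is fitted per final group, and the clump's pixels are
   partitioned by nearest normalized ellipse distance
   ((u/a)^2 + (v/b)^2 in the ellipse frame), so splitting conserves
   the pixel set exactly.

If fewer than two concave points or no valid grouping exists the whole
contour is fitted as a single ellipse and nothing is split (fail-safe).

## Feature extraction (F1-F201)

Each nucleus yields 201 features: 14 morphometric, 6 colorimetric
(mean R, G, B, H, S, V), 49 first-order statistics (7 statistics x 7
color components R, G, B, H, S, V, gray), 88 GLCM (22 statistics x 4
orientations) and 44 GLRLM (11 x 4).  Conventions:

- all components are expressed on the 0-255 scale (H, S, V rescaled);
  gray is ITU-R 601 luma;
- the perimeter is the chain-code length of the 8-connected boundary
  (axial steps 1, diagonal steps sqrt 2); axis lengths come from the
  image-moments ellipse; eccentricity is sqrt(1-(b/a)^2);
- first-order statistics are computed from a 256-bin histogram of the
  masked pixels (rounded to integer levels); smoothness is
  1 - 1/(1+variance) on the raw 0-255 scale, kurtosis is excess
  (includes the -3 term); for a constant region skewness and kurtosis
  are defined as 0;
- texture matrices quantize gray to 8 uniform levels over [0, 255]
  (fixed bins, so darkness and texture stay coupled across nuclei) and
  use 1-based level indices in every statistic; pairs/runs are counted
  only inside the mask, GLCM accumulation is symmetric, runs truncate
  at the mask boundary; logarithms are natural with 0 log 0 = 0;
- the "sum energy" cooccurrence statistic is computed as the entropy
  of the p_{x+y} distribution — the formula, not the name, is what the
  feature table defines — and the sum-variance statistic is centred on
  that value; the sum-of-square statistic is centred on the matrix
  mean mu_x; degenerate denominators (sigma_x sigma_y = 0, or
  max(HX, HY) = 0 for the information measures) return 0 so every
  vector is finite.

Both texture families are verified against brute-force pair/run
enumeration oracles to 1e-9, and the histogram-route first-order
statistics against closed-form moments to 1e-6.

## SA-ANN feature selection

A simulated-annealing wrapper searches subsets of fixed size `nf`
(default 20).  The cost of a subset is the held-out misclassification
rate of a 3-layer network — `nf` inputs, 10 tanh hidden units
(configurable), one logistic output — trained by L-BFGS (a
quasi-Newton trainer; the selector depends on the cost *ranking*, not
the trainer brand) on a standardized stratified 75/25 split, averaged
over `n_cost_repeats` = 3 restarts.  A restart redraws both the split
and the initial weights; averaging over splits suppresses the
split-specific luck that otherwise lets noise features masquerade as
signal when many subsets are compared.  The annealer proposes a
uniform single swap (one selected feature out, one unselected in),
accepts downhill moves always and uphill moves with probability
exp(-dcost/T), cools geometrically (T <- alpha T), and returns the
best-so-far subset; `moves_per_temp` neighbor evaluations run per
temperature step (default 1, the classic loop).

Temperature must match the cost scale.  The classical setting
temp0 = 10 with alpha = 0.99 presumes a cost counted in misclassified
*samples*; for a cost expressed as a rate in [0, 1] the equivalent
initial temperature is temp0 / n_heldout
(`rate_equivalent_temp0`), and a run of 50 temperature steps only
anneals — moves from exploratory to effectively greedy — if alpha is
chosen so the schedule traverses that range within the run (the
recovery experiments use alpha = 0.9).  With temp0 = 10 on a
rate-scaled cost every uphill move is accepted and the search
degenerates to a random walk.

## ECBDT classification

One hundred unpruned CART trees are each fit on an n-out-of-n
bootstrap resample of the training rows restricted to the selected
features; prediction is majority vote with exact 50/50 ties broken
toward malignant (in a screening context a false alarm is cheaper than
a missed cancer; configurable).  Training reports stratified 5-fold
cross-validation inside the training split; final evaluation uses an
80/20 *image-level* split so no image contributes nuclei to both
sides.  Metrics are sensitivity, specificity, precision,
recall (= sensitivity), F-score and accuracy as percentages; a ratio
with zero denominator is reported as 0 and flagged.

## The synthetic scene generator

Real annotated CPE image sets are scarce, so scenes are rendered:
pale pink-grey background with a mild diagonal illumination gradient;
nuclei as filled ellipses (aspect ratio 0.6-0.95) with multiplicative
low-frequency chromatin texture plus per-pixel Gaussian chromatin
noise; additive Gaussian sensor noise and salt-and-pepper impulses.
Benign nuclei draw equivalent radii from 14-22 px and mean intensity
120; malignant nuclei from 24-38 px (nuclear enlargement), 40 grey
levels darker (hyperchromasia), with stronger chromatin noise (14 vs 6
SD).  A configurable fraction of nuclei is placed in touching pairs
(center distance uniform in [0.7, 1.1] x the summed mean radii,
resampled until the ellipses genuinely share pixels), guaranteeing the
concave neck the splitter needs.  Default scenes are 1024x1024 with 30
nuclei, 20% in pairs, 15% malignant.  Identical spec (including seed)
reproduces a byte-identical scene.

The generator emulates the cues the feature set measures — size,
darkness, shape, chromatin texture, overlap geometry — and none of the
confounds of real smears: no cytoplasm, inflammatory background,
stain batch variation, out-of-focus blur, or irregular (non-elliptical)
nuclear outlines.  Passing tests therefore establish that the
implementation does what the method prescribes under its own
assumptions, not that the method reaches any particular accuracy on
clinical material.

The feature-table generator plants `n_informative` marker columns in a
201-column table.  Each marker carries a class mean shift of
`effect_size` (default 0.6) column SDs, and the markers'
within-class fluctuations share latent factors that cancel only over
the full panel: each marker alone is weak, every strict subset of the
panel leaves roughly 10% residual error, and the complete panel is
cleanly separable.  This complementary design is deliberate — with
independent, equally-shifted markers any 4-of-5 subset plus a lucky
noise column is statistically indistinguishable from the planted
panel (the marginal error reduction of a redundant fifth marker is
bounded near 0.025 regardless of effect size), so planted-panel
recovery would be unidentifiable for any selector.  Complementary
marker panels are also the regime in which wrapper selection earns its
cost over per-feature filters.

## Problem sizes used in the validation suite

Scene-level checks run on 1024x1024 scenes with the default 30 nuclei
(20 scenes for segmentation recovery); splitting accuracy uses 50
rendered two-disk clumps with radii 14-22 px and centers 1.5 r apart;
selector recovery uses a 500-row table, 5 planted markers, nf = 5,
20 annealing runs (60 proposals per temperature step); the ensemble
comparisons use 600-800-row tables at 5-30% prevalence.  The
imbalanced ensemble-vs-tree comparison plants markers at effect 1.5 —
the regime where the features genuinely discriminate; with
near-uninformative features majority voting has no advantage over a
single tree.

## Known limitations

- The multiscale-refinement combination rule and the pixel
  reassignment of split clumps are this package's declared
  interpretations of underdetermined prescriptions; both are
  deterministic and documented above.
- The shape gate ships trained on synthetic shapes; its operating
  point on real smears is untested.
- Concave-point detection assumes a single closed outer boundary per
  component; interior holes are ignored.
- Feature values for very small regions (below ~20 px) are noisy;
  the refinement stage's `min_area` guard is the intended defence.
- The annealing selector's runtime is dominated by network fits
  (milliseconds each); selecting from tables with many thousands of
  rows calls for reducing `moves_per_temp` or `n_cost_repeats`.
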