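# Methods

## Segmentation models

`FuzzyCMeans` implements the classical alternating optimisation of the
fuzzy C-means cost on the flattened in-mask intensities. One iteration is
a membership update followed by a center update; the loop stops when the
largest absolute center shift falls below `tol` (default `1e-4`) or after
`max_iter` (default 300) iterations. With this bookkeeping a very large
tolerance stops after exactly one iteration, which makes the termination
rule testable in isolation. The cost sequence is non-increasing (asserted
in the tests to 1e-9 slack). Voxels that coincide exactly with one or more
centers are singular points of the membership formula; their membership is
split equally over the coinciding centers. Numerically the same rule
absorbs denormal overflow in the inverse-power weights, so the update is
total on all finite inputs. Cluster identity is fixed by sorting centers
ascending on output; defuzzification breaks ties toward the lower cluster
index. Both choices are arbitrary but deterministic.

`IntuitionisticKernelFCM` runs the improved loop on the intuitionistically
fuzzified image. The working signal is the membership image
`b = b0**2` of the min–max-normalised gray level; hesitation
`pi = 2 b0 (1 - b0)` is computed once from the input image and held fixed
across iterations (no update rule for a per-iteration hesitation exists,
and the fixed-point semantics keep the correction idempotent at
convergence). The non-membership `(1 - b0)**2` is the unique quadratic
completion for which the triplet sums to one.

Distances are kernel-induced with a Gaussian kernel,
`d(u, v) = 2 (1 - exp(-(u - v)^2 / delta^2))`, computed through `expm1`:
with the naive `1 - exp(...)` form the reduction to Euclidean FCM at very
wide kernels loses all significant digits (the subtraction cancels at
`(u-v)^2/delta^2 ~ 1e-12`) and memberships drift at the 1e-3 level.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_clusters` | 3 (4 with a tumor class) | tissue classes f |
| `fuzzifier` | 2.0 | membership softness l; the field-standard value |
| `spatial_weight` | 0.5 | theta, weight of the neighbourhood term |
| `kernel_width` | `"auto"` | delta; auto = sample std (ddof=1) of the working intensities |
| `neighborhood_radius` | 1 | p; 3×3 (2-D) or 3×3×3 (3-D) window |
| `tol` | 1e-4 | max-abs membership change (center change for classical FCM) |
| `hesitation_mode` | `per_iteration` | also `final` or `off` |
| `kernel_weighted_centers` | `True` | see below |

The neighbourhood mean excludes the center voxel, mirrors the image at its
borders, drops out-of-mask neighbours from the average, and falls back to
the voxel's own intensity when no in-mask neighbour exists. 3-D volumes
use exactly the same update rules with cubic windows.

### The center update

Two center updates are provided. The *plain* spatial update

    a_x = sum_y b^l (m_y + theta * mbar_y) / ((1 + theta) sum_y b^l)

is the direct weighted mean of the blended signal. On piecewise-constant
images its fixed point is systematically displaced: interface voxels carry
neighbourhood averages that blend two tissues, and when a third class's
intensity lies near that blend value (here the tumor, between CSF and
gray matter) the displaced center captures the whole interface layer — on
the noiseless 64³ phantom this costs ~5 % of voxels. The default is
therefore the *fully kernelised* update, in which each voxel's pull on
center x is additionally weighted by the kernel values K(m_y, a_x) and
K(mbar_y, a_x) evaluated at the previous centers. Far-away blends are then
exponentially down-weighted, centers stay on their plateaus, and the
noiseless phantom is recovered exactly. With a wide kernel the two
variants coincide, so the documented reduction to classical FCM is
unaffected. The plain form remains available
(`kernel_weighted_centers=False`).

### Hesitation correction

Per voxel, non-winning memberships are scaled by the hesitation degree and
the winner absorbs the released mass; column sums return to exactly one
and the argmax is never changed, so the correction sharpens but cannot
re-label. Because the quadratic generator bounds hesitation by 0.5, the
correction is always a contraction toward crispness. It is applied inside
the loop by default (`per_iteration`); `final` applies it once after
convergence, and `off` disables it — the latter is the right setting when
comparing memberships against classical FCM, whose fixed point has no
sharpening step.

## Validity indices

Vpc and Vpe depend only on the membership matrix. The Xie–Beni index is
evaluated **in the intensity domain the model was fitted on, with the
fitted centers**: classical FCM against the gray image, the improved
algorithm against its fuzzified working image. A partition's compactness
is only meaningful relative to the data it explains; mapping the improved
algorithm's centers back to gray through the inverse generator and scoring
them against data they were never fitted to inflates the numerator with a
transformation artefact. Vxb is scale-invariant, which is what makes the
cross-domain comparison of the two fits meaningful at all.

One caveat is documented rather than hidden: classical FCM *directly
minimises* the Vxb numerator on its own data, and the index rewards soft
memberships on ambiguous voxels (a half-half split contributes half as
much as a crisp assignment at equal distance). On piecewise-constant
phantoms the crisper, more accurate improved partition therefore tends to
carry a *larger* Xie–Beni value than a degraded-but-fuzzy FCM partition,
even when the latter has merged two tissues. The acceptance suite keeps
the full directional comparison (higher Vpc, lower Vpe, lower Vxb, higher
accuracy) as a single check and the Vxb leg fails on the synthetic
fixture; the accuracy, Vpc and Vpe legs hold with wide margins.

## Phantom generator

The phantom emulates a skull-stripped T1 spin-echo acquisition: concentric
ellipsoidal shells (outer CSF rim 20 %, gray-matter ribbon 30 %,
white-matter core, 4 % tumor blob carved from the core around an
off-center seed) with class intensities from
`S = beta (1 - exp(-TR/T1)) exp(-TE/T2)` at TR = 1980 ms, TE = 2.28 ms,
1 mm³ voxels. Tissue relaxation times are literature-typical 3 T values
(CSF 4000/2000, GM 1300/110, WM 830/80, tumor 1600/150 ms; unit spin
density). Geometry is assigned by ranking voxels on ellipsoidal radius and
cutting at exact per-tissue counts, so requested voxel counts are honoured
exactly and volumetry has an integer oracle. Noise models: additive
Gaussian (default, analytically convenient), Rician (the physically
correct magnitude-image model), and salt-and-pepper (the classic
robustness stressor for spatial regularisation). Noise is injected inside
the brain mask only and is fully seeded.

What the phantom does **not** emulate: cortical folding, partial-volume
mixing at interfaces, bias fields, and spatially correlated multi-coil
noise. Passing tests therefore demonstrate correctness of the optimisation
and its robustness to independent voxel noise, not performance on real
anatomy.

Problem sizes: module tests run mostly on 32³ phantoms; the
segmentation-recovery and robustness checks use 64³ (≈100 000 brain
voxels), where the tissue shells are several voxels thick. This matters:
with the 3×3×3 spatial window, structures thinner than about two voxels
(the 32³ phantom's CSF rim) are dominated by interface blending and the
improved algorithm loses accuracy there — a real limitation of
neighbourhood-regularised clustering, documented rather than worked
around.

The "standard noisy phantom" used for the robustness comparison adds
Gaussian noise with sigma equal to half the smallest class contrast
(≈ 3.8 % of the white-matter signal, SNR ≈ 26 — a typical clinical level).
At that level classical FCM visibly degrades (≈ 73 % accuracy, merged
tumor/GM centers) while the improved algorithm stays near 87 %. The much
cleaner sigma = 10 % of the smallest contrast is used for the
parameter-recovery check, where both algorithms are expected to succeed.

## Grading statistics

The two-group comparison gates on Shapiro–Wilk normality (alpha = 0.05,
each group): both normal → pooled-variance two-sample t-test; otherwise
Wilcoxon rank-sum. Groups too small or constant for Shapiro–Wilk fall to
the rank-sum branch. The ROC curve is the empirical curve over all
observed thresholds (no interpolation, ties counted half), so the
trapezoidal AUC equals the normalised Mann–Whitney U statistic exactly —
the test suite asserts this identity on randomised inputs. The "optimal
critical value" maximises Youden's J with ties broken toward higher
specificity; the reported cutoff is the smallest score classified
positive. The cohort simulator draws seeded Gaussian groups per parameter;
for a standardised separation d its population AUC is Phi(d/sqrt(2)),
which the Monte-Carlo calibration check reproduces to < 0.02 averaged over
20 cohorts of 500 subjects per group.

## Degenerate inputs and numerical policy

Constant images are rejected before normalisation; images with fewer
distinct in-mask intensities than clusters raise an infeasibility error;
coincident centers and empty (zero-membership) clusters raise degeneracy
errors rather than propagating NaNs. All stochastic entry points take an
integer seed and are bit-reproducible; random initialisation draws a
uniform membership matrix and column-normalises it, with deterministic
quantile-based center initialisation available for demos.

## Known limitations

- Scalar (single-channel) intensities only; no multi-echo or multi-contrast
  joint clustering.
- No bias-field correction or registration; inputs are assumed
  skull-stripped or maskable by threshold + morphology.
- The spatial term trades thin-structure fidelity for noise robustness;
  structures ≲ 2 voxels thick are smoothed into their surroundings.
- The Xie–Beni comparison across algorithms inherits the index's
  preference for soft partitions (see above).
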