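# Methods

## Scope and conventions

`ticcad` analyses one 2-D slice over time: a `(T, H, W)` array with
`T ≥ 4` (one pre-contrast phase plus at least three post-contrast phases)
and strictly increasing acquisition times starting at 0 s. Arrays are
0-based `(row, col)`, row-major; a pixel's center sits at its integer
coordinate. 4-D NIfTI volumes are accepted only with an explicit slice
index — slice selection (conventionally the slice with the largest lesion
cross-section) is an input, not something the tool infers. When no timing
sidecar is present, phases are assumed 80 s apart, the spacing of the
emulated protocol.

## Segmentation

The five-step extraction operates on the subtraction image
`data[k] − data[0]` (signed, no clamping). The default `k = 3` follows the
common practice of reading lesion margins on the third post-contrast
subtraction; it is configurable.

Design choices where the procedure is underdetermined:

* **Foreground side.** Otsu's method only bisects the ROI histogram; the
  above-threshold class is taken as lesion because lesions enhance.
* **Otsu discretization.** 256 equal-width bins over the ROI's observed
  range; the threshold is the interior bin *edge* maximizing between-class
  variance with classes `{≤ t}`/`{> t}`. Since bin centers are affine in
  the bin index, the maximizer is computed with exact integer arithmetic
  over indices (cross-multiplied rational comparison), making tie-breaking
  (smallest edge) deterministic even across long runs of empty bins.
* **Structuring element.** The 4×4 all-ones element is even-sized and has
  no central pixel; its origin is fixed at grid position (1, 1), giving
  offsets {−1, 0, 1, 2}². Erosion requires every translated offset to land
  inside the image on a set pixel (outside-image = background); dilation
  is the Minkowski sum with the *same* offset set, so
  `dilate(erode(X))` is the algebraic opening of `X` — a subset of `X` and
  idempotent — which the test suite asserts on random masks.
* **Component selection.** Largest 8-connected component; exact size ties
  go to the component containing the first set pixel in row-major order,
  which is deterministic and independent of labeling order.
* **Final clipping.** Dilation can leak past the ROI boundary, so the
  result is re-intersected with the ROI to keep the contract
  `lesion ⊆ ROI`.

Degenerate inputs raise typed errors: a constant-intensity ROI cannot be
thresholded, and a foreground that vanishes under erosion (any blob
smaller than the 4×4 element) reports an empty segmentation with the
remediation hint to enlarge the ROI or reduce the element size.

## Kinetic parameters

The early-phase reference `SI_mean` is the mean of post-contrast phases 1
and 2 (80 s and 160 s); `SI_peak` is searched over post-contrast phases
only, the baseline being a reference rather than a candidate peak, with
ties resolved to the earliest phase. MSI includes the pre→first-post step
(`i` from 0) and generalizes to `i = 0…T−2` for other phase counts. ESER
is reported ×100 like the other percentages.

NaN policy: zero or negative baselines make the baseline-relative
percentages undefined (NaN), and `SI₂ = SI₀` makes ESER undefined; such
pixels are excluded from region means *per parameter*, not listwise. Zero
baselines cannot occur inside a properly segmented enhancing lesion, but
the guards keep pixelwise maps total. Values are never rounded internally;
CSV presentation rounds to 2 decimals.

The two quantification pathways are deliberately kept distinct: the
*mean-curve* pathway averages the lesion TICs first and derives parameters
once; the *region-mean* pathway derives parameters per pixel and averages
afterwards. They coincide exactly on homogeneous lesions and differ on
heterogeneous ones (the parameters are nonlinear in the curve), which is
itself diagnostic information.

## ROC evaluation

AUC is the tie-corrected Mann–Whitney concordance probability; its
standard error uses DeLong's structural components
(`var = S₁₀/n₊ + S₀₁/n₋`), with the 95 % CI as ±1.96·SE clipped to [0, 1].
MedCalc-style binomial-exact CIs are not implemented; the CI method is
reported alongside the numbers. The operating point maximizes Youden's
J over all distinct observed scores, with the criterion direction chosen
so the reported AUC is ≥ 0.5 (scores where low values indicate malignancy,
such as the late slope, get a `≤ c` criterion). J ties are broken toward
higher sensitivity, then smaller |c|. Cases with an undefined parameter
are dropped pairwise per parameter and the count is reported.

The categorical rule calls types II and III malignant and type I benign.
The classification bounds default to ±10 % but are configurable
(`--slope-bounds`), and a direct slope-cutoff malignancy rule
(`--slope-cutoff-override`, e.g. 9.7039) can be reported alongside, since
a data-driven cutoff near +9.7 % can outperform the conventional +10 %.

## Phantom

The generator emulates a 1 pre + 8 post, 80 s protocol on a 64×64 slice:
one elliptical lesion (semi-axes drawn 3–12 px, random orientation, ≥4 px
margin), background at baseline 100 rising linearly by 20 % over the
acquisition, lesion baseline 100 with wash-in fraction drawn 0.7–1.3 and
peak at 80 s.

Lesion kinetics are **piecewise linear**, not pharmacokinetic: the typing
rule and all six parameters constrain the curve only at the sample times,
and linear segments make every parameter analytically invertible — the
late segment's slope is solved in closed form so that the sampled curve's
SI_slope equals the requested target exactly, which the tests verify to
machine precision. Per-pixel realism comes from multiplicative jitter
(±5 %) on the lesion curve and additive Gaussian noise (σ = 5 % of
baseline by default); a Rician magnitude-noise option is provided for MRI
realism, Gaussian being the default for analytic tractability. All
randomness flows from one seed; per-case seeds are drawn up front from the
root generator, so cohorts are reproducible case-by-case and σ changes
never move the truth geometry or labels.

Cohort composition defaults: benign cases draw archetypes I/II/III with
probabilities 0.75/0.20/0.05, malignant with 0.15/0.35/0.50 — mass
distributions that put the categorical rule's operating point near the
sensitivity/specificity regime reported for semi-automatic TIC typing in
clinical cohorts. Within each archetype the late-slope target is drawn
from a class-conditional band (e.g. benign type I 20–45 %, malignant
type I 10–25 %; malignant type III −45 to −15 %, benign type III −20 to
−10 %): malignant lesions wash out faster than benign lesions *of the same
curve type*. This mirrors the clinical observation that the continuous
slope carries discriminative information beyond the coarse three-way
label; with slope distributions depending on the archetype alone, the
slope's AUC could never exceed the archetype concordance (≈0.84 under the
default mixes).

What the phantom does **not** emulate: 3-D partial-volume effects, motion,
coil/bias fields, rim enhancement, necrotic cores, non-mass-like lesions,
or T1 saturation. Passing recovery tests therefore demonstrates internal
consistency of the chain on idealized mass-like lesions, not clinical
performance.

## Problem sizes and numerical choices

The bundled recovery experiment uses a 30+30 cohort at 64×64 resolution
(seed 42, σ = 0.05), a size at which segmentation Dice, slope AUC and rule
accuracy are stable enough to assert bounds while the whole chain runs in
seconds. Noise-free self-consistency (every generated archetype
re-classifies to itself through segmentation and quantification) is
checked on 8+8 cases. The end-to-end pipeline is byte-deterministic for a
fixed config and seed, including CSV output.

## Known limitations

* Single-slice, single-lesion analysis only; no registration or motion
  correction.
* The DeLong SE assumes independent cases; clustered or paired designs
  need resampling instead.
* The Youden-optimal cutoff is an in-sample estimate and optimistic on
  small cohorts; no cross-validation is built in.
* Clinical AUC/accuracy values from patient cohorts cannot be reproduced
  by the phantom and are out of scope.
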