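# ticcad

Semi-automatic, quantitative analysis of time–intensity curves (TICs) from
breast dynamic contrast-enhanced MRI (DCE-MRI), for researchers evaluating
kinetic-curve criteria that discriminate invasive ductal carcinomas from
benign mass-like lesions.

Subjective reading of breast TICs (persistent / plateau / washout by eye)
has high sensitivity but poor specificity. `ticcad` implements the
alternative: the lesion is extracted semi-automatically inside a
user-drawn ROI, the curve type is assigned by a numeric rule, and a panel
of semi-quantitative kinetic parameters is evaluated by ROC analysis.

## Method

**Segmentation.** On the subtraction image (post-contrast phase *k* minus
pre-contrast, default *k* = 3), the ROI pixels are split by Otsu's
threshold; the above-threshold foreground is eroded with a 4×4 all-ones
structuring element, reduced to its largest 8-connected component, dilated
with the same element (a morphological opening of the selected component),
and clipped to the ROI.

**Kinetics.** With SI₀ the pre-contrast intensity, SIᵢ the *i*-th
post-contrast phase, SI_mean = (SI₁+SI₂)/2, SI_tail the last phase and
SI_peak the post-contrast maximum:

| parameter | definition |
|---|---|
| SI_slope | 100 · (SI_tail − SI_mean)/SI_mean |
| MSI | maxᵢ (SIᵢ₊₁ − SIᵢ), i = 0 … T−2 |
| E_initial | 100 · (SI₁ − SI₀)/SI₀ |
| E_peak | 100 · (SI_peak − SI₀)/SI₀ |
| ESER | 100 · (SI₁ − SI₀)/(SI₂ − SI₀) |
| SEP | 100 · (SI₂ − SI₀)/SI₀ |

The curve is type I (persistent) when SI_slope ≥ +10 %, type III (washout)
when SI_slope ≤ −10 %, type II (plateau) in between. Parameters are
computed both from the lesion's mean curve and pixel-by-pixel (parametric
maps with region means) — the two pathways agree only on homogeneous
lesions. Types II/III are called malignant, type I benign.

**Evaluation.** Per-parameter ROC analysis: Mann–Whitney AUC with the
DeLong standard error, and the operating point maximizing Youden's J over
observed scores, with the criterion direction (`> c` vs `≤ c`) chosen from
the data.

**Phantom.** A seeded generator emulates the acquisition (1 pre- + 8
post-contrast phases, 80 s apart, single slice): elliptical mass-like
lesions with piecewise-linear type I/II/III kinetics whose sampled late
slope hits a prescribed target exactly, on a mildly enhancing background,
with Gaussian or Rician noise.

## Worked example

```sh
ticcad simulate --n-benign 1 --n-malignant 1 --seed 7 --out demo
ticcad segment  --series demo/case0001.nii.gz --roi demo/case0001_roi.json \
                --out demo/lesion.nii.gz
ticcad quantify --series demo/case0001.nii.gz --mask demo/lesion.nii.gz \
                --out demo/params.csv
```

The segmentation log shows each stage's pixel count
(`threshold=26.57, foreground=342 px` → `after erosion 225 px` →
`largest component 225 px` → `final lesion 339 px`) and `params.csv`
holds both pathways:

```
pathway,si_slope,msi,e_initial,e_peak,eser,sep,tic_type
mean_curve,3.4,70.0,69.95,76.32,98.36,71.12,II
region_mean,3.45,70.0,70.37,81.47,98.75,71.54,II
```

Here the mean curve rose ~70 % after the first phase and stayed flat
(late slope +3.4 %, inside ±10 %), so the case is typed II — plateau,
called malignant under the type rule.

A full cohort experiment chains everything:

```sh
ticcad run --simulate 30 30 --seed 42 --out demo/run
```

writing `cohort.csv` (60 cases × 2 pathways), one `roc_<param>.csv` per
parameter and a `summary.txt` whose mean-curve block reads:

```
param         AUC      SE           95% CI     criterion   sens%   spec%    acc%
si_slope    0.949  0.0263    (0.897,1.000)       <= 22.5   96.67   83.33   90.00
msi         0.547  0.0759    (0.398,0.696)       > 113.4   30.00   86.67   58.33
...
mean_curve   sensitivity 90.00%  specificity 86.67%  accuracy 88.33%
mean segmentation Dice vs truth: 0.9873
```

i.e. on this phantom cohort the late slope is the strongest discriminator
(AUC 0.949 with a "≤ cutoff" criterion — washout scores low), the
type-rule accuracy is 88 %, and segmentation recovers the truth masks
with mean Dice 0.987.

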