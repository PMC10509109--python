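# Methods

## Scope and data model

The package replicates, in silico, a three-protocol coronary-calcium
study: every subject is "scanned" at 120 kVp (the reference), 80 kVp and
70 kVp; each scan is scored with its voltage's Agatston threshold table;
and risk-class agreement between the low-voltage scans and the reference
is summarized. Real patient scans from the clinical study are not
public, so the subjects are digital phantoms; the study's printed 5×5
risk-class contingency tables (n = 169) are embedded verbatim and drive
the exact statistical reproductions.

An `ImageVolume` is a stack of axial slices of integer HU on a 512×512
matrix over a 25 cm displayed field of view (pixel 250/512 =
0.488 mm, pixel area 0.2384 mm²) with 2.5 mm slice thickness. The
512 matrix is assumed (it is the universal CT reconstruction matrix; the
clinical protocol states only the field of view).

## Scoring engine

Per slice, pixels ≥ t1 of the voltage's table are grouped into
8-connected components; a component is a lesion when
`pixel_count × pixel_area ≥ 1 mm²` (≥ 5 pixels on the default grid) —
the minimum-area rule that suppresses isolated noise pixels. Lesion
score = density weight of the component's **maximum** HU (the standard
Agatston convention) × area; totals are kept as real numbers and
half-up-rounded only for risk classification. Thresholds are inclusive
integer lower bounds. Connectivity is strictly in-plane: the Agatston
score is a per-slice sum, so components are never merged across slices,
and the 1 mm² rule is applied per slice.

Threshold tables: 130/200/300/400 (120 kVp), 177/272/409/545 (80 kVp),
207/319/478/637 (70 kVp). Each adapted band is the 120 kVp band times
1.3625 (80 kVp) or 1.5925 (70 kVp) to within ±0.01 — these two ratios
are also the calcium HU multipliers used by the scan simulator, since
they are the only calcium-attenuation relations the validation data
quantify.

## Phantoms and acquisition model

A subject phantom is: uniform soft-tissue background (40 HU), an aortic
blood-pool cylinder (radius 15 mm, 48.5 HU at 120 kVp) carrying the
20 mm measurement ROI, and calcific lesions modelled as uniform discs
(every pixel at the lesion's peak HU), each on one slice. Uniform discs
make ground-truth density weights exact; overlapping lesions are
rejected rather than merged so per-lesion ground truth stays
unambiguous. Phantom slabs default to 4 slices — per-slice scoring
makes slab length a pure computation-cost knob (it only adds identical
independent slices), so a thin slab is used rather than a full 12–16 cm
cardiac coverage.

Simulated acquisition at voltage v: calcium voxels ×1.3625 (80 kVp) or
×1.5925 (70 kVp); all other voxels ×1.0515 / ×1.0948 (the published
blood-signal ratios 51.0/48.5 and 53.1/48.5); additive white Gaussian
noise; half-up rounding to integer HU. Half-up (not banker's) rounding
matters: 200 HU × 1.5925 = 318.5 must quantize to 319, the 70 kVp t2,
for the noiseless scaling to classify identically at every published
boundary (verified by brute force over all integer HU 0–2000). No beam
hardening, scatter, partial-volume, reconstruction-kernel or motion
effects are modelled.

### Noise model

```
sigma(kvp, mA, bmi) = 28.1 HU × gain(kvp) × sqrt(200 / mA) × exp(0.02 (bmi − 26))
```

- 28.1 HU is the published mean aortic-ROI noise at 120 kVp / 200 mA
  (population median BMI ≈ 26 kg/m²).
- `gain(120) = 1`; `gain(80) = 1.495` and `gain(70) = 1.550` are
  calibrated so the published mean low-kVp currents (460.1 / 460.6 mA)
  return the published mean noise (27.7 / 28.7 HU) at BMI 26.
- The exponential BMI term is the simplest monotone choice; its
  coefficient β = 0.02 per kg/m² is a free model parameter (the clinical
  data quantify only that noise rises with patient size). The published
  noise dispersion at fixed technique (28.1 ± 3.7 HU at 200 mA) caps any
  BMI-only coefficient at roughly 0.04, so the default sits inside the
  plausible range but the *true* size dependence of image quality also
  involves spectral effects this model excludes.

The scanner's proprietary noise-index lookup is replaced by closed-form
inversion of this model: `select_tube_current` returns the mA that
achieves a requested noise level, clamped to 10–1000 mA with a warning.
The study pipeline's default emulates the observed behaviour of the
clinical noise normalization: each subject's low-kVp scans are targeted
at the per-voltage published mean noise scaled by the subject's own BMI
factor. This choice reproduces simultaneously the published mean
currents (460.1 / 460.6 mA) and the published per-patient noise
agreement (Bland–Altman biases −0.4 and +0.6 HU with narrow limits —
which a fixed absolute target for all subjects could not produce, since
the population noise spread is ±3.7 HU). A fixed absolute target in HU
remains available in `StudyConfig`.

### Cohort generator

Each subject draws: a target risk class from the published class mix
(29.0 / 10.7 / 26.6 / 20.1 / 13.6 %); a BMI from a log-normal matched to
the published median 26.1 and IQR 23.7–28.3 kg/m², truncated to the
observed 18.9–39.9; and a lesion set. Target scores are log-uniform over
essentially the full class band (the clinical cohort is all-comers with
median CAC 42 and IQR 0–199, so boundary-adjacent scores are common and
are what drives reclassification). The score is split into lesions with
density weights drawn 35/30/20/15 % (15/20/25/40 % above 400), peak HU
uniform within the weight's 120 kVp band (trimmed 1 HU so integer
quantization cannot flip a planned weight), and areas 1.6–12 mm²
(up to 40 mm² above 400). Lesions are placed without overlap in an
annulus clear of the blood pool; the subject is rejection-sampled until
the exact rasterized noiseless score lands in the target class, so
ground truth is exact by construction. Per-lesion anatomy (counts,
areas, peaks, positions) is invented — the study publishes none — which
is why simulated reclassification rates are compared to the clinical
ones only structurally, never numerically.

## Agreement statistics

Cohen's κ is unweighted (the value 0.908 printed for the 80 kVp table is
consistent with the unweighted form; a linear-weighted variant exists
behind a flag for sensitivity analyses only). Kendall's τ_b uses the
tie-corrected pair-counting form computed directly on the 5×5 counts.
Both are cross-checked in the test suite against scikit-learn and SciPy
on expanded per-subject data, and τ_b additionally against a brute-force
O(n²) pair-counting oracle. Reclassification counts split into upward /
downward moves relative to the 120 kVp reference (columns). Bland–Altman
uses bias ± 1.96 × sample SD. The ICC is the single-measure
absolute-agreement ICC(A,1) from the two-way subjects × raters mean
squares (cross-checked against pingouin); single-measure was chosen
because each condition contributes one measurement per subject, and the
published ICCs are not reproduction targets since the underlying raw
scores are unavailable.

Large-sample normal-approximation p-values for κ and τ_b are available
(`agreement_p_values`) but informational only.

## Dosimetry

Effective dose = DLP × 0.0145 mSv·mGy⁻¹·cm⁻¹ at 120 kVp, × 0.0147 at 80
and 70 kVp. Per-patient DLP is not published, so the simulator attaches
a parametric DLP model, linear in tube current and anchored so the
study's mean currents yield the study's mean doses (0.54 / 0.42 /
0.26 mSv); simulated doses are descriptive output only and are never
used as a validation quantity, which would be circular.

## Problem sizes and determinism

Every stochastic component is a pure function of its seed (numpy
`default_rng`); identical configurations are bit-identical. The test
suite runs the simulated-study sweep at 20 seeds × 169 subjects with
4-slice phantoms, the noise calibration at 1000 replicates per protocol,
and the detection-vs-flood-fill equivalence at 1000 random small
volumes; the acceptance script uses 5 study seeds and 1000 noise
replicates. These sizes were chosen so the whole analysis reruns from
scratch in minutes on one CPU.

## What the synthetic validation does and does not show

The phantom study validates the *pipeline*: thresholds, scoring
arithmetic, noise calibration, statistics, and the qualitative structure
of the clinical findings (70 kVp reclassifies more than 80 kVp; moves go
predominantly downward; low-voltage scores underestimate the reference
with Bland–Altman limits widening at high scores; a noise-free scan
reclassifies nobody). It cannot validate the *clinical magnitudes*:
reclassification percentages depend on real lesion anatomy, and the
strong BMI dependence observed clinically arises largely from
size-dependent spectral physics (beam hardening, scatter) that a pure
additive-noise model cannot reproduce — with the defensible β range
(≤ 0.04), the model's BMI gradient in reclassification is real but so
shallow that adjacent BMI-cutoff subgroup rates (e.g. < 25 vs
< 24 kg/m²) are statistically indistinguishable at 20 × 169 subjects.
Known further limitations: uniform-disc lesions (no partial volume, so
measured areas are slightly more stable than clinical ones), a uniform
soft-tissue background (no air, bone or fat), and no reader-variability
model beyond noise reseeding.
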