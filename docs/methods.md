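# Methods

`cordlevel` implements an along-level ("tractometry-style") analysis of the
cervical spinal cord: quantitative MRI metrics are profiled against a
continuous vertebral coordinate rather than against streamlines, compared
between a patient group (relapsing–remitting multiple sclerosis, pwRRMS)
and healthy controls (HC), and related to clinical disability. Because no
patient data ship with the package, a phantom generator produces synthetic
cohorts whose every ground-truth quantity is recorded, so each stage of the
pipeline is verifiable end to end.

## Along-level coordinate and parcellation

The backbone is a voxelwise continuous vertebral coordinate: 2.0 marks the
top of the C2 vertebral level, 2.37 a point 37% of the way down C2, and so
on. The pipeline discretizes this coordinate into twenty half-open bins of
width 0.2 (C2.0, C2.2, …, C5.8); a voxel with value v falls in bin
⌊v/0.2⌋·0.2. Values of 6.0 and above (C6) are generated by the phantom but
excluded from analysis, since the corresponding anatomy is only partially
covered in typical cervical acquisitions; the upper cut is exposed as
configuration. Bin edges are compared with a tolerance of 1e−5 bins
(2e−6 level units) so that edge values survive float32 storage of the
level map.

Fifteen regions are profiled at three scales: the whole cord; white and
gray matter (WM = cord AND NOT GM, by mask subtraction); six WM pathway
sectors (left/right × dorsal/lateral/ventral columns) and six GM horn
sectors (left/right × dorsal/intermediate/ventral). Pathways partition WM
and horns partition GM by construction, and these partitions are asserted
on every generated subject. Probabilistic masks are binarized strictly
above 0.5.

Per sub-level the pipeline extracts:

* **CSA** — per-axial-slice mask area (voxel count × in-plane voxel area,
  mm²). Each slice is assigned to the bin of the median cord-voxel level in
  that slice (lower median on ties); the bin's CSA is the mean over its
  slices. No cord-angle correction is applied: the phantom cord is straight
  along the slice axis, which makes CSA exactly voxel count × area and
  keeps centerline estimation out of scope.
* **FA/MD/AD/RD** — unweighted means over region ∩ sub-level voxels.
  Lesion voxels are *included* in region means (regions are masked as the
  entire region whether or not a lesion is present); voxels flagged by the
  tensor fit are excluded.
* **Lesion load** — |lesion ∩ region ∩ bin| / |region ∩ bin|, plus a pooled
  whole-region value.

Missing (region, sub-level) combinations are absent rows, never zeros. The
minimum voxel count per cell defaults to 1 and is configurable because
horn × sub-level cells can be tiny.

## Diffusion tensor estimation

Tensors are fitted per voxel by weighted linear least squares on
ln S = ln S0 − b gᵀDg: an unweighted pass followed by one reweighting
iteration with weights equal to the squared predicted signal. This
estimator is deterministic, fast, and exact on noiseless data (the
acceptance suite verifies recovery to ~1e−14). Eigenvalues are sorted
descending and clamped below at ε = 1e−7 mm²/s so FA remains defined at
noisy voxels; clamped and excluded (non-positive-signal) voxels are
counted in the fit report. Scalar indices use the standard closed forms
MD = (λ1+λ2+λ3)/3, AD = λ1, RD = (λ2+λ3)/2,
FA = √(3/2)·‖λ−MD‖/‖λ‖. No Rician-bias correction is applied in the fit;
at the default acquisition (below) the residual FA bias of a WM region
mean is ~0.003, absorbed by the 0.03 acceptance bound. Tensors are fitted
first and scalar maps resampled afterwards when grids differ.

## Phantom

The phantom emulates *preprocessed* data: co-registered masks at 0.5 mm
isotropic atlas resolution, no motion, no distortion. Geometry is a
straight elliptical cord (semi-axes 3.4 × 2.7 mm at C2) whose cross-section
grows smoothly by 25% toward C5 (cervical enlargement, monotone by
construction), with a butterfly-shaped GM core built from four ellipses
and the sector parcellations described above. The level map is linear in
slice index from exactly 2.0 at the top slice to just under 6.0.

Ground-truth tensors are axially symmetric with the principal axis along
the cord. Tissue classes are parameterized by (FA, MD), converted to
eigenvalue triples in closed form: WM (0.63, 1.17e−3 mm²/s), GM
(0.62, 0.95e−3), lesion eigenvalues (1.2, 0.8, 0.8)×10⁻³ (FA ≈ 0.24,
elevated radial diffusivity). GM is modeled nearly as anisotropic as WM —
consistent with reported cord GM FA values, which sit far above cerebral
GM — and oriented along the cord; a more isotropic GM could not reproduce
whole-cord FA ≈ 0.63. Group effects are *additive on FA and MD* per tissue
class, optionally band-limited; defaults are ΔFA = −0.02 (WM) and −0.04
(GM) in patients, which, with lesions included in region means, reproduce
the whole-cord FA pattern 0.63 (HC) → 0.60 (pwRRMS). Per-subject
random intercepts (sd 0.025 FA, 3e−5 mm²/s MD) apply cord-wide, giving the
(1 | subject) correlation structure the mixed model targets.

Lesions (patients only) are 1–4 spheres of radius 1–3 mm centered at
uniformly drawn WM voxels and clipped to the cord; they overwrite the
local tensor but do not deform geometry (no lesion-induced atrophy by
default — both choices are configuration). The defaults yield a mean
whole-cord lesion load of ~0.16 at desk scale.

The DWI forward model is S = S0·exp(−b gᵀDg) over a deterministic
quasi-uniform (Fibonacci-hemisphere) direction set — 15 directions at
b = 750 s/mm², one b = 0 — with Rician noise: each of 3 averages receives
independent Gaussian noise of sd S0/snr in both quadrature channels and
magnitudes are averaged; snr defaults to 20, the regime where magnitude MR
noise matters but a 3-average protocol keeps region means accurate.
Background voxels carry noise-only signal.

**Subject size variation.** Cord caliber gets a global per-subject scale
(sd 4%). GM is sized in template coordinates — it follows the cervical
enlargement but *not* the subject's cord scale — with an independent scale
per vertebral band (C2–C3, C4–C5; sd 5%) plus a small global term (sd 1%).
This makes GM CSA at C2–C3 an imaging feature that neither whole-cord CSA
nor GM CSA at C4–C5 can proxy, which is what lets the clinical-association
analysis demonstrate *localization*. A side effect: WM CSA (cord minus GM)
is mildly anti-correlated with GM size, an acknowledged artifact of the
decomposition; association analyses therefore use cord and GM as the
control family.

**Clinical model.** TUG and T25 walking times are generated from a
standardized latent: B1·z(GM CSA at C2.0–C3.8) + 0.15·z(age) +
0.10·male + diagnosis term + N(0, 0.6²), mapped to seconds via
healthy-control anchors (TUG 6.10 s, scale 1.2; T25 4.25 s, scale 0.75);
the diagnosis terms reproduce the reported group gaps. B1 defaults to
−0.28 for TUG. The noise sd of 0.6 is a deliberate calibration: together
with B1 = −0.28 it makes the generative cells reliably (≥90% of cohorts)
survive FDR at n = 100 while the recovered standardized coefficient stays
within ±0.08 of the generative value — the designed operating
characteristic of the recovery experiment. Real cohorts show larger
clinical variance (patient TUG sd ≈ 1.8 s), so detection there is closer
to marginal; the phantom is an idealization on this axis. EDSS is a latent
score from the same family, snapped to the 0–3.5 half-point grid
(inclusion range), patients only.

Determinism: one master seed is fanned out with `numpy` `SeedSequence`
spawning — one child per subject, three grandchildren per subject
(anatomy, tensors, DWI) — so identical configurations are bit-identical
regardless of processing order, and subject-level parallelism cannot
change results.

## Statistics

* **Welch's t-test** on per-subject region means (unweighted mean over a
  region's sub-levels), α = 0.05; statistics are oriented pwRRMS − HC, so
  deficits are negative. Demographics use Welch (age), Pearson chi-squared
  without continuity correction (sex; samples are large), and ANCOVA
  (walking scores adjusted for age and sex).
* **Cohen's d** = mean difference / pooled sd, per (region, metric) at
  every sub-level and for the region mean; the accompanying significance
  flag uses Welch at the stricter p < 0.01 used for pathway-level tests.
* **Per-level mixed model.** One random-intercept model per
  (region, metric) across all sub-levels:
  value ~ group * sublevel + (1 | subject), fitted by REML with the
  variance ratio γ = σ_b²/σ_ε² profiled out — for fixed γ the GLS solution
  is closed-form (V = I + γZZᵀ is block diagonal by subject) and γ is
  maximized by bounded one-dimensional search on [0, 1e6]; the boundary
  γ = 0 is admissible and preferred on ties, and a solution at the upper
  bound is flagged unconverged. The group contrast at sub-level ℓ is
  β_group (+ the interaction term off the reference level), with normal-
  approximation p-values (no Satterthwaite correction; with ~100 subjects
  × 20 levels the difference is negligible) and α = 0.01. This resolves
  the tension between "a model applied at each level" and a single formula
  containing level and its interaction: one fit, twenty contrasts.
  Implementation note: the twenty contrasts of one family share the
  cohort's subject-level group imbalance, so under the null they tend to
  flag together; null flag *rates* are only meaningful pooled over many
  simulated cohorts.
* **Clinical associations.** clinical ~ imaging + age + sex + diagnosis,
  continuous variables centered and scaled over the pooled analysis sample
  (diagnosis is a covariate in the same model, so pooled standardization
  is the consistent choice), sex/diagnosis as 0/1 indicators; B1 is the
  imaging coefficient. Because the outcome is standardized by its marginal
  sd, which includes covariate and diagnosis variance, a generative
  coefficient of −0.28 is recovered near −0.31; this inflation is a
  property of marginal standardization, not an estimator bias.
* **FDR.** Benjamini–Hochberg step-up, one family per (clinical measure ×
  metric) pooling all region × sub-level cells — the most conservative
  reading consistent with scanning many cells per metric — with q < 0.05.
* **Display normalization** (effect-size matrices scaled by the max
  absolute value into [−1, 1], disability into [−0.5, 0.5]) happens at
  render time only and is never stored in results tables.

## Problem sizes and numerical choices

Desk-scale defaults: 24 × 24 × 40 voxels at 0.5 mm (cohort tests use
22 × 22 × 20), cohorts of 46 HC + 54 pwRRMS, 20 replicates for the
recovery experiments, 10,000 null replicates for Welch calibration. These
sizes make every result in the test suite and acceptance script
recomputable on a single CPU in minutes while keeping ≥150 cord voxels per
slice and ≥500 WM voxels per region mean. Ties in the slice-to-bin median
use the lower median; b-values below 50 s/mm² are treated as b = 0 (common
gradient-file dialect); binarization is strictly above threshold.

## What passing tests do and do not show

The phantom is straight, motion-free, co-registered, and single-shell with
axially symmetric tensors; its tests demonstrate that the along-level
bookkeeping, the estimators, and the statistical battery are correct and
calibrated *given* preprocessed data of this form. They say nothing about
segmentation quality, registration error, cord curvature and angle
correction, partial-volume effects at tissue boundaries, crossing or
dispersing fibers, or pulsation/motion artifacts — all of which real
pipelines must handle upstream. Known limitations: no Rician-bias
correction in the fit (small FA bias at snr 20); WM CSA anti-correlates
with GM size by construction; EDSS is generated from the same latent
family as the walking scores rather than from a clinical progression
model.
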