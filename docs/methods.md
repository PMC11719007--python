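# Methods

`riskpipe` re-implements, as a tested and reusable pipeline, a pre-treatment
CT analysis for predicting progressive disease (PD) versus disease control
(DC) in advanced NSCLC patients starting first-line pembrolizumab
monotherapy. The chain is: intra-/peritumoral mask construction on axial CT
slices → 2-D radiomic feature extraction → feature filtering and selection →
a slice-level logistic risk model → a slice→lesion→patient
frequency-thresholding classifier → survival comparison of the predicted
risk groups. Because the clinical cohort behind the published model is
private, the package ships a first-class synthetic-cohort generator with
known planted structure; every stage is validated against that ground truth
and against independent brute-force oracles.

## Region-of-interest geometry

Each lesion is represented on up to five axial slices: the central slice
(largest tumour area) plus up to two cranial and two caudal neighbours,
clipped to the lesion extent and the volume bounds. Per slice, three nested
masks are built from a seed-grown segmentation:

* **Core** — the Otsu-thresholded, 8-connected, hole-filled component
  containing the radiologist seed. Otsu's threshold is computed inside a
  local square window (half-width 0.75 × the annotated diameter) rather than
  the whole slice, which would be dominated by air and bone.
* **Core-plus-edge** — the core dilated by `edge_width_px` (default 2 px),
  absorbing partial-volume transition pixels at typical 0.7–1.0 mm in-plane
  spacing.
* **Ring** — the peritumoral annulus: a further dilation by `ring_width_px`
  minus the core-plus-edge. The ring width targets 6 mm of parenchyma,
  `round(6 mm / spacing)` px (8 px at 0.75 mm; 8 px is also the fallback when
  spacing is unknown).

Dilation is implemented as a thresholded Euclidean distance transform (an
exact disk dilation). This was a deliberate choice over iterated
structuring-element dilation: rasterized disk kernels under-dilate when
composed, violating both the annulus-area check and the identity
`core_plus_edge ∪ ring = dilate(core, edge + ring)` that the tests enforce.

Intensities are windowed before analysis: HU values are clipped to a
clinical display window (default soft-tissue, centre 40 HU, width 400 HU)
and mapped linearly to [0, 1]. An optional lung-parenchyma mask can be
intersected with the ring; the synthetic images do not need one, and whether
the original analysis restricted the ring to lung is unknown, so the
behaviour is a flag rather than a default.

## Feature bank

The exact in-house feature calculator behind the published model is not
public, so this package defines an explicit registry of 173 features per
region (519 across Core/Core-plus-edge/Ring, matching the ~522-feature pool
scale of the original analysis), each with a stated formula and a
brute-force test oracle. Definitions of the headline features:

* `OD-CentroidDifference` — ‖intensity-weighted centroid − geometric
  centroid‖ / √(area/π). "OD" is read as an optical-density analogue of
  normalized intensity; weighting is linear in intensity (whether the
  original used a log transform is unknowable and is documented as a
  limitation).
* `RadCentre` — intensity-weighted mean of the normalized radial position
  r/r_boundary(θ) over mask pixels: 0 when mass sits at the centre, →1 at
  the rim. Normalization is per-angle (by the boundary distance in the
  pixel's direction), which keeps the statistic meaningful for elongated
  and annular regions.
* Radial-signature statistics (`MeanRadius`, `RadSD-Angle`,
  `RadVarianceAngle`, `RadKurtosis-Angle`, …) — moments of the boundary
  distance r(θ) sampled at 360 equal angles from the geometric centroid by
  vectorized ray marching (0.25 px steps, outermost crossing, half-step
  extent correction).
* `ODEccentricity` / `OD-MajAxis` / `OD-MinAxis` — the intensity-weighted
  second-moment ellipse; `MinAxis` is the binary-mask ellipse minor axis.
* `TotalVariance` — variance of masked intensities; `V-Correlation` — GLCM
  correlation at offset (1, 0) (vertical, distance 1), 32-level
  quantization; `GrayLevel6` — occupancy of bin 6 of a 16-bin equal-width
  histogram over [0, 1]; `FFT2` — fractional spectral energy in the second
  of four radial frequency bands of the 2-D FFT of the mask-cropped patch
  zero-padded to 64×64.

The remainder of the registry is standard first-order statistics,
2-D shape descriptors (scikit-image regionprops, Hu moments), a GLCM grid
(distances 1–3 × four angles × six statistics, computed within the mask by
reserving grey level 0 for background), spectral band energies, Haar
level-1 wavelet sub-band statistics, and Sobel/Laplacian gradient
statistics. Quantization (16 histogram bins, 32 co-occurrence levels) is
fixed at build time so values are comparable across runs. All features are
computed on the bounding-box crop of the mask and are therefore exactly
translation invariant (a property test asserts ≤1e-9 drift under a (5, 7) px
shift). Numerical equality with the original calculator's values is not
attainable and is not claimed; the registry reproduces every published
feature *name* with a pinned, tested formula.

## Preprocessing and first-pass filter

Categoricals are one-hot encoded (unseen levels at apply time become
all-zero indicator blocks with a warning). Each numeric feature is rescaled
to [−1, 1] by min/max learned **on the discovery split only**; external
values outside the training range are preserved, never clamped. The
first-pass filter removes, in order: near-constant features
(variance < 1e-8), weak features (folded univariate AUC `max(a, 1−a)` <
0.55), and redundant features (pairwise Spearman |ρ| > 0.95, dropping the
lower-AUC member, ties to the lexicographically later name). The exact
thresholds behind the original 339-of-522 removal are unpublished; these
three defaults implement the same stated intents, are surfaced in
configuration, and are echoed in the serialized `FilterReport`.
Clinically determined columns are exempt from all three rules. Spearman
rather than Pearson is used because monotone transforms are common across
texture features.

## Feature selection and the signature menu

Three selectors over the filtered pool, each run with and without the
clinical covariates, give six candidate signatures:

* **SFS** — greedy forward selection maximizing grouped-CV logistic AUC;
  a candidate is admitted only if it improves AUC by more than 0.03, and
  signatures are capped at five features (the one-in-five rule for a
  27-patient minority class).
* **mRMR** — difference (MID) form: relevance MI(f; y) minus mean MI(f;
  selected), mutual information on 8-bin quantile-discretized features.
* **ReliefF** — all-instance sampling, Manhattan distance, 10 neighbours,
  top-k by weight.

mRMR and ReliefF produce rankings, not stopping rules; their rankings are
trimmed by the same ΔAUC > 0.03 admission rule the forward search applies,
so all six signatures obey the same size discipline (the original menu also
shows sub-maximal signature sizes for these selectors). Ties everywhere
break lexicographically by feature name for cross-platform determinism. The
menu winner is the signature with the highest mean grouped-CV AUC, ties to
the lower standard deviation. Selection is evaluated at slice level with
patient-grouped folds, matching the slice-level training target of the risk
model.

## Risk model

A 5-fold nested, patient-grouped, label-stratified cross-validated logistic
regression. The inner loop grid-searches the only standard LR knobs
consistent with the method's overfitting concerns — L2 strength
C ∈ {10⁻², 10⁻¹, 1, 10, 10²} × class weighting {none, balanced} — the outer
loop produces out-of-fold slice scores, and the final model is refit on all
discovery rows with the grid point chosen by grouped CV over the whole
discovery set. Grouping guarantees that no patient's slices appear on both
sides of any split; a test verifies that corrupting the labels of an outer
test fold leaves that fold's out-of-fold scores bit-identical.

The published risk calculator is also shipped verbatim:

    Risk of PD = [1 + exp(−0.282 − 0.509·PackYears + 0.999·NMetSites
                          − 0.816·ODCD_RING + 1.148·RadCentre_RING)]⁻¹

Read literally, this expression makes risk *decrease* as the number of
metastatic sites grows, which contradicts the cohort's clinical
directionality; the likely explanation is a sign-convention slip in the
printed form. Both readings are implemented behind an explicit
`convention` flag (`literal` | `conventional`, the latter negating the
linear predictor); the default is the literal printed form, with a warning.
The calculator's inputs are assumed to be on the [−1, 1] training scale
(the original scaling parameters are unpublished), so it never rescales
internally.

## Frequency-threshold hierarchy

Slice scores become patient calls through three thresholds, all inclusive
(≥): a slice is high-risk when its score ≥ X; a lesion's frequency score is
its count of high-risk slices; the lesion is PD when that count ≥ Y; the
patient is PD when ≥ Z lesions are PD. Published operating point:
X = 0.22 (Youden-J of the slice-level ROC), Y = 2, Z = 1. Threshold fitting
uses discovery out-of-fold scores only — X as the slice-ROC Youden-J cutoff,
then (Y, Z) maximizing the patient-level Youden-J with ties toward smaller
values (the sensitivity-favouring, risk-averse choice) — and refuses
externally tagged rows outright.

For patient-level ROC curves a continuous statistic is needed; the maximum
lesion frequency score per patient (0–5) is used, the only choice consistent
with "any PD lesion makes the patient PD". Lesions with fewer than Y slices
can never be called PD; the case is unaddressed in the source method, so the
absolute cutoff is applied unchanged and a warning is emitted. Youden-J ties
break toward the lower threshold (again favouring sensitivity).

ROC AUC uses the Mann–Whitney identity with ties counted 0.5. Confidence
intervals use the fast DeLong placement-value variance estimator with a
normal approximation, clipped to [0, 1]; a test checks the endpoints against
a 2000-replicate stratified bootstrap. RECIST labelling applies the
inclusive ±20 % / −30 % diameter-sum boundaries with CR for disappearance of
all target lesions.

## Survival

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
lifelines behind the module's record/curve types (event-before-censoring at
tied times, the standard convention). p-values are reported to machine
precision. Calibration is tested: the null rejection rate at α = 0.05 over
500 equal-hazard simulations must lie in [0.03, 0.07], and the p-value
agrees with a 2000-permutation reference within 0.02 on a 60-record fixture.

## Synthetic cohort generator

The generator defines the study conditions for all end-to-end tests:

* 97 patients at 28 % PD prevalence by default (the discovery-set scale);
  ~18 % of patients carry a second lesion; five axial slices per lesion.
* Each lesion is a Gaussian-smoothed ellipse (radius 8–14 px, tapering
  1.0/0.85/0.65 across the slice stack) over parenchyma background with
  Gaussian noise (σ = 0.05 on the normalized scale).
* Background parenchyma is placed at −100 HU rather than realistic lung
  (≈ −750 HU) so peritumoral intensities fall inside the soft-tissue
  analysis window after normalization; with realistic lung values the
  planted ring signal would be clipped to zero at the window floor. This is
  the generator's single largest departure from real CT.
* **The PD signal lives only in the ring zone**: an angularly asymmetric
  halo (amplitude `ring_contrast_effect` × 15 HU, random phase, radial
  decay) displaces the ring's optical centroid and shifts its radial mass
  profile. Core intensities are class-identical by construction, so a
  pipeline that discriminates must be reading peritumoral features — the
  headline claim becomes a testable property.
* Clinical covariates are class-conditional (PD: fewer pack-years, more
  metastatic sites, worse ECOG, directionally matching the cohort tables);
  survival is exponential with hazard ratio 3 between the *true* classes
  (median DC PFS 10 months, OS 16.5 months, the cohort's follow-up medians),
  independently censored at rate 0.2. Tying hazard to truth rather than to
  predictions means the survival separation test exercises the whole chain.
* All randomness descends from one integer seed through
  `numpy.random.SeedSequence` spawning; a fixed seed reproduces the cohort
  exactly.

What passing tests do **not** show: the generator has no anatomy, no
scanner-specific noise, no pleural or vascular structures confounding the
ring, and its planted effect sizes are free parameters, not calibrated to
the private cohort (which published no texture distributions). End-to-end
results on synthetic cohorts demonstrate that the machinery recovers planted
peritumoral structure; they are not evidence about real-patient
performance, and the published cohort AUCs (0.85 discovery / 0.81 external)
are not reproducible without the private data.

## Problem sizes and numerical choices

The default test suite runs the end-to-end recovery check on ten replicate
120-patient cohorts using the SFS-with-clinical signature path (the final
model's path); the full six-signature menu is exercised on a smaller cohort
and in `scripts/acceptance.py`. The planted-signal monotonicity property is
checked at the level of the manipulated quantity itself (ring-asymmetry
feature AUC across effect sizes 0/0.5/1/2, three replicate seeds), which
isolates the generator-to-feature link; the model-to-classifier link is
covered by the end-to-end check. These sizes are the package's own choices
for a laptop-scale default run; all are configurable.

Other numerics: Otsu ties resolve toward the lower threshold; a degenerate
(near-constant) segmentation window raises rather than returning an empty
mask; GLCM statistics on single-level regions are defined as their
finite limits (NaN → 0); scaler spans of zero map the feature to 0;
logistic fits use lbfgs with up to 2000 iterations.

## Known limitations

* Feature formulas are reconstructions pinned by name and documented
  formula, not the original calculator; absolute feature values differ.
* The Eq.-style calculator's coefficient signs are implemented as printed
  (with the `conventional` escape hatch); which reading the original
  software used cannot be determined from the publication.
* The filter thresholds are declared stand-ins; matching the original's
  339-removed count is not a goal.
* Whether slice-level selection in the original operated at slice or
  patient granularity is unstated; slice-level with patient-grouped folds
  is implemented.
* The synthetic cohort's realism limits are listed above; external-set
  survival comparisons on 18-patient splits are underpowered by design.
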