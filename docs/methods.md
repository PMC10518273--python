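# Methods

`cartispec` couples a synthetic cadaver-cohort generator with the
analysis chain used to discriminate normal from (early) osteoarthritic
human knee cartilage by visible/near-infrared (Vis-NIR) diffuse
reflectance spectroscopy, and to validate the resulting classifiers
against indentation biomechanics. This note records the models, the
parameters that matter, and the design choices made where the design
was genuinely open.

## Synthetic cohort

Real cadaver spectra of this kind are not publicly depositable, so the
package is built around a generator whose outputs exercise every
downstream stage under a known ground truth.

**Hierarchy.** Donors (cadavers) contribute samples at six knee sites
(lateral/medial femur, lateral/medial tibia, trochlea, patella), each
sample carries an OARSI grade 0–5 drawn from a configurable
distribution and yields three replicate single-point spectra and one
indentation test. The default shape (17 donors × 6 sites × 3 samples ×
3 replicates = 918 spectra) mirrors a realistic multi-donor study; the
default grade mix gives roughly 38 % normal (OARSI 0–1), 38 % early OA
(2–3) and 24 % advanced OA (4–5).

**Spectra.** Each measurement is produced on the two instrument grids
(Vis detector 350–1100 nm at 0.6 nm; NIR detector 1000–2500 nm at
6.5 nm) and merged at 1050 nm. The generative form is a low-order
polynomial baseline minus Gaussian absorption bands, plus:

* a grade-proportional baseline offset over 400–700 nm (soft-edged
  window), emulating scattering changes as collagen loses organisation;
* collagen-associated bands near 1156/1210/1350 nm and
  proteoglycan-associated bands near 1650/1720/1780 nm whose depths
  shrink linearly with grade (amplitudes are therefore monotone in
  grade by construction);
* an additive per-donor random intercept over the whole spectrum
  (`donor_effect_sd`, default 0.02), which creates the within-cadaver
  correlation that the mixed model downstream exists to absorb;
* i.i.d. Gaussian noise (`noise_sd`, default 0.008) and saturation
  noise in the 1400–1520 nm water band with 8× the noise SD, which the
  trimming step excises;
* a small fraction of "attenuated" samples (default 3 % at 0.15×
  signal) representing tissue whose spectral signature understates its
  histological grade — the main source of irreducible classification
  error in the synthetic world.

`class_effect_size` multiplies every grade-dependent term. It is a free
parameter of the synthetic world: no per-grade band amplitudes are
measurable from published figures, so the default (1.0) was chosen once
to place site-level test accuracies in the 0.7–0.9 range typical of
this application, and the generator makes no claim of radiative
transfer realism. Physically accurate light transport,
dark/white-reference calibration and probe-contact artefacts are
explicitly out of scope; consequently, passing tests demonstrate the
correctness and calibration of the *analysis*, not instrument-level
performance on real tissue.

**Mechanics.** Each sample's ground-truth moduli are its pooled-group
mean (normal / early OA / advanced OA) times a shared log-normal factor
(donor intercept SD 0.15, within-donor SD 0.10 on the log scale);
phase angle and thickness vary additively. Group means default to
reported values for human knee cartilage: equilibrium modulus
1.29/0.74/0.164 MPa, instantaneous 19.12/11.57/1.67 MPa, dynamic
9.42/5.46/1.517 MPa, phase 5.37/6.12/2.88°, thickness
2.37/2.57/2.27 mm for normal/early/advanced respectively.

The forward model follows the test protocol: a 12.5 kPa equilibrium
pre-stress, four stress-relaxation steps of 5 % of the remaining
thickness with 15-minute holds, then four 1-Hz sinusoid cycles at 2 %
amplitude. Relaxation is single-exponential per step (τ = 30 s by
default), sampled at 10 Hz (100 Hz for the sinusoid, which resolves
phase well below 0.1°). Peak forces lie on the instantaneous-stiffness
line and plateaus on the equilibrium line, both through the Hayes
relation, so the inverse analysis recovers the ground truth *exactly*
in the noiseless case — this round trip is the package's central
self-consistency contract, not an empirical claim. With τ = 0 the
step peaks coincide with the plateaus (fully relaxed limit).

## Indentation analysis

* **Zero-strain origin**: the equilibrium position under the 12.5 kPa
  pre-stress, averaged over the last 10 s of the pre-stress hold. If no
  pre-stress segment is marked the first sample is used, with a warning.
* **Equilibrium modulus**: nominal stress (plateau force / πa²,
  plateau = mean of the last 60 s of each hold) against strain
  (displacement from origin / thickness); the least-squares line is
  fitted *with* an intercept, which absorbs the pre-stress bias, and the
  slope is converted by `E = m·πa(1−ν²)/(2hκ)`, ν = 0.3.
* **Instantaneous modulus**: at the step whose cumulative strain is
  nearest 10 % (step 2 of the protocol: 1 − 0.95² = 9.75 %),
  `E = (F_peak − F_pre)(1−ν²)/(2auκ)`, ν = 0.3. The pre-stress force is
  subtracted so that a purely elastic record returns the equilibrium
  modulus; without the subtraction the elastic limit is biased by
  ~2.5 % at the stated pre-stress.
* **Dynamic modulus and phase**: least-squares sinusoids at the loading
  frequency fitted to stress and strain over the dynamic segment (first
  cycle discarded as start-up transient); modulus from the amplitude
  ratio with ν = 0.5 (incompressible short-time response), phase as the
  stress–strain lag wrapped to [0°, 90°).
* **Geometry**: thickness is the mean of three circumferential
  readings; κ is evaluated once per sample at the pre-test thickness
  (the pre-stress compression is ≪ 1 % of thickness and is ignored for
  κ). Unit fields on the time series allow mN/µm/m inputs; results are
  always MPa, degrees, mm.

**Hayes factor.** The finite-thickness correction κ(a/h, ν) for a rigid
flat-ended cylindrical punch on an elastic layer bonded to a rigid base
is computed by solving the governing Fredholm integral equation of the
second kind (Nyström method, Gauss–Legendre quadrature) rather than
transcribing printed tables; the bundled CSV
(`cartispec/data/hayes_kappa.csv`, a/h ∈ [0, 2] in steps of 0.025,
ν ∈ {0, 0.05, …, 0.5}) is regenerated by
`scripts/build_hayes_table.py` and interpolated monotonically (PCHIP in
a/h, linear in ν) at run time. The interpolant is cross-checked against
the direct solver in the test suite. Note that κ − 1 grows like
(0.88…1.13)·a/h to first order, so the half-space formula is accurate
to 0.5 % only below a/h ≈ 0.005.

## Spectral preprocessing

Order: trim → Savitzky–Golay → localized SNV, each applied per
contiguous segment of the trimmed grid (segments are separated by gaps
> 50 nm, so no filter or normalization window ever crosses the excised
1400–1520 nm water band). Defaults: trim windows 400–1400 and
1520–1850 nm; SG window 11 points, polynomial order 2, no derivative;
LSNV window 200 nm anchored at each segment start. The SG/LSNV
parameters are conventional chemometric choices exposed in the run
configuration, not constants of the method. Replicates are kept as
separate observations throughout. MSC, detrending and outlier rejection
are out of scope.

## Wavelength selection

Greedy forward sequential feature selection to k = 30 wavelengths,
scored by donor-grouped cross-validated accuracy (stratified grouped
folds; 5 by default) of a standardized RBF-kernel SVM with
inverse-frequency class weights — the same family as the final model
with a single hyperparameter point, since a full nested grid search per
candidate would be disproportionate. Exact accuracy ties are pervasive
at this scale (fold accuracies are coarse fractions, and the accuracy
path typically plateaus well before 30 wavelengths), so ties are
resolved by a deterministic hierarchy: the candidate's own
single-wavelength CV accuracy (univariate relevance, precomputed once),
then the mean held-out decision margin, then the lower wavelength.
Accuracy alone cannot distinguish an informative wavelength from a
noise wavelength once the path plateaus; the hierarchy keeps the
selection on spectrally meaningful bands while remaining fully
reproducible. Per-step score tables are logged so greedy-step
optimality can be re-verified after the fact. A `min_spacing_nm`
pre-decimation (default off) thins the dense visible grid for runtime
control without touching the coarser NIR grid.

## Classification

Two binary tasks: *classifier 1*, normal (OARSI 0–1) vs OA (2–5);
*classifier 2*, normal vs early OA (2–3) with advanced OA excluded
entirely. Per site and repeat: donors are assigned whole to a ~70/30
train/test split (among feasible whole-donor subsets within 0.03 of the
optimal deviation from 70 % of spectra, one is drawn seeded-at-random —
exact minimisation would make repeats identical whenever the optimum is
unique); wavelength selection runs on training donors only; kernels
{RBF, linear, polynomial, sigmoid} are grid-searched
(C ∈ {0.1, 1, 10, 100}; RBF γ = scale-heuristic × {0.1, 1, 10};
polynomial degree ∈ {2, 3}) by donor-grouped 5-fold CV with
inverse-frequency class weights, scoring by accuracy (balanced accuracy
once the minority class falls below 40 %); the best model is refit on
all training rows and evaluated on the held-out donors. The whole
procedure repeats three times with fresh splits. Feature
standardization is fit on training rows inside each fold's pipeline.
Degenerate folds (single-class training part) trigger a reshuffled fold
assignment and, if a single donor monopolises a class, are dropped.
Per-spectrum test predictions are aggregated to per-sample groups by
replicate majority vote with ties going to the degenerated class
(conservative toward disease detection).

## Evaluation

Confusion-matrix metrics with the degenerated class positive. Two
"accuracy" variants are reported side by side: the standard proportion
correct, and TP/(TP+FP) — conventionally *precision*, but printed under
the accuracy label in parts of the application literature — plus
balanced accuracy. Zero-denominator metrics are flagged `None`, never
silent NaN. ROC curves come from a threshold sweep over the decision
values with trapezoidal AUC (equal to the pairwise Mann–Whitney
statistic with half credit for ties, which the test suite verifies by
brute force). Wavelength importance uses permutation (20 shuffles per
column by default) of held-out test columns, reported as mean %
accuracy drop; literal column elimination is not implementable for a
fitted kernel machine without refitting.

## Mixed-model validation

Biomechanical responses are compared across groups with a linear
mixed-effects model — group fixed effect, donor random intercept,
REML — because several samples share a donor. Pairwise contrasts use
Fisher's LSD (model-based SEs, no multiplicity adjustment; Holm
available by flag) with a between-within degrees-of-freedom
approximation `df = N − n_groups − (n_donors − 1)`, recorded in every
result. Grouping designs mirror the classifiers: pooled OARSI groups,
SVM prediction groups, and the three-group comparison
(normal/early/advanced); models are fitted per site and pooled. A
singular random-intercept fit (variance → 0) is reported and flagged,
not hidden. Simulation checks in the suite put 95 % CI coverage at
≥ 93/100 and null type-I error within 0.05 ± 0.02.

## Problem sizes and runtime choices

The pipeline's desk-scale configurations trade cohort size for
turnaround: end-to-end runs in the test suite and acceptance script use
8–10 donors, 2–4 samples per site, selection of 6–8 wavelengths over a
25-nm-spaced candidate grid, and three repeats — enough to exercise
every code path and the determinism, leakage and calibration
guarantees. The full-scale defaults (17 donors, k = 30, full 0.6-nm
visible grid) run the identical code and are the recommended settings
for actual studies. Stage seeds derive deterministically from a single
master seed, and completed stages are skipped on re-runs via
configuration-hash markers.

## Known limitations

* The spectral generator is phenomenological; it reproduces the
  qualitative group differences (baseline offset, band-depth changes)
  but not scattering physics, instrument drift or probe-contact
  variation.
* The viscoelastic forward model is quasi-linear with one relaxation
  time; real cartilage shows multi-exponential, strain-dependent
  relaxation. The inverse analysis is nevertheless the standard
  protocol analysis and applies to real traces with marked segments.
* Only ν ∈ [0, 0.5] and a/h ∈ [0, 2] are tabulated for κ; thicker
  indenters or thinner samples than that range raise an error rather
  than extrapolate.
* The SFS tie-break hierarchy is a package design choice; with real
  data at larger sample sizes, exact ties are rarer and the hierarchy
  matters less.
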