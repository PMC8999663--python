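# Methods

This note documents the models behind `ctperf`: what the synthetic cohort
generator simulates and how it is calibrated, how measurement works, the
statistical conventions, and the limits of what the package's passing
tests demonstrate.

## 1. Study design being emulated

A stress dynamic myocardial CTP acquisition of 30 ECG-gated frames (one
per cardiac cycle at the stress heart rate), preceded by a diluted
timing-bolus scan at the ascending aorta. One "sub-optimal" late frame of
the dynamic series serves as the static perfusion image. The left
ventricle is reformatted into short-axis slices (5 mm, base to apex) and
divided into 16 AHA segments (6 basal, 6 mid, 4 apical; no apex cap).
Segment-level truth mimics stress/rest SPECT scoring on a 0–4 scale:
stress ≥ 2 defines an abnormal segment; reversible defects (rest < 2) are
ischemic, fixed defects (rest ≥ 2) infarcted.

The reference cohort scale is 25 patients × 16 segments = 400 segments
with 63 abnormal (49 infarcted, 14 ischemic), timing-bolus aortic peak
enhancement (PE) 80.8 (SD 18.1) HU, dynamic-scan PE 393.8 (SD 91.7) HU,
inter-scan PE correlation r ≈ 0.84, and per-class parameter quartiles of
0.9/1.0/1.1 vs 0.5/0.7/0.8 (MPR) and 112/128/144 vs 95/106/124 HU
(endocardial attenuation). These are the generator defaults
(`CohortConfig`); everything below describes how they are realized.

## 2. Contrast kinetics and the inter-scan PE correlation

The aortic first pass is a gamma-variate bolus
`C(t) = A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)` with defaults t0 = 8 s,
α = 3, β = 3.5 s (peak at t0 + αβ = 18.5 s), a standard first-pass form.
The myocardial curve is a delayed (4 s), dispersed (β × 1.3) copy, so
myocardial enhancement always lags the aortic peak. Frame times are
spaced by the stress RR interval; frame 1 is pre-contrast.

Sampling never lands exactly on the continuous peak, so bolus amplitudes
are rescaled to the **on-grid** maximum: the sampled curve's peak minus
baseline equals the patient's PE target exactly. This makes noise-free
round trips exact and keeps PE targets meaningful at any heart rate.

Both scans share a lognormal **cardiac-output factor** `c_p`:
`PE_timing = 80.8·c_p·ε₁`, `PE_dynamic = 393.8·c_p·ε₂`, with the shared
log-variance chosen in closed form so the Pearson correlation of the
lognormal pair equals the configured target (0.84) given the two
configured coefficients of variation. The diluted timing bolus is thereby
≈ 20 % of the full-strength amplitude, as acquired with a 20 % contrast
solution. Curve noise is i.i.d. Gaussian per frame at `roi_curve_noise_sd`
(default `noise_sd/10` ≈ 1 HU — ROI-mean noise is far smaller than voxel
noise, and a large per-frame noise would bias the max-over-frames PE
upward).

## 3. Per-class parameter distributions

Printed cohort summaries give only median and quartiles per class, so each
class distribution is a **two-piece (split) normal**: lower/upper
half-normals glued at the median with `σ_lo = (q50−q25)/z₇₅`,
`σ_hi = (q75−q50)/z₇₅` (z₇₅ = 0.6745). This matches all three configured
quartiles exactly with minimal assumptions; draws are truncated at zero by
resampling (the truncated mass is < 1 % for all default classes, so the
quartile perturbation is negligible).

**MPR** is a patient-normalized quantity by construction, so per-segment
true MPR is drawn i.i.d. from its class split normal. The segment's true
subendocardial enhancement is then `E_i = MPR_i · PE_timing,p`
(definitional, giving exact noise-free round trips through measurement).

**Endocardial attenuation** is where patient-level contrast variability
lives: `A_i = b₀ + f_p · H_i`, with `b₀ = 47 HU` the unenhanced
myocardial attenuation, `f_p = PE_dynamic,p / 393.8` the patient's
aortic-PE factor, and `H_i` a segment-level split normal. `H`'s three
parameters are solved numerically (Gauss–Hermite integration over the
lognormal factor + bounded least squares) so that the **marginal**
quartiles of `A` hit the configured class triples. For the normal class
the patient factor alone (CV 0.233) nearly exhausts the printed spread
(112–144 HU), so the system sits on its feasibility boundary; the
least-squares fit leaves a residual of ≈ 0.02 in CDF units, i.e. the
marginal quartiles land within ≈ 3 HU of the targets (verified by
simulation at 10⁴–4·10⁵ draws). The per-segment unenhanced baseline
`b_i = A_i − E_i` absorbs the difference between the independently
calibrated attenuation and enhancement draws.

This construction realizes the central premise: patient-level PE
variability contaminates raw attenuation but cancels out of MPR (and of
TPR, which divides by a same-patient mean).

## 4. Defect structure and the TPR failure mode

Abnormal segments arrive as **contiguous per-patient defects**: a patient
is diseased with probability `expected_abnormal_fraction × 16 /
mean_defect_extent` (defaults: 0.1575 × 16 / 6.3 = 0.40); a diseased
patient's defect spans `1 + Binomial(15, (6.3−1)/15)` segments centred on
a uniformly random angle (nearest segment centres across levels — a crude
vascular-territory wedge). The whole defect is infarcted with probability
49/63, else ischemic. Expected abnormal fraction equals the configured
63/400; per-cohort counts fluctuate as in a real 25-patient sample.
Setting `defect_contiguity = False` reverts to i.i.d. per-segment draws.
The wedge heuristic is a modelling choice, not a claim of anatomical
fidelity.

Epicardial attenuation uses a **transmurality** τ per abnormal segment:
`H_epi = ((1−τ)·H_cf + τ·H)/γ`, where `H_cf` is a counterfactual draw
from the normal class, γ ~ N(1.0, 0.05) is endo/epi ratio noise, and
τ ~ Beta with mean 0.75 (infarcted) or 0.30 (ischemic), concentration 6.
Infarcts are predominantly transmural, ischemia predominantly
subendocardial. An extensive transmural defect depresses the
patient-mean epicardial attenuation — TPR's denominator — and falsely
normalizes TPR in exactly the way that makes it underperform MPR; the
headline AUC ordering (MPR above both comparators) emerges from this
mechanism rather than being imposed.

SPECT-like scores are graded from the drawn MPR (abnormal: ≥ 0.75 → 2,
0.5–0.75 → 3, < 0.5 → 4; normal: < 0.95 → 1 else 0); ischemic segments
score 0 at rest, infarcted keep their stress score.

## 5. Rendering and measurement

Each slice is an annular wall (default endo/epi radii 20/32 voxels in a
128×128 matrix, 12 slices: thirds to basal/mid/apical with ties to the
more basal level) around a contrast-filled cavity; wall voxels take the
segment's endocardial or epicardial layer value at the rendered frame
plus i.i.d. Gaussian voxel noise (default SD 10 HU). Segment sectors are
binned by polar angle from the recorded anterior-groove angle,
counterclockwise as viewed from the apex; layers split at normalized
transmural depth 0.5 (radially, from the per-slice min/max masked
radius — the renderer and the measurement use the same rule, so
round trips are exact).

Measurement conventions:

- PE: baseline = mean of the first n frames (1 for the dynamic series,
  whose first frame is pre-contrast; 2 for the timing bolus), peak = max
  of the remaining frames, raw (no curve fitting, no smoothing by
  default).
- Static phase: first frame at/after the aortic peak frame at which the
  mean myocardial curve attains its maximum over the remaining frames; a
  fixed-offset alternative is exposed. The selected frame can never
  precede the aortic peak.
- ROI statistics are whole-layer means per segment; enhancement subtracts
  the same voxels in the pre-contrast (frame-0) stack, i.e. per-segment
  baseline subtraction.
- Classification: abnormal iff value **strictly below** the cutoff; a
  value at the cutoff is normal (fixed for determinism).

## 6. Statistical conventions

- Empirical AUC = Mann–Whitney probability with midrank ties, oriented
  lower-is-abnormal; CI from the DeLong structural-components variance
  with a normal approximation (no logit transform), clipped to [0, 1].
- DeLong's paired test: structural-components covariance, two-sided
  normal p-value; zero variance with equal AUCs returns p = 1, with
  unequal AUCs it is an error.
- Youden cutoff: maximize sens + spec − 1 over midpoints between adjacent
  distinct values plus the degenerate all-normal threshold (so J ≥ 0);
  ties break toward higher specificity.
- Proportion CIs: Wilson score intervals. Percentages are rounded half-up
  to integers; this pairing reproduces every derived cell of the
  published accuracy table from its printed operating points.
- Mann–Whitney U: midranks, tie-corrected normal approximation with
  continuity correction (group sizes here are ≥ 14; exact enumeration
  lives in the test oracles).
- ICC: two-way random effects, single measure, absolute agreement —
  ICC(2,1) — from the ANOVA mean squares, CI via McGraw–Wong
  F-distribution bounds; the conventional choice for two fixed raters.
- Paired t-test: two-sided; a zero-variance nonzero difference is
  reported as a degenerate-statistic error rather than an infinite t.
- No multiple-testing correction (α = 0.05, raw p-values). Per-segment
  analyses ignore within-patient clustering; the report metadata flags
  this.
- Effective dose = DLP × 0.014 mSv per mGy·cm.

## 7. Reproducibility and problem sizes

One master seed drives everything; per-patient, per-stage RNG substreams
(`SeedSequence([master_seed, patient_index, stage])`) let any stage be
re-simulated independently. Identical config + seed gives byte-identical
CSV/JSON/NIfTI outputs, recorded with SHA-256 checksums in the run
manifest.

Problem sizes used by the test suite and the acceptance script — chosen
to estimate each quantity comfortably within its tolerance — are: 400
segments (default cohort), 10,000 segments (625 patients) for quartile
calibration (tolerances ±0.05 ratio / ±5 HU), 200 patients for the PE
correlation (±0.1), and 100 replicate cohorts for the AUC-ordering
fraction. The full default rendered run takes seconds on one CPU.

## 8. What the phantom does and does not show

The generator reproduces the *statistical structure* of a static-CTP
study: class-conditional parameter distributions, patient-level contrast
variability and its differential effect on ratio vs raw parameters,
contiguous partially-transmural defects, and consistent SPECT-like truth.
It does **not** simulate CT physics or anatomy: no beam hardening, motion
or reconstruction artifacts, no papillary muscles or realistic LV shape,
no misregistration between frames, no DICOM/ECG, and no human visual
assessment (the published visual-assessment row is reproduced only via
confusion-matrix arithmetic). Passing tests therefore demonstrate the
correctness and calibration of the algorithms and the qualitative
mechanism behind MPR's advantage — not clinical performance on real
images. AUCs on the noise-free phantom truth run higher than published
clinical values (e.g. MPR ≈ 0.94 vs 0.84) because observer variability
and artifacts are absent; the *ordering* of the parameters, not the
absolute AUC level, is the transferable result.

Known limitations: the normal-class attenuation calibration is a
least-squares compromise (§3); the defect wedge ignores true coronary
territories; epicardial layer statistics inherit the endocardial
calibration through the transmurality blend rather than being calibrated
to their own printed quartiles; and whether published ROIs covered whole
layers or small patches is unknown — whole-layer means are implemented.
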