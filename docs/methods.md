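# Methods

## The signal model

Diffusion-weighted MRI signal in perfused tissue is modelled as a
bi-exponential (intravoxel incoherent motion, IVIM) decay in the diffusion
weighting b (s/mm²):

    S(b) = S0 · [ f · exp(−b·D*) + (1 − f) · exp(−b·D) ]

with tissue diffusivity `D` (mm²/s), pseudo-diffusion coefficient `D*`
(mm²/s) describing the fast capillary-perfusion decay, and perfusion
fraction `f` (stored as a fraction, reported in %). The default acquisition
scheme is a 12-point protocol with b = 0, 10, 20, 30, 40, 50, 75, 100, 150,
250, 400, 600 s/mm² and per-b direction counts (15, 9, 9, 9, 9, 9, 4, 12,
4, 4, 4, 16); direction replicates are arithmetic-averaged into one signal
per b before fitting (isotropy assumed), so effective noise at a b-value
scales as 1/√n_directions.

Because blood (long T1/T2) and tissue (short T1/T2) are weighted differently
by the sequence timing, the fitted signal fraction over-represents blood.
With relaxation weights w_x = exp(−TE/T2_x)·(1−exp(−TR/T1_x)), the
blood-volume fraction is recovered by inverting that weighting:

    f_blood = f·w_t / (f·w_t + (1−f)·w_b)

Defaults (3 T pancreas, respiratory-triggered): TE = 45 ms, TR = 5000 ms,
tissue T1/T2 = 725/43 ms, blood T1/T2 = 1932/275 ms. Under these constants
the correction roughly halves a small signal fraction (0.05 → 0.023). The
map is the identity when w_t = w_b, fixes 0 and 1, and is monotone — these
invariants are tested. The corrected fraction is what the evaluation layer
consumes for every algorithm.

## The six fit algorithms

All fitters share the constraint box 0.5×10⁻³ < D < 6×10⁻³ mm²/s,
6×10⁻³ < D* < 200×10⁻³ mm²/s, 0.001 < f < 0.99 and a common initialiser
(S0 from the b = 0 signal; D and intercept from a log-linear fit to
b ≥ 150 s/mm²; f from the intercept deficit; D* started at 70×10⁻³ mm²/s).

* **free** — constrained non-linear least squares over (S0, f, D, D*). A
  trust-region-reflective solver is used rather than plain
  Levenberg–Marquardt because LM cannot honour box constraints; on interior
  solutions the two coincide.
* **fixed** — same objective with D* frozen at 70×10⁻³ mm²/s, a value
  typical of healthy abdominal tissue. Removing the worst-determined
  direction stabilises D and f.
* **adaptive** — segmented fit with an adaptive threshold: for each
  candidate threshold b_t among the scheme's b-values in [40, 400] s/mm²
  (requiring ≥ 3 points at/above and ≥ 2 below), D and the intercept come
  from log-linear least squares on b ≥ b_t (D deliberately unconstrained —
  the high-b mono-exponential slope is already stable), f from the intercept
  deficit, and D* from a bounded 1-D least squares on the full curve. The
  threshold with the smallest full-curve SSE wins; ties break toward the
  smaller b_t. SSE is the selection criterion of choice here; other
  goodness measures would be defensible.
* **mle** — maximum likelihood under Rician magnitude noise,
  log p = Σ_b log[(S/σ²)·exp(−(S²+ν²)/2σ²)·I0(Sν/σ²)], maximised with
  σ estimated jointly per voxel (a study-wide fixed σ is available via
  `NoiseModel`). The Rician likelihood removes the noise-floor bias of
  least squares at low SNR. Initialised from the least-squares solution.
* **bayes-lin** — per-voxel posterior over (S0, f, D, D*) under a Gaussian
  likelihood with the noise scale marginalised analytically under a
  Jeffreys prior (giving −(n/2)·log SSE) and a uniform box prior over the
  constrained space. Summary = posterior mean (mode optional).
* **bayes-log** — hierarchical empirical-Bayes model: each voxel's
  transformed parameters θ = (logit f, log D, log D*) — the transforms
  enforce positivity and f ∈ (0,1) without hard boxes — are drawn from a
  shared N(μ0, Σ0) whose hyperparameters are learned from the fitted voxel
  population. S0 and σ are marginalised analytically (flat and Jeffreys
  priors): log p(y|θ) = −½·log(gᵀg) − (n−1)/2·log(yᵀy − (gᵀy)²/gᵀg) with g
  the unit-amplitude model curve. Needs ≥ 10 voxels; in practice one fits a
  rough outline of the whole organ and masks afterwards, which also means
  the prior is dominated by the larger (healthy) tissue — the mechanism by
  which shared priors can suppress tumour contrast.

### MCMC details

Both Bayesian fitters use a vectorised adaptive random-walk Metropolis
sampler that updates all voxels of a region in parallel; the hierarchical
fitter interleaves, every sweep, conjugate draws of μ0 (Normal) and Σ0
(inverse-Wishart, df 5 + V, weak identity ridge 10⁻⁶ to guarantee positive
definiteness for small regions). The uniform-prior fitter uses a mixture
kernel — 90% random-walk steps with per-coordinate proposal widths matched
during burn-in to the running posterior spread (the constraint box is
extremely anisotropic relative to typical posteriors), 10% independent
uniform draws over the box, which decorrelate the chain for weakly
identified voxels whose posteriors fill much of the box. A single joint chain with per-sweep
hyperparameter updates was chosen over an outer-loop
estimate-prior-then-refit scheme: it is the standard formulation, subsumes
the alternative, and yields posterior spreads for free. Defaults: 12 000
iterations, 4 000 burn-in, proposal scales adapted every 50 burn-in
iterations toward ~30% acceptance (within the 20–45% band where random-walk
Metropolis mixes well). Chains are reproducible bit-for-bit given the seed;
the pipeline derives one seed per patient × acquisition from the base seed
by hashing.

Numerical choices: the marginal likelihoods floor the residual sum of
squares at (10⁻⁶·RMS(y))²·n, which acts as a minimal noise scale and keeps
log SSE finite on noise-free input (where the posterior then concentrates
on the exact solution); the floor is invisible at any realistic noise
level. Degenerate inputs: all-zero signals are rejected; non-positive
signals in a log-linear stage cause that threshold to be skipped (segmented
fit) or trigger midpoint fallback (initialiser).

## The synthetic study generator

The generator emulates a two-session test-retest cohort: per patient, a
tumour ROI (default 210 voxels) and a normal-tissue ROI (default 118
voxels) with voxel-wise true parameters drawn uniformly from tissue ranges;
session 1 acquired twice (the repeat used only for intra-session
precision), session 2 once. Defaults:

| | f | D (mm²/s) | D* (mm²/s) |
|---|---|---|---|
| tumour | 0.01–0.07 | 1.0–1.5 ×10⁻³ | 15–100 ×10⁻³ |
| normal | 0.04–0.12 | 1.2–1.8 ×10⁻³ | 30–100 ×10⁻³ |

Tumour ranges envelope reported per-patient ranges in poorly perfused
pancreatic adenocarcinoma; the normal-pancreas ranges are package
configuration chosen to give the expected direction of contrast (tumour
less perfused, slightly lower diffusivity), not measured values.

Session and acquisition effects are multiplicative mean-1 lognormal factors
(default CV 5% between sessions, 2% between acquisitions), one factor per
parameter per patient×session (and per acquisition), *shared across the
patient's voxels* — modelling scanner/physiology drift that survives ROI
averaging. Lognormal keeps parameters positive and makes the induced wCV
analytically equal to the CV (verified by a calibration test at 10%).

Noise is Rician per direction replicate, then direction-averaged. The
`snr` parameter is defined as the SNR of the direction-averaged b = 0
signal entering the fit (default 20); the per-direction noise scale is
therefore (S0/snr)·√n_directions(b=0).

**What the generator does not emulate** — and hence what passing tests do
not show about patient data: spatial correlation of noise and physiology
within an ROI, EPI distortion, partial-volume and registration error,
between-patient hardware variation. Voxels are statistically independent.
One consequence is documented and deliberate: averaging ~200 independent
voxels suppresses fit scatter by √n, so ROI-level test-retest wCV of the
poorly identified D* comes out near the session-effect floor (~5–7%) in
simulation, whereas patient studies with same-size ROIs report ~50%; the
difference is the intra-ROI correlation that a signals-only phantom cannot
carry. The corresponding acceptance check of that pattern is accordingly
expected to fail on this generator, and the parameter-recovery,
shrinkage and calibration checks — which do not depend on intra-ROI
correlation — are the meaningful simulation evidence.

## Evaluation measures

ROI summaries are the means of the voxel-wise fits. Three measures, per
algorithm × parameter, mirroring a test-retest biomarker study:

* **Uniqueness** — Spearman rank correlation (midrank ties) between
  parameter pairs (D&f, D&D*, f&D*) across patients, tumour ROI, first
  acquisition only. The p-value is the exact n!-permutation probability for
  n ≤ 10, t-approximation beyond.
* **Precision** — within-subject coefficient of variation,
  wCV = 100·√(Σ(m1−m2)²/2N)/μ, μ the mean over all 2N measurements (a
  per-subject-mean variant is a config switch). Inter-session pairs are
  acquisition 1 of each session; intra-session pairs are acquisitions 1 and
  2 of session 1. Algorithms are compared with a Wilcoxon signed-rank test
  on the per-subject (m1−m2)²/μ² against the best (lowest-wCV) algorithm —
  exact null for n ≤ 25 without rank ties, normal approximation otherwise;
  all-zero differences return p = 1 with a degeneracy flag.
* **Contrast** — 100·|normal − tumour|/mean per patient, from
  session-averaged acquisition-1 ROI means (patients with one tissue in
  only one session contribute that session), averaged over patients;
  Wilcoxon on per-patient contrasts against the highest-contrast algorithm.
  The absolute difference and two-tissue mean denominator are the package's
  reading of "percentage difference"; a signed variant would flip no
  conclusions here because the constructed effect directions are uniform.

The trade-off table pairs each algorithm × parameter's contrast with its
inter-session wCV (the content of a precision-versus-contrast scatter).
No multiple-testing correction is applied (α = 0.05 throughout). The
fixed-D* algorithm contributes no D* rows to any table.

## Problem sizes

Default chain lengths and the study design above run the full six-algorithm
pipeline on a 14-patient study in minutes on one core. The bundled
`scripts/acceptance.py` uses 48-voxel tumour / 24-voxel normal ROIs for its
six-algorithm study (ROI-mean statistics stabilise well below the default
ROI sizes), 200 voxels for the shrinkage experiment, 100 000 MCMC
iterations for the quadrature comparison, and 200 replicate studies for the
wCV calibration.

## Known limitations

* D* is structurally poorly identified at pancreatic perfusion fractions
  (f of a few per cent); its estimates are bound- and initialisation-
  dominated for the non-Bayesian fitters. This is a property of the model
  and protocol, not a solver defect.
* The uniform-prior Bayesian fitter is labelled "data-driven" in some of
  the literature it follows, but its prior here is a plain per-voxel
  uniform box (no population information); only the log-Gaussian
  hierarchical fitter learns from the voxel population.
* The exact threshold-candidate set and selection rule of the segmented
  fit, and the stopping rule of the hierarchical sampler's original
  outer-loop formulation, are not uniquely fixed by the literature; the
  choices here (all scheme b-values in [40, 400], SSE selection, joint
  chain) are documented package decisions.
* No spatial regularisation beyond the hierarchical prior; no tri-exponential
  or kurtosis extensions; no DICOM/NIfTI ingestion (CSV tables are the
  interchange format; NIfTI export would only matter for image-shaped
  phantoms, which the generator does not produce).
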