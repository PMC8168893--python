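# Methods

## The measurement

During drowsiness and light sleep the brain produces large, slow (<0.1 Hz)
global activity fluctuations, visible as the mean gray-matter BOLD signal in
resting-state fMRI. Each global dip is accompanied, a few seconds later, by
an inflow of fresh cerebrospinal fluid into the lowest slice of the imaging
volume: unsaturated spins entering the volume raise the measured intensity
(the "inflow effect"). The coupling between the two series is a candidate
imaging proxy for glymphatic drive, and its weakening has been linked to
Alzheimer-related pathology.

The package quantifies this coupling per session as follows.

**Signals.** The global BOLD signal `G(t)` is the average of per-voxel
z-scored gray-matter series. Because each voxel contributes unit variance,
`SD(G)` measures global synchronization and is reused as the session's
*amplitude* (arousal) metric; it is ≤ 1 by construction. The CSF signal
`F(t)` is the average over a bottom-slice CSF mask, z-scored once after
averaging; this normalization is presentational, since Pearson correlation
is scale-invariant.

**Temporal preprocessing** (fixed order): optional spatial smoothing
(Gaussian, FWHM 4 mm, σ = FWHM/2.3548 converted to voxels), zero-phase
band-pass 0.01–0.1 Hz (Butterworth order 2 run forward and backward;
verified gain ≥ 0.98 at 0.05 Hz and ≤ 0.01 at 0.002 Hz and 0.15 Hz for
TR = 3 s), removal of linear and quadratic trends, then discarding the
first and last 5 volumes so filter edge effects fall outside the analyzed
window. Zero-phase filtering is mandatory: any group delay would shift the
lag of the cross-correlation extrema, which is the quantity of interest.

**Coupling.** The cross-correlation function is

    CC(τ) = Pearson( G(t), F(t − τ) ),   τ = k·TR,  k ∈ [−K, K],

computed on the overlapping samples at each lag, re-standardized per lag so
every value is a genuine correlation with |r| ≤ 1 and CC(0) is the plain
correlation of the full series. Negative lags shift CSF ahead of time
(τ = −6 s pairs G(t) with F(t+6 s)). The default lag range is ±21 s (±7 TR).
The scalar coupling metric is CC(+1·TR) = CC(+3 s); *more negative means
stronger coupling*. A variant correlates −dG/dt with F; the derivative uses
the forward difference −(x[t+1] − x[t])/TR assigned to the leading sample.
The stencil convention matters: the forward difference estimates the
derivative half a sample late, which can move the derivative-CCF peak from
−d to the neighbouring lag (−3 s vs −6 s at TR = 3 s for a 3 s delay). This
is documented rather than hidden because no stencil choice removes the
ambiguity at a 3 s sampling interval.

**Permutation inference.** Significance of the session-mean CCF is assessed
by uniformly permuting the session labels of the global signals, re-pairing
them with the CSF signals, and recomputing the mean CCF (default 10,000
draws; sessions of unequal length are truncated to the shortest length from
the start). The two-sided empirical p per lag uses the add-one correction,
p = (1 + #{|null| ≥ |obs|})/(1 + B) ≥ 1/(B+1). Permutations are true uniform
shuffles and may contain fixed points; with tens of sessions this biases the
null conservatively. Implementation note: the all-pairs correlation matrix
at each lag is precomputed once, so every permutation reduces to a gather —
algebraically identical to re-correlating each permuted pair.

One genuine subtlety: when sessions of different durations (140 vs 200
volumes) are mixed, each series is filtered and detrended at its native
length before truncation, so same-session pairs share window-length
characteristics that randomly re-paired series do not. This inflates the
observed statistic's variance very slightly relative to the null (measured
rejection rate ≈ 0.06 instead of 0.05 at the 5% level on null cohorts with
10% long sessions; equal-length cohorts are calibrated to within Monte
Carlo error of the exact rate). Calibration checks therefore use
equal-length cohorts; analyses of mixed cohorts inherit a mildly
anticonservative null, which is noted here as a limitation.

## Session state and nuisance metrics

- **Amplitude**: sample SD of `G`; larger in drowsy/sleeping sessions.
- **Arousal index**: SD over time of the spatial correlation between each
  volume and an arousal template, computed over the template's support.
  The index is invariant to affine rescaling of the template. The original
  template is not redistributable; the package accepts any template volume
  and, on synthetic data, uses the generator's gray-matter loading map
  (labelled synthetic).
- **Framewise displacement**: per-frame sum of absolute backward
  differences of the three translations (mm) plus the three rotations
  converted to arc length on a 50 mm sphere; the session metric is the mean
  over the T−1 frame differences. Head motion is summarized, never
  censored: removing frames would corrupt lagged correlations.

## Association statistics

Sessions repeat within subjects, so every session-level association uses a
linear mixed model with a subject random intercept (statsmodels `MixedLM`,
REML). Effect sizes are reported as Spearman ρ between the
covariate-adjusted outcome and the predictor: "adjusted" means the outcome
minus the fixed-effect contribution of the nuisance covariates (intercept
retained), fitted in the same mixed framework. Significance always comes
from the full model with the predictor included; ρ and p are deliberately
separate statistics.

Degrees of freedom use a between–within (containment) approximation: a
predictor varying within subjects is tested on
`n_obs − n_subjects − (k − 1)` df, a purely between-subject predictor on
`n_subjects − k` df (k = fixed-effect columns incl. intercept). When every
subject contributes one session the random intercept is unidentifiable and
the model is fitted as ordinary least squares, so the p-value reduces
exactly to the simple-regression p. Null calibration of the full path was
verified by simulation (rejection rate 5% ± 2% at α = 0.05). Regressors are
standardized internally for optimizer stability and coefficients mapped
back to the raw scale.

Other pieces: the diagnostic groups are treated as an ordered severity
score HC=0 < SMC=1 < MCI=2 < AD=3 for the dose–response trend (pairwise
contrasts are also emitted); cohort-characteristic comparisons use the
pooled-variance two-sample t (which reproduces the published table's
printed p-values where Welch does not) and the two-sided Fisher exact test
(sum of hypergeometric probabilities ≤ the observed table's); longitudinal
change is follow-up − baseline, so decline is negative; SUVR is gray-matter
tracer uptake over the composite-reference uptake. No multiplicity
correction is applied; the battery reports its test count.

## The synthetic cohort generator

Real sessions are access-restricted, so a generator produces cohorts with
known ground truth; everything downstream is validated by parameter
recovery. Defaults are chosen once to emulate the study conditions.

**Signals.** Global activity is a sum of Gaussian event bumps (FWHM 5 s,
Poisson onsets at 2/min — a stand-in for the 10–20 s arousal events that
drive the real global signal) with amplitudes scaled by a per-session
arousal level drawn from (0.3, 1.7), plus band-limited background noise
(SD 0.1); ≥ 90% of spectral power lies below 0.1 Hz. CSF inflow is
`F(t) = κ · (−G0′(t − d))` with delay d = 3 s, optionally half-wave
rectified (inflow cannot be negative; the linear default is analytically
tractable). Generation runs at dt = 0.5 s and is block-averaged to
TR = 3 s, so sub-TR delays are representable. Sessions have 140 volumes
(200 for the synthetic "ADNI3" batch, 10% of sessions), TR = 3 s.

**Measurement model.** Fast mode emits 30 gray-matter pseudo-voxels
(positive loadings 0.5–1.5 times G, iid noise SD 0.5) and 4 CSF voxels
(F plus iid noise SD 0.2); this preserves the synchrony semantics of the
amplitude metric at a fraction of the cost of full volumes. Volume mode
paints the same model into a 12×12×8 grid (gray-matter block above the
bottom slice; CSF patch on slice 0) so the NIfTI/mask/smoothing path is
exercised end to end.

**Covariates.** Age ~ N(74, 6²); gender balanced; groups with probabilities
(HC, SMC, MCI, AD) = (0.26, 0.15, 0.53, 0.06); APOE ε4 allele counts
enriched in impaired groups; baseline SUVR and MMSE drawn per group from
the published cohort's means/SDs. The per-session gain is

    κ_i = max(0, κ0 − Σ effects·covariates + N(0, 0.12)),  κ0 = 1,

with effects 0.10 per SD of age, 0.18 for female gender, 0.10 per severity
level, 0.20 per SD of SUVR — no quantitative gain–covariate model exists in
the literature, so these are design parameters, sized so each covariate
contributes a comparable, recoverable share of gain variance (each
direction recovered in ≥ 90% of 200-session cohorts). Follow-up MMSE
declines by 3 points per unit gain deficit (noise SD 1, clipped to [0, 30]);
follow-up SUVR drifts by N(0.01, 0.05²). Second sessions sit 2 years later
and chain the markers (one session's follow-up is the next one's baseline).
Motion parameters are random walks (step SD 0.05 mm; rotations scaled by
1/50 per mm).

**What the generator does not emulate** — hence what passing tests do not
show about real data: no hemodynamic response function or BOLD physics, no
cardiac/respiratory signals (unsampleable at TR = 3 s), no spatial
structure beyond block masks, no registration or motion artefacts coupled
to the signals, and a linear gain–covariate linkage invented for
testability. Recovery results demonstrate that the *pipeline* is unbiased
and calibrated under a known truth, not that the physiological effect sizes
are realistic.

## Numerical and design choices

- Lag-sign convention anchored so that "CSF shifted ahead by 6 s"
  corresponds to τ = −6 s; the cosine fixture (G = cos(2πt/20), F its
  negative derivative delayed 3 s) yields CC(+3 s) = −sin(2π·6/20) ≈ −0.951
  with a positive extremum at a negative lag, reproducing the published
  peak geometry. With the default 5 s event kernel, the analytic location
  of the raw-CCF negative extremum is τ ≈ argmax C′(u) − d ≈ 0 s, one TR
  from +3 s; the derivative-CCF peak identifies the delay itself.
- Problem sizes in the test suite and acceptance script (e.g. 120–200
  session cohorts, 50-replicate recovery, 300–600 replicate calibrations
  with 500 permutations) are chosen so the whole battery runs on a laptop
  core in minutes while keeping Monte Carlo error well inside the asserted
  tolerances.
- Edge cases: constant series raise undefined-correlation errors;
  zero-variance gray-matter voxels are reported by index; empty masks,
  overlapping masks, non-integer delay/dt ratios and cutoffs above Nyquist
  are rejected; a CSF mask above the bottom slice warns but computes.
- All randomness flows from a single seed through `numpy` SeedSequence
  spawning; identical config + seed reproduces cohorts bit-for-bit.

## Known limitations

- The Satterthwaite small-sample correction is approximated by containment
  degrees of freedom (exact only in the one-session-per-subject limit);
  for the cohort sizes involved the difference is far below the Monte
  Carlo noise of any reported p.
- Mixed-duration cohorts make the permutation null mildly anticonservative
  (see above).
- The subject-level variant keeps the earliest session per subject and uses
  simple regression; no weighting for subjects with more data.
- Real-data spatial preprocessing (motion correction, registration,
  skull-stripping, mask drawing) is out of scope; masks and aligned volumes
  are inputs.
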