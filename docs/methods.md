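# Methods

`graspnirs` re-implements, as a tested pipeline over synthetic data with known
ground truth, a whole-head continuous-wave (CW) fNIRS analysis of a
block-design motor-grasping task in two Parkinson's-disease severity groups:
early (ePD, Hoehn–Yahr 1–1.5) and moderate (mPD, Hoehn–Yahr 2–3). The clinical
recordings such an analysis is normally run on are private, so every stage is
exercised end-to-end on the package's own generator, and the tests assert
recovery of planted truth rather than reproduction of any clinical table.

## The measurement model

A CW instrument measures intensity attenuation at two wavelengths (760 and
850 nm here). Optical density is defined with the natural logarithm against
the channel's session-mean intensity,

    ΔOD(c, λ, t) = −ln( I(c, λ, t) / mean_t I(c, λ, ·) ),

and the modified Beer–Lambert law (MBLL) maps concentration changes to OD:

    ΔOD(λ) = [ ε_HbO2(λ)·Δ[HbO2] + ε_HbR(λ)·Δ[HbR] ] · d · DPF(λ),

with ε the base-e molar extinction coefficients (shipped as a versioned CSV of
compiled literature values, converted from the base-10 tabulation), `d` the
source–detector distance (default 30 mm) and DPF the differential pathlength
factor (default 6.0 at both wavelengths — the field's conventional values;
both config-exposed). Inversion is an exact 2×2 solve per channel and sample.

A CW system has no absolute baseline: with the mean-referenced OD definition,
any forward-simulated recording is recovered exactly *up to a per-channel time
constant* (the offset is `ln mean_t exp(−ΔOD)`, constant in time). All
round-trip checks therefore compare session-mean-centred signals, where
recovery is exact to ~1e-14 µM. The forward model calibrates its baseline so
that the emitted trace's temporal mean equals the nominal source intensity.

## Preprocessing chain

Fixed order, enforced through a provenance log (running a stage out of order
raises): OD → wavelet motion correction → high-pass → PCA → MBLL.

- **Wavelet motion correction.** Daubechies-2 discrete wavelet decomposition to
  the maximum dyadic depth with symmetric boundary extension; detail
  coefficients outside `[q1 − f·IQR, q3 + f·IQR]` of their own level are set
  to zero (`f` = 1.5 by default). Levels with fewer than 16 coefficients are
  left untouched: quartiles estimated from a handful of values are
  meaningless, and zeroing those deepest-level coefficients destroys real slow
  hemodynamics (17% RMS distortion of a clean 0.02 Hz oscillation versus 0.2%
  with the guard). Spikes of 10× the background SD are attenuated by ~87%
  (median) at the spike sample; sharp baseline *shifts* are only partially
  repaired — a known limitation of coefficient-zeroing methods.
- **High-pass.** 3rd-order Butterworth at 0.01 Hz applied forward–backward
  (zero phase, so event timing is preserved). No low-pass smoothing anywhere:
  smoothing would manufacture serial correlation that the GLM's pre-whitening
  would then have to undo.
- **PCA superficial removal.** Per subject, both wavelengths' channel traces
  are pooled into one channels×time matrix; the smallest leading set of
  principal components whose cumulative explained variance reaches 80% is
  subtracted. "Reaches 80%" is read as a target (the boundary component is
  removed); the cap reading differs by one component and the fraction is
  config-exposed. The stage runs on OD, before MBLL — the superficial
  contamination is an optical phenomenon shared across wavelengths. When one
  global scalp component dominates (the realistic regime the generator
  emulates) this removes one-to-few components and leaves the task response
  nearly intact; on data whose variance is mostly channel-specific the 80%
  target digs far deeper and removes task signal — the well-known hazard of
  aggressive PCA filtering, visible in this package as a mild (~9%)
  subject-level false-positive inflation on null channels and a scale
  dependence of the small negative amplitude bias (−8% at 16 channels, −11%
  at 102).

## Subject-level GLM (SLSA)

The design matrix has one regressor per condition (left grasp LG, right grasp
RG): a boxcar over the 10 s task blocks convolved with a canonical double-gamma
HRF with peak at 6 s (positive gamma lobe with mode 6 s minus 1/6 of an
undershoot lobe with mode 16 s, unit dispersion, normalized to unit peak — the
exact parameterization beyond the 6 s peak is this package's choice), plus the
boxcar convolved with the HRF's first temporal derivative (absorbs latency
jitter; never tested), plus a constant. Condition columns are normalized to
unit peak so coefficients are in µM. Because the data are high-pass filtered,
the condition and derivative columns receive the *identical* zero-phase filter;
without this the randomized left/right ordering leaves ~15% of the regressor's
energy below the cutoff and the coefficients are attenuated accordingly.

Each channel×chromophore trace is fitted by AR-IRLS: iterate {Tukey-bisquare
robust fit on the whitened system (MAD scale, standard H1 robust covariance —
numerically identical to the statsmodels RLM reference, which serves as the
test oracle) → AR(p) Yule–Walker fit (Levinson–Durbin) to the raw-scale
residuals with p chosen by BIC over 0…round(4·fs)≈8 → re-whiten y and X with
the AR filter} until max|Δβ| < 1e-4 (≤10 outer iterations; non-convergence is
flagged, not raised). BIC rather than AIC: under white noise the order must
come out 0 almost always (AIC picks a spurious positive order ~30% of the
time), and BIC is the convention of the algorithm family this stage follows.
Under AR(1) noise with coefficient 0.8 the two-sided 5% channel test holds
its level (empirically ≈0.055 over 2000 traces) while naive OLS rejects ~50%.

Task-vs-rest inference contrasts the canonical-HRF coefficient against zero
(the 20 s rest is the implicit baseline; under the block design this is
equivalent to an explicit rest regressor). Positive t = activation, negative =
inhibition. BH-FDR runs across channels within one chromophore×condition map
per subject.

## Group level (GLSA)

Per channel and chromophore, the subject contrast coefficients enter a
no-intercept cell-means linear mixed-effects model over the four
group×condition cells with a random intercept per subject
(`beta ~ −1 + group:cond + (1|subject)`), fitted by REML (statsmodels MixedLM;
unweighted — subject-level precisions are not used). Inference uses
dof = n_obs − n_fixed − (n_subjects − 1) when subjects contribute replicates;
with one observation per subject the random intercept is unidentifiable and
the fit reduces to per-cell one-sample inference (dof = n_obs − n_fixed),
which reproduces the one-sample t exactly. Activation maps test each cell
against 0; contrast maps test ePD minus mPD per condition (positive t = higher
activation in the early group). Both uncorrected p and BH-FDR q are always
emitted, per chromophore map.

## ROI analysis and clinical correlations

Ten canonical regions (left/right × SMN, VIS1, VIS2, PFC1, PFC2) map channels
to cortical parcels; membership comes from explicit channel lists or from an
ROI×channel sensitivity matrix thresholded at 20% (inclusive; a channel may
serve several regions). ROI averaging is the unweighted mean over member
channels — note the documented caveat that channels of opposite sign cancel.

The two-step ROI correlation analysis (ROI-CA): (1) per chromophore and
condition, channels significant in the ePD-vs-mPD contrast map at uncorrected
p < 0.05 (the convention of uncorrected selection is config-exposed) are
intersected with each region's members; (2) each subject's contrast betas are
averaged over the selected channels; (3) Spearman's ρ (Pearson on mid-ranks,
t-approximate p at n−2 dof) between the per-subject averages and each clinical
variable, pooling both groups, pairwise-complete over missing values, plus an
age-partialled companion computed by the first-order partial-correlation
formula on mid-ranks (p at n−3 dof). No correction across the ROI×variable
grid in the primary columns; a BH-adjusted companion column is emitted.
Group characterization gates each variable through Shapiro–Wilk on the pooled
sample at p ≥ 0.05 (pooled rather than per-group — the simpler reading) into
an equal-variance t-test or a two-sided Mann–Whitney U.

## The synthetic generator

The generator *is* the study conditions: 13 ePD + 26 mPD subjects, 102
channels (10 per region, contiguous blocks; 2 unassigned), 1.9531 Hz sampling,
10 trials per side of 10 s task + 20 s rest in seeded random left/right order
(10 s lead-in/out; ~620 s per subject). Per subject and region, response
amplitudes are group base values plus a subject offset (SD 0.05 µM, shared
across a region's channels; regions with zero base stay exactly null):
contralateral SMN 0.30 (ePD) vs 0.20 µM (mPD) Δ[HbO2], prefrontal regions
0.05 vs 0.10, secondary visual 0.05 vs −0.04; Δ[HbR] = −0.5 × Δ[HbO2]. Noise
per channel is AR(1) (coefficient 0.8, stationary SD 0.10 µM) plus shared
quasi-periodic oscillations — cardiac 1.1 Hz (deliberately above the 0.977 Hz
Nyquist, so it appears aliased as in real recordings; sampling the tone at the
recording rate is mathematically identical to decimating an oversampled tone
without an anti-alias filter), Mayer 0.1 Hz, respiration 0.25 Hz, drift
0.005 Hz — each with a random-walk phase (σ = 0.15 rad/sample) and its own
spatial gain pattern. The phase walk matters: strictly periodic tones sit
exactly on the 30 s task harmonics and correlate with the regressors by
construction, which real wandering rhythms do not. A shared superficial (scalp)
component (AR(1) 0.95, SD 0.5 µM, positive per-channel loadings U(0.5, 1.5))
makes PCA removal the correct remedy. Motion artifacts (spikes of 0.05 OD,
1–3 samples; baseline shifts of 0.02 OD) arrive at Poisson times (1/min) in OD
space, hitting both wavelengths of a channel. The amplitudes and rates are in
physical units no publication reports; they were set once to values a
practitioner would call a realistic µM-scale block design and are all
config-exposed.

Clinical covariates are drawn per group from normal marginals whose means/SDs
derive from published group summaries (age 63.5±6.0 vs 71.7±7.0 years, etc.),
with physical clipping (duration ≥ 0, age ≥ 18) and fixed missingness for the
Stroop scores (2 and 3 subjects). The designated covariate (UPDRS by default)
is instead built by a Gaussian copula on the designated region's realized
subject amplitudes (Pearson coupling 2·sin(πρ/6)), so its pooled-population
Spearman correlation with the amplitude equals the target ρ = 0.5 exactly,
whatever the marginals; consequence: the designated covariate's *group*
structure is overridden by the coupling, which is the point — ROI-CA pools
both groups. Everything is seeded through named substreams (one per subject
and component), so identical (params, seed) are bit-identical and adding
subjects does not perturb existing ones.

What the generator does *not* emulate: photon transport and channel
sensitivity profiles (membership is synthetic), optode-coupling differences,
task-correlated motion, non-stationary noise variance, HbR dynamics beyond a
fixed −0.5 ratio, and any neurological structure behind the covariates. A
passing suite therefore shows the *statistical machinery* is calibrated and
unbiased under a realistic noise model — not that any clinical conclusion is
reproduced.

## Verification scales and observed behavior

Problem sizes chosen for the test suite (all on one CPU): MBLL round trip at
10 channels × 5 min; AR-IRLS calibration on 2000 traces; amplitude recovery on
20 subjects × 16 channels (median relative bias −8%, detection 88% at
q < 0.05); group-contrast sign recovery over 20 end-to-end runs at 13/26
subjects × 10 channels (the equal-amplitude α check uses the null visual
channels of the same runs); correlation recovery over 100 replicates of
39 subjects × 13 channels with three channels in the target region, HbO2 fits
only, and age configured group-independent so the partial coefficient has
nothing to remove; determinism and runtime on the full 39 × 102 × 620 s study
(≈45 s per run), executed twice and compared byte-for-byte. On pure-noise
recordings with the full physiological mix, the subject-level test is
*conservative* (≈1% rejection at α = 0.05): the AR filter whitens the dominant
low-frequency structure and the robust weights further downweight it; the
nominal-level calibration holds exactly in the AR(1) regime the whitening
models.

## Numerical choices and degenerate inputs

Zero-residual (interpolating) fits return the least-squares solution with zero
covariance and AR order 0. A singular MixedLM profile (tiny or degenerate
cells) falls back to OLS cell means, flagged unconverged. Spearman with zero
rank variance, and partial correlation when the covariate carries essentially
all rank information of either variable (1 − r² ≤ 1e-12), are omitted with a
warning; a constant covariate falls back to the plain coefficient. Extinction
wavelengths are matched to the nearest table entry within 5 nm; a condition
number above 1e8 (wavelengths too close) raises. Result tables are written
with fixed float formatting so reruns are byte-identical.
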