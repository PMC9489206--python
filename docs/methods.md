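# Methods

This note documents the modeling choices, default parameters and known
limitations of scoutlite. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Feature extraction

**Time conventions.** All times are 0-based stimulus seconds; event
intervals are half-open `[onset, onset + duration)`. This makes indicator
sampling unambiguous: a grid sample at time `t` is inside a word or event
iff `onset <= t < onset + duration`.

**Brightness** is the per-frame mean over pixels of the per-pixel maximum
across RGB channels, divided by 255 (the 8-bit channel maximum), so values
lie in [0, 1]. **RMS loudness** is the windowed root-mean-square of the
audio signal, windows anchored at multiples of the hop. **Speech** is the
binary union of word intervals from a force-aligned transcript.
**Change-point indicators** (shot changes and similar) place a 1 at the
grid sample containing each transition.

**Lexical norms** become a sparse per-word regressor
`(lookup − mean)/sd`. The moments are those of the *dictionary*, not of
the stimulus: this makes the regressor stimulus-independent and gives
out-of-vocabulary words — assigned 0 after rescaling — the interpretation
of dictionary-mean imputation. Lookup lowercases and strips punctuation,
since transcripts carry both.

**Dense downsampling** (default target 3 Hz, the rate dense streams are
stored at) bin-averages rather than decimates: averaging is anti-aliasing
and preserves the stream's time-average; incomplete trailing bins are
dropped. Streams at or below the target rate pass through unchanged.

## Face identities and the adaptation regressor

Face observations are 512-dimensional embeddings; similar faces are close
in Euclidean distance. Clustering uses Chinese Whispers on the graph whose
edges connect pairs closer than `edge_threshold`, weighted 1/distance, with
a seeded node-update order and 20 passes by default (the algorithm usually
converges much earlier; a converged pass terminates the loop). Labels are
relabeled contiguously by first occurrence, so results are reproducible
given (fixture, seed). Note that with 1/distance weights, well-separated
blobs remain separate clusters *even on a complete graph* (infinite
threshold); only structureless data coalesces to a single label.

`prune_clusters` drops the most diffuse cluster — largest mean pairwise
within-cluster distance, ties to the lowest id, singletons scoring 0 —
emulating the manual curation step of removing one noisy catch-all
cluster. The only cluster of a single-cluster assignment is never removed.
Manual merging of over-split identities is not automated; callers can
remap labels before building regressors.

The adaptation regressor `log_mean_time_cum` is, per output sample, the
natural log of the mean cumulative on-screen time (seconds, including the
current sample so a first appearance logs a finite value) across the
identities visible in that sample; samples with no visible face emit 0.
The order of operations is mean-then-log — the average of co-visible
characters' cumulative exposures, then the log — matching the regressor's
name. `any_faces` is the per-sample maximum detection probability.

## Design matrices

The HRF is the difference of two gamma densities with SPM-convention
defaults: peak delay 6 s, undershoot delay 16 s, both dispersions 1 s,
undershoot ratio 6, truncated at 32 s, peak-normalized to 1 (the peak sits
at delay − dispersion = 5 s). The dispersion derivative is the finite
difference of the HRF with respect to peak dispersion (step 0.01 s),
sharing the canonical peak normalization so it scales linearly with the
HRF. Each predictor contributes a canonical column and (by default,
switchable off) one dispersion-derivative column; contrasts address the
canonical columns only.

Convolution renders the stream on a fine grid of spacing TR/oversampling
(default oversampling 50, so sub-TR onsets are honored), sparse events as
boxcars of height `value` (zero-duration events as single-sample impulses
of area `value`), computes the Riemann approximation of the continuous
convolution, and samples at volume onsets `t = k·TR`. Sampling at onsets
rather than mid-volume is a fixed convention.

Transformations listed in the model spec execute in their declared
(topologically validated) order on stream values *before* convolution;
orthogonalization residualizes against the named co-streams plus an
intercept and requires a shared support. Drift columns are unit-norm
DCT-II vectors for periods longer than the cutoff (default 128 s, the
convention paired with this confound set); confounds enter verbatim in
table order; the intercept is last. Non-steady-state indicator columns, if
present in the confound table, pass through like any other confound.

The correlation report computes pairwise Pearson r over all columns,
reporting constant columns (the intercept) as 0 with a warning flag.

## GLM estimation

Run-level noise is modeled as AR(1): the pooled ρ is the average over
in-mask voxels of the per-voxel lag-1 correlation of OLS residuals
(normalized by the geometric mean of the leading/trailing sums of squares,
so a perfectly alternating series yields exactly −1), clipped to ±0.99.
Data and design are filtered with the AR(1) square-root filter (first
sample scaled by √(1−ρ²), later samples `x_t − ρ x_{t−1}`) and refit by
OLS; `dof = n_volumes − rank(X)`. A pooled rather than voxelwise ρ is a
deliberate desk-scale simplification of the "AR(1) + noise" family.

Smoothing (default 4 mm FWHM, σ = FWHM/(2√(2 ln 2)) ≈ 1.70 mm) applies to
run-level *parameter estimate* maps only — never to raw data or z maps —
with the kernel renormalized over in-mask voxels so constants are
preserved and no mass leaks across the mask boundary. Subjects combine
their runs by inverse-variance fixed effects; the group level is an
ordinary one-sample t across subjects (a fixed-effects summary, not a
random-effects variance model), converted to z via log-space tail
probabilities so large |t| stays finite and two-sided p-values are
preserved exactly.

## Meta-analysis

Study-level group maps (effect = subject mean, variance = sd²/k) are
resampled to the target grid by linear interpolation with output values
clipped to the source map's in-mask range, then combined per voxel with
the DerSimonian–Laird moment estimator. Whenever `Q ≤ k − 1` the estimate
reduces exactly to inverse-variance fixed effects. Voxels covered by fewer
than two studies are excluded from the combined mask (their count is still
reported in `k_map`); an optional analysis mask (e.g. gray matter) is
intersected on top. No further harmonization (smoothing, design scaling,
renormalization) is applied. Thresholding is two-sided at |z| ≥ 3.29
(two-sided normal p < 0.001). The default target spacing is 2 mm; no atlas
template is bundled — any mask NIfTI on the target grid is accepted.

## Synthetic data

The simulator emulates the statistical structure the pipeline must
survive, not the content of real movies:

- **Binary streams** (speech-like, face-like) are thresholded latent
  bivariate Gaussians sampled at 1 Hz. The latent correlation is solved
  numerically (bivariate-normal orthant probabilities) so the *binary*
  Pearson correlation matches the request; the default 0.5 sits inside the
  range of face–speech correlations observed in narrative media. Latents
  are temporally independent, so indicator runs are short; real speech has
  longer bouts.
- **Dense streams** (brightness-like) are smoothed Gaussian noise mapped
  to [0, 1].
- **Faces** are tight per-identity Gaussian blobs in embedding space
  (within-identity sd 0.05 against typical between-identity distances of
  ≈ √(2·512) ≈ 32), far cleaner than real embeddings.
- **BOLD** is design × true-betas + confound signal (independent random
  voxel loadings on 6 motion-like random walks and 6 white-noise
  components) + stationary AR(1) noise (marginal sd `noise_sd`).
- **Studies** draw their true effect as the global effect plus an
  independent Normal(0, between_study_sd²) jitter at each active voxel;
  non-active voxels stay exactly null in every study.

Defaults define the standard experimental conditions: 20 studies × 4
subjects × 2 runs × 100 volumes at TR 2 s on an 8×8×8 grid of 2 mm voxels
with 10% active voxels at amplitude 1, ρ = 0.3, noise sd 1, between-study
sd 0.1. These sizes keep the full three-level pipeline plus a 20-study
meta-analysis under ~3 s per collection on one CPU while leaving enough
voxels for calibration statements. Because study grids share the meta
grid's 2 mm spacing, the default meta-analysis resampling is an identity;
resampling is exercised separately.

`simulate_study_maps` generates study-level effect/variance maps directly
(with *known* sampling variance), bypassing the time-series levels; it is
the right tool for meta-level calibration and τ² recovery questions, where
re-running 50 studies through the GLM would only add noise and runtime.

## Calibration: what passing and failing tests show

With known within-study variances, DerSimonian–Laird z maps are
well-calibrated (the suite verifies the |z| ≥ 3.29 exceedance rate at
k = 20 null studies) and mean τ̂² is unbiased (verified at k = 50).

The *end-to-end* null calibration — feeding the meta level variance maps
estimated from only 4 subjects (df = 3 sample variances) — is
overdispersed: inverse-variance weights built from df-3 variance estimates
have heavy tails (the second moment of 1/χ²₃ does not exist), so the
combined z has sd ≈ 1.2 and the empirical exceedance rate at 3.29 is
about 0.012 rather than 0.001. This is a statistical property of treating
estimated variances as known in the meta model at very small k, not an
implementation artifact; the corresponding acceptance test asserts the
nominal band and is expected to fail, documenting the effect. The
group-level z maps themselves are exactly calibrated (the quantile
transform preserves p-values; verified in the suite). With realistic
subject counts the distortion shrinks rapidly — the confound-control
demonstration therefore uses 16 subjects per study, where the per-voxel
null exceedance is ≈ 0.002.

A related visible consequence of the pipeline design: 4 mm smoothing of
isolated active 2 mm voxels retains only the kernel's center weight
(≈ 0.23) at the voxel itself and spreads genuine signal into neighbors, so
recovered amplitudes are attenuated and suprathreshold sets are larger
than the active set. Detection and sign recovery are unaffected.

## Numerical choices and degenerate inputs

- HRF peak normalization uses a 1 ms reference grid, cached per parameter
  set.
- Event-to-grid rounding uses half-open interval semantics with a 1e-9 s
  tolerance against floating-point boundary ties.
- `demean_rescale` uses the population sd and rejects constant input;
  correlation of constant columns is reported as 0 with a flag rather than
  NaN.
- `estimate_ar1` excludes zero-variance voxels from pooling and clips to
  ±0.99; `fit_run` rejects rank-deficient designs and empty masks.
- In `group_onesample`, zero-sd voxels yield t = 0 when the mean is 0 and
  ±∞ otherwise (kept as ±∞ z, which thresholding handles).
- `dl_meta` requires strictly positive variances; k = 1 returns the study
  itself with τ² = 0.
- Chinese Whispers breaks label-weight ties toward the smallest label to
  keep runs reproducible; zero distances get weight 1e12.

## Known limitations

- Pure AR(1) prewhitening with a run-pooled ρ; no voxelwise or ARMA noise
  models, no spatial noise model, no cluster-extent or permutation
  inference.
- The meta model treats study variances as known (see the calibration
  discussion above); no small-k correction (e.g. Hartung–Knapp) is
  implemented.
- The simulator's streams lack temporal autocorrelation and the BOLD model
  is linear and stationary; passing tests demonstrate correctness of the
  estimation machinery under its own assumptions, not robustness to
  hemodynamic nonlinearity, motion artifacts or real scanner noise.
- Video/audio decoding, forced alignment and embedding networks are out of
  scope: frames, aligned transcripts and face embeddings are consumed as
  given.
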