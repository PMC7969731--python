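# Methods

`awakerest` re-implements, as a tested library, a multivariate fMRI
analysis of *awake reactivation* and *awake suppression*: an orientation
decoder trained on task scans is applied to resting scans collected
before and after a brief stimulus exposure, and the scan-averaged
classification probability measures whether spontaneous activity drifts
toward (reactivation) or away from (suppression) the pattern of the
exposed orientation.  Because the raw subject data for this paradigm are
not publicly available, the package pairs the analysis with a
synthetic-data generator that reproduces the experimental design with a
known ground truth, so every claim the analysis makes can be checked by
parameter recovery.

## The analysis pipeline

**Preprocessing** follows the published chain exactly and in a fixed,
enforced order:

1. *Hemodynamic shift.* BOLD is shifted by 6 s (3 volumes at TR = 2 s)
   by index remapping — no interpolation, no HRF deconvolution.  The
   trailing 3 volumes lose coverage and are dropped.
2. *Spike filter.* A voxel is removed from all analyses if, in any one
   of the ten decoder-construction runs, any volume deviates from the
   voxel's within-run mean by more than 10 within-run SDs (sample SD,
   n − 1).  Note the filter measures the spike against an SD the spike
   itself inflates: at 150 volumes a spike must exceed ≈ 17 nominal SDs
   to be caught, which is why the generator's default spike amplitude is
   25 SDs.
3. *Linear detrend* per voxel per run (ordinary least squares).
4. *Z-score* per voxel per run (sample SD).  Zero-variance voxels are
   zeroed and logged, not dropped, so voxel indices stay aligned; the
   sparse decoder prunes them.
5. *Averaging.* Decoder scans: one sample per trial, the mean of the 6
   stimulus volumes (after the shift), giving 10 runs × 18 trials = 180
   samples, 90 per orientation.  Resting scans: consecutive
   non-overlapping 6-volume windows starting at the first usable volume
   (24 windows per 5-min scan; the trailing partial window is
   discarded).  The rest scans inherit the decoder runs' spike mask and
   voxel set.

**Decoder.** Binary logistic regression with automatic relevance
determination: each voxel weight has a zero-mean Gaussian prior whose
precision is learned by evidence maximization (Laplace approximation at
the MAP weights, MacKay fixed-point update α_j ← γ_j / w_j², with
γ_j = 1 − α_j Σ_jj).  Voxels whose precision exceeds 10⁸ are pruned to
exactly zero weight.  The bias is unpenalized; initialization is
deterministic (weights 0, precisions 1), convergence is declared when
the largest weight change falls below 10⁻⁵, with a 500-iteration cap
(non-convergence returns a flagged model plus a warning — this occurs
when the training data are close to separable and weights grow without
bound, which the study conditions below deliberately avoid).  On
near-separable low-dimensional data the decoder's decisions agree with
an L2-regularized logistic oracle; with few informative voxels planted
among many, the retained set is strongly enriched for them.

**Rest read-outs.**  The decoder's two-class probability is evaluated on
every 6-volume window; the *scan probability* for an orientation is the
arithmetic mean of its window probabilities (probabilities are averaged
on the probability scale, not the logit scale).  The two pre-task scans
are combined by averaging their scan scores with equal weight; the two
post-task scans are analyzed separately (post1, post2).  *Template
similarity* correlates (Pearson) each window pattern with the
per-orientation mean pattern from the decoder-scan samples; undefined
correlations (zero-variance window or template) are excluded and logged,
never imputed.  Suppression of one orientation must lower the
probability and the similarity to that orientation's template while
leaving the other orientation's template similarity unchanged — this
disambiguation is only meaningful because the two orientations' evoked
patterns are distinct rather than mirror images (see below).

**Statistics.**  All inferential machinery is implemented from closed
forms and validated against independent implementations in the test
suite: one-/two-way fully-within repeated-measures ANOVA with
subject-partitioned error terms; Mauchly's W per effect on orthonormal
contrast scores with the Huynh–Feldt ε applied to the p-value only when
Mauchly rejects at 0.05; partial η² = SS_effect/(SS_effect + SS_error);
orthogonal polynomial trend contrasts (quadratic weights ∝ (1, −2, 1)
for three levels, tested as a one-df contrast, so F = t²); one-sample,
paired, pooled and Welch t tests with Cohen's d and Hedges' g
(small-sample correction 1 − 3/(4 df − 1)); the exact two-sided binomial
test at p₀ = 0.5 by tail doubling, with Cohen's g = |k/n − 0.5|; Dixon's
Q (variant r10, two-sided critical values at α = 0.05 for n = 3–30);
a rank-based median split (odd n puts the median subject in the lower
group; Welch replaces the pooled t when Levene's test rejects); and the
assumption checks (Kolmogorov–Smirnov normality, Levene, Mauchly) that
drive those policy branches.  A 10,000-replicate null simulation keeps
the one-way rm-ANOVA's type-I rate inside 4–6% at nominal 5%.

## The synthetic data and what it does (not) emulate

`TuningMap` assigns each ROI a set of voxels, half of them (by default)
orientation-selective.  Each informative voxel responds to exactly one
of the two orientations (disjoint subsets), so the two evoked patterns
are distinct rather than sign flips of one contrast vector — as in
cortical orientation maps, and necessary for the template-similarity
disambiguation to be non-trivial.  The decoder-construction scan adds
each trial's response pattern as a 12-s boxcar delayed by 6 s (matching
the shift-and-average analysis, which never deconvolves), plus a per-run
linear drift, white (optionally AR(1)) Gaussian noise, and rare
single-volume spikes.

**Planted rest signal.**  A resting scan plants
`planted_amplitude × unit(pattern of the target orientation)`; positive
amplitudes plant reactivation, negative ones suppression (the
anti-pattern), zero is the null.  A tonic pattern held for the entire
scan would be *exactly annihilated* by the per-scan z-score (mean
removal per voxel), so a tonic trace is unobservable by the published
pipeline — the package keeps a `constant` mode precisely to demonstrate
that.  The default `epoch` mode therefore models the trace as sustained
but fluctuating: 12-s epochs aligned to the analysis windows, each "on"
with probability `duty_cycle` (default 0.75).  What survives the
z-score is the on/off contrast, giving scan probabilities that are
monotone in the planted amplitude, equal to 0.5 at zero amplitude, and
bounded by the duty cycle in the saturating limit.  In the cohort
simulation one gate per scan is shared across the ROIs the signal is
planted in, so a multi-area suppression waxes and wanes coherently, as
a single brain state.

**Study conditions.**  The default `StudyConfig` mirrors the
experimental design: 12 subjects; ROIs V1/V2/V3 of 24/20/16 voxels
(deliberately compact so a full cohort simulates in ~2 s; the analysis
is dimension-agnostic); exposure order counterbalanced with exactly half
the subjects meeting the novel orientation first; reactivation planted
only in V1 after novel exposure (amplitude +2.5), suppression planted
across V1–V3 after familiar exposure (amplitude −2.5, scaled by each
subject's simulated learning), nothing planted at pre or post2.  The
voxel tuning amplitude (0.25 signal units) puts leave-one-run-out
decoding accuracy near 0.8 — good but far from separable — and the rest
amplitudes put scan probabilities in the ~0.45–0.55 band the method
reports in practice, rather than at saturation.  Under these conditions
100 out of 100 seeded cohorts reproduce the qualitative study signature
(post1 above/below chance and pre in the correct direction, post2 back
at pre, untouched-template similarity unchanged), while null cohorts
stay at 0.5.

**Behavioral simulation.**  The 2IFC observer has a logistic
psychometric function in log₁₀ S/N, parameterized directly by the S/N
at which accuracy equals the 2-down 1-up convergence point (70.7%);
guess rate 0.5, lapse rate 0.02, slope 10 per log₁₀ unit.  Staircases
start at 25% S/N, step multiplicatively by 1.5 dB (a geometric-mean
threshold implies log-scale stepping; the step size is not specified by
the protocol and is config-exposed), stop at the tenth reversal, and
estimate the threshold as the geometric mean of the last six reversal
levels.  With the default observer, blocks average ~37 trials (inside
the reported 30–40 band) and the mean threshold estimate lands within
a few percent of the true 70.7% point; the high start plus a shallower
slope or smaller step biases estimates upward, which is why the
defaults are calibrated jointly.  Training lowers the true threshold by
a per-subject learning factor (mean 0.30, SD 0.08) applied to both
orientations (the transfer the behavioral literature reports); planted
suppression depth scales with true learning.  Note that three staircase
blocks per day measure improvement with substantial noise, so the
learning–suppression median split — like the original, borderline
observation — is *not* reliably significant in every simulated cohort.

## What passing tests do and do not show

The generator has no 3D spatial structure, head motion, physiological
noise, scanner drift nonlinearity, or session-to-session registration
error, and its noise is white by default.  Parameter recovery under
these conditions validates the *pipeline* — that the estimator recovers
what was planted, with correct null calibration — not the neuroscientific
claim on real data.  Conversely, the arithmetic targets (180 samples;
138 fixation events per scan at a 2.17-s mean cycle) are properties of
the experimental design itself and transfer exactly.

## Numerical and design choices

- Sample SD (n − 1) everywhere; z-score guards zero variance.
- The inter-stimulus interval of the fixation task is stated as ranging
  0.5–0.8 s with mean 0.67 s; a continuous uniform on that range has
  mean 0.65, so the generator uses a two-point mixture on {0.5, 0.8}
  with weights (13/30, 17/30), whose mean is exactly 0.67 s
  (config-exposed).
- Rest windows are non-overlapping with configurable phase; phase 0
  (first usable volume) is the default.
- Pre-task scans are z-scored per 5-min scan and their scan scores
  averaged; they are never concatenated and re-decoded.
- The positive class of the decoder is fixed at fit time (the
  lexicographically larger label by default, i.e. "45"); downstream
  orientation probabilities select a column, never refit.
- Dixon's printed critical value in the original report (0.546 at
  n = 12) does not match the standard two-sided r10 table (0.426); the
  variant is config-exposed and the discrepancy documented rather than
  guessed at.
- The post-hoc pre-vs-post1 comparison pooled across regions is a paired
  t on region-averaged scores with its t-based 95% CI; the original does
  not name its post-hoc procedure.
- `median_split_compare` breaks covariate ties by stable order, making
  the split deterministic and invariant to monotone transforms.

## Known limitations

- The ARD decoder reconstructs the published algorithm family
  (evidence-based relevance determination), not any toolbox's exact
  numerics; equivalence is behavioral (agreement on decisions,
  enrichment of informative voxels).
- Mauchly's test requires more subjects than contrast dimensions; for
  effects where the covariance is singular the test is reported as NaN
  and no correction is applied.
- The epochal planted-signal model is one of many time courses
  compatible with the design; amplitudes are in arbitrary signal units
  and calibrated by the probabilities they induce, not by physiology.
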