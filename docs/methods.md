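# Methods

This note records the modeling choices behind `sleepreact`: what is
computed, under which assumptions, which knobs matter, and what the
synthetic benchmark does and does not establish.

## Classifier

**Model.** A linear-chain CRF over five brain states with transition
weights λ (S×S) and per-state linear observation weights μ (S×(N+1)).
The state feature functions are realized as per-state weight vectors over
the N ROI features plus a bias: scalar state weights cannot classify an
ROI vector, so μ_s is a vector by construction. The conditional
probability and the training objective are the standard Gibbs form and
penalized conditional log-likelihood; the penalty is l2 on all free
parameters (bias included), default `l2 = 1e-3`, chosen for numerical
stability on near-separable synthetic data. `l2 = 0` is supported.

**Uniform transitions.** Sleep decoding holds the transition features
constant and uniform, encoded as λ ≡ 0 (any constant is equivalent after
normalization). The chain then factorizes: log Z(x) = Σ_t logsumexp_s
score_ts, posterior marginals are per-scan softmaxes, and training is
exactly multinomial logistic regression — the implementation exploits
this with a pooled-matrix fast path, while the general forward-backward
and Viterbi recursions (log space throughout) serve arbitrary λ. Both
routes are cross-checked against brute-force enumeration in the tests.

**Per-volume likelihood.** The continuous 0–1 per-scan value reported for
each state is the posterior marginal from forward-backward, not the
Viterbi path (a hard path carries no graded evidence). Both outputs are
exposed.

**Optimization.** L-BFGS on the mean per-scan penalized negative
log-likelihood (same optimum as the summed objective; scaling makes the
gradient tolerance meaningful regardless of cohort size). Convergence:
projected-gradient max-norm below 1e-5 or 500 iterations; a fit whose
final gradient norm exceeds 100× the tolerance raises an error carrying
the last iterate. Model initialization is a tiny seeded Gaussian; the
l2-regularized objective is strictly convex, so the seed is immaterial to
the optimum.

**Standardization.** Features are z-scored per ROI with statistics pooled
over the *training* subjects; the same statistics are applied to held-out
and sleep data (a switch allows own-stats scoring). Zero-variance ROIs
become all-zero columns with a warning.

**Cross-validation.** Validation holds out whole subjects (one subject =
one session per fold); the alternative reading, holding out one run,
would test within-subject generalization instead and is not implemented.
Scans from the won (rewarded) block and its trailing rest are excluded
from training everywhere, so the reward outcome itself cannot leak into
the Reward-state pattern.

## Design and labeling

Scans are assigned to blocks by onset within half-open intervals
[onset, onset + duration): boundary-coincident scans belong to the later
block. Labels are not shifted for hemodynamic lag by default — the HRF
shapes the features, and training on block timing matches the block-design
convention — but `shift_labels` provides an integer scan delay for
sensitivity analyses. The pseudo-random game order forbids more than two
consecutive blocks of the same game and places the to-be-won game last.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, at
the study's nominal dimensions; defaults are the study conditions where
stated and calibration choices where not.

- **Game session:** 8 blocks per game × 60 s, 3-s pre-cues, 90-s rests,
  TR 2.1 s (≈ 1166 scans over two runs). BOLD = state boxcars convolved
  with a canonical double-gamma HRF (gamma shapes 6 and 16, undershoot
  ratio 1/6, normalized to unit sum so a sustained block plateaus at the
  pattern amplitude) times an S×58 pattern matrix, plus AR(1) Gaussian
  noise (marginal sd 1.0, lag-1 coefficient 0.3). Game patterns have unit
  RMS amplitude per ROI (SNR chosen so leave-one-subject-out accuracy
  sits near 0.9, comfortably above the 0.76 floor being tested); pre-cue
  patterns are faint (amplitude 0.25), which is what makes the trained
  classifier absorb pre-states into Rest, as the real classifier does.
  Patterns are shared across the cohort with per-subject jitter (sd 0.1).
- **Hypnogram:** first-order Markov chain over {W, N1, N2, N3} at 20-s
  epochs, resampled until ≥ 10 min of N3 (and all four stages) are
  present; the default chain descends into sustained N3 within 10–15 min
  of a 60-min record.
- **Sleep session:** reactivation events start independently at each N3
  scan with probability rate·TR/60 (default 3 events/min of N3), last 3
  scans, and inject the Reward game's pattern scaled by a per-subject
  amplitude (base 1.0 × a subject factor with sd 0.5, truncated at 0 —
  subjects genuinely differ in reactivation strength, and this
  between-subject spread is the signal the memory correlation recovers).
  Six log10 band-power series are generated directly on the 2-s Welch
  epoch grid with stage-dependent baselines (delta rising toward N3,
  alpha/beta dominating wake, sigma peaking in N2) plus AR(1) noise; the
  low-delta series is additionally elevated around events in proportion
  to `delta_coupling` (default 1.0), sharing the HRF time course for
  simplicity. Hippocampus and VTA channels receive the event response
  with gains 1.0 and 0.7 plus noise. A raw-EEG path (band-limited noise
  mixtures) exists to exercise the spectral estimator itself.
- **Memory:** the expected fraction of exactly replaced faces and the
  expected shortage of the maze distance both increase linearly with
  coupling × reactivation strength (coupling default 1.0, placement noise
  sd 0.1, baseline accuracy 0.25, baseline maze fraction 0.85 of the map
  diameter — kept off the clipping boundaries so null cohorts retain
  variance). The maze is a random spanning-tree corridor maze on a 7×7
  grid standing in for the unpublished game map.

What the generator does **not** emulate: physiological noise and motion,
spatially correlated ROI noise, spindles/K-complexes or any raw-EEG
microstructure, REM sleep, scanner drift, inter-session pattern drift.
Passing tests therefore demonstrate that the pipeline recovers the
encoded effects under idealized noise — not that the effects are
detectable in arbitrary real data.

## Spectral estimator

One Hamming-windowed periodogram per 4-s epoch, epochs advancing by 2 s;
band power is the in-band *integrated* power (density summed × bin width),
then log10. Integration (rather than mean density) makes white-noise band
powers scale with bandwidth, the property the sanity checks pin down;
the choice is documented here because the alternative (mean density) is
equally defensible on its own. Band edges are lower-inclusive,
upper-exclusive. Artifact handling is a caller-supplied boolean mask
(epochs touching masked samples are dropped); no artifact detection is
implemented. Resampling to scan times is linear interpolation with
constant extrapolation at the edges.

## Sleep-stage aggregation and couplings

Each scan takes the stage of the 20-s epoch containing its onset (same
half-open convention as block labeling). Stages absent from a hypnogram
are flagged missing, never zero-filled. Likelihood-band coupling uses
Spearman rho with the Fisher z transform (|rho| clamped at 1 − 1e-7);
seed-region coupling uses Pearson rho. The voxelwise regression +
small-volume-corrected conjunction of the original analysis is replaced
by ROI-level OLS (Face, Maze, Rest likelihood columns + intercept;
pre-states excluded for their rarity; optional HRF convolution of the
regressors, off by default) with a set-intersection conjunction — the
same mathematical object at the artifact's spatial resolution.

The per-subject reactivation measure correlated with memory is the mean
N3 activity of the wake-defined task network (ROIs with wake-regression
t > 3 for the won game's contrast). Mean network activity integrates both
how strongly and how often the pattern re-expresses; a regression beta
alone captures only amplitude-per-occurrence and is nearly uninformative
about event frequency. The wake definition keeps the measure defined even
when sleep reactivation is weak or absent (the conjunction network can be
empty under the null).

## Statistics

Balanced univariate repeated-measures ANOVA with subject error strata,
supporting any number of within-subject factors and at most one
between-subjects factor (split-plot), computed by the classical
cell-total decomposition and verified against pingouin/statsmodels to
1e-10. No sphericity correction by default (matching the integer degrees
of freedom convention); Greenhouse-Geisser is available per within
effect. Planned comparisons are paired contrasts with F = t²(paired),
two-sided, as are all tests. Spearman p-values use exact permutation for
n ≤ 10 and the t approximation otherwise.

**Known limitation — interaction calibration.** On null generator data
the state × stage interaction of the uncorrected univariate ANOVA rejects
at ≈ 0.12 instead of 0.05: decoded likelihoods are compositional (rows
sum to 1) and strongly non-spherical. The Greenhouse-Geisser option is
conservative here (≈ 0.01). The planned paired contrast — the inference
the headline claim rests on — is correctly calibrated (≈ 0.03–0.05), as
is the memory-correlation permutation test; both are verified by 500-run
null simulations in the test suite. Conclusions about interactions on
likelihood data should use the corrected p or a contrast-based follow-up.

## Problem sizes in the test suite

The deep end-to-end checks run at the study's nominal dimensions
(18-subject game cohort for classifier validation; 25 cohorts of 13
subjects for directional recovery; 50 single-subject runs for the
coupling directions). Type-I calibration uses 500 reduced-dimension null
runs (8 subjects, 12 ROIs, 4 blocks/game, 30-min sleep) — type-I error of
a paired t and a permutation test does not depend on these sizes, which
are chosen so the calibration is exact rather than a spot check. Unit
tests use small fixtures throughout.

## Determinism

Every stochastic component draws from named substreams
(`SeedSequence([master, tags...])`) of one master seed; identical
configurations produce byte-identical result bundles, and every emitted
file is tied to a sha256 config hash in the bundle manifest.
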