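# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `srmap`.

## Design and geometry

Eight dot locations sit on a circle of radius 7 dva, at polar angles
22.5° + k·45° measured clockwise from the vertical meridian.  A sequence is
built from a starting location by three rules — B opposite A, C 90°
clockwise from B, D opposite C — giving exactly eight sequences, one per
start.  Every sequence stimulates each quadrant once, never uses adjacent
(45°) locations, and has the pairwise chord-distance multiset
{9.9 ×4, 14.0 ×2} dva; the temporally adjacent pair A-B is the spatially
maximal pair, which is what makes temporal and spatial tuning empirically
distinguishable.

Main-task runs hold 192 trials (128 full sequences, 64 partial, 16 per
partial type), with every partial trial flanked by full trials and 52 full
trials per run carrying the delayed last dot (ISI 170 ms instead of 17 ms;
full-sequence span 451 ms).  Partial-trial placement is sampled *exactly
uniformly* over the constraint set by a gap transform (choose 64 of 127
slots), rather than by rejection shuffling: with 64 non-adjacent interior
positions among 192 trials the acceptance probability of a random shuffle
is vanishingly small, while the transform is bijective onto the valid
placements, deterministic, and seedable.

Inter-trial intervals follow a shifted exponential truncated at 10.9 s with
minimum 2 s.  The design states the mean (3.72 s), not the rate, so the
scale β is obtained by root-finding on the closed-form truncated mean
m(β) = min + β − (max−min)/(e^{(max−min)/β} − 1); the root is β ≈ 1.78 s,
and sampling uses the inverse CDF of the truncated law (no rejection).
Feasible targets lie strictly between the minimum and the midpoint
(min+max)/2; anything else raises.

The localizer is read as eight cycles of eight 13.5 s blocks with one 15 s
rest closing each cycle (64 blocks + 8 rests = 984 s ≈ 16.4 min, matching
the stated session length); each location opens exactly one cycle, the run
start counting as a rest-like boundary.  The alternative reading (a rest
after every block) would give a far longer run and is not used.

## SR, CO and H0 models

The sequence chain is a 4-state transition matrix T with one-hot rows A→B,
B→C, C→D and a terminal all-zero row D (a cyclic D→A variant is available
but off by default; trials end after D).  The successor matrix is
M = (I − γT)⁻¹, computed by direct inversion and equal to the finite
Neumann sum for the nilpotent chain.  Model predictions for the 4×4
activity profile (partial-trial type × sequence location) are

- SR: a·M(γ) — graded, forward-only anticipation;
- CO: a·(identity + ω off-diagonal) — non-directional, ungraded;
- H0: a·identity — stimulation only.

The multiplicative scale *a* maps unit predictions onto BOLD betas and is
shared across all 16 cells, so SR and CO have two free parameters and H0
one.  ω may be negative (predecessor suppression is a meaningful
sub-baseline value).  All 16 cells enter the fit, the diagonal representing
bottom-up stimulation.

Fitting minimizes the RMSE over the 16 cells.  γ is optimized on a
deterministic 0.01 grid over [0, 1] with *a* solved in closed form at each
grid point, followed by bounded local refinement (tolerance 1e-7) — the
1-D landscape is smooth, and the procedure is exactly reproducible.  The CO
model is linear in (a, a·ω) and is solved exactly by least squares (with
a ≥ 0 clamped); H0's scale is the mean diagonal.  Models are compared by
RMSE and by the Gaussian-error BIC, n·ln(RSS/n) + k·ln(n), which encodes
the parameter-count difference; the group-level winner is the lowest mean
BIC, with paired t tests on the per-subject RMSEs.  Note the fits are not
invariant to adding a constant to all cells (there is deliberately no
intercept — the null model must mean "no off-diagonal activity"); profiles
are therefore always control-subtracted first, and the
successor-minus-predecessor contrast *is* invariant to per-condition
shifts.

The exponential-decay summary fit (a·γ^lag to the mean activity at lags
+1..+3) uses the same grid-plus-refinement scheme at step 1e-3 and is
checked against a 1e-4 brute-force grid oracle in the tests.

## Synthetic cohorts

The generator emulates the study conditions: TR 1.5 s, three main-task runs
of 192 trials, one 984 s localizer, cohorts of 35 subjects with sequence
assignment counterbalanced across the eight starts (⌊n/8⌋ or ⌈n/8⌉ each),
and per-subject seeds spawned deterministically from the cohort seed.

V1 is modeled as eight retinotopic subpopulations (default 8 voxels each).
Neural events are impulses at trial onset — the 117 ms within-sequence dot
offsets are two orders of magnitude below the sampling resolution and are
absorbed into the trial impulse, which keeps the simulator in exact
register with the trial-onset GLM regressors (noiseless data are recovered
to machine precision).  Full trials drive all four sequence locations at
the stimulus amplitude; partial trials drive the shown location at full
amplitude and the omitted sequence locations per the generative row (SR row
of M, CO constant ω, H0 zeros; predecessor amplitude configurable,
default 0).  Cross-location spatial bleed is Gaussian in chord distance
with scale 1.5 dva, making neighbor (5.4 dva) bleed ≈ 0.2% — "minimal
spreading", and small enough not to bias the discount-factor recovery
through the control-location baseline.  Localizer blocks are 13.5 s
boxcars.  Signals are convolved on a 0.1 s grid with a unit-peak gamma HRF
and sampled at volume times; white Gaussian noise (default SD 1.0 in beta
units, against stimulus amplitude 1.0) is added per voxel and volume.  The
default convolution basis is the single-gamma HRF that the GLM also uses;
the double-gamma canonical form (peak ≈ 5.0 s, undershoot at 16 s, ratio
1/6) is available and is the basis of the decoding time-course fit.

The hippocampus is modeled as random multivoxel patterns, one per location
(default 50 voxels, pattern amplitude 0.05).  Main-task trials drive the
patterns with the same generative row as V1.  During the localizer,
stimulating a sequence location drives its own pattern at amplitude 1 and
its sequence-mates along the configured tuning law — a linear fade from the
stimulated item, 1 + slope·|lag| (default slope −0.25/step) for temporal
tuning, 1 + slope·chord-distance (default −0.06/dva) for spatial tuning,
or nothing ("none").  The fade is continuous through the stimulated item
itself so that the ground truth actually lies in the linear model family
being compared.  The default pattern amplitude deliberately puts localizer
decoding well below ceiling: in the saturated regime the classifier's
softmax compresses the graded structure into a near-identity evidence
matrix and no linear tuning model can describe it, whereas the study's own
hippocampal decoding operated just above chance.  The synthetic SNR
defaults are calibration choices: they are set so that the group-level
successor-versus-predecessor tests at n = 35 reach the expected direction
and the recovery properties in the acceptance tests hold, since the
original effect sizes in beta units are not published.

A profile-level fast path (`simulate_profiles`) draws 4×4 activity
profiles directly as model prediction + cell-level Gaussian noise (default
SD 0.05, matching the beta-level noise the full pipeline propagates at
default SNR) for large model-recovery studies.

What the generator does **not** emulate: anatomical geometry, head motion
and physiological noise (the GLM interface accepts nuisance regressors, but
none are simulated), autocorrelated noise (an AR(1) switch was considered
and left out of scope), scanner drift, and hippocampal pattern similarity
that is not sequence-induced.  Passing tests therefore demonstrate the
*estimators'* correctness and identifiability under the stated generative
model, not robustness to real-data artifacts.

## GLM and ROI analysis

Design matrices convolve condition events with the single-gamma basis on
the same 0.1 s grid as the simulator; nuisance columns pass through
unconvolved.  Estimation is voxel-wise OLS; contrast t statistics use the
analytic covariance and map to z through the normal quantile of the t CDF
(numerically stabilized in the tails).  Voxel selection follows the
preregistered rule: top-n voxels per location by one-versus-rest z
(n = 25 in the original, which presumes thousands of candidate voxels; the
synthetic default is the simulated subpopulation size), removal of voxels
appearing in more than one location's list, and trimming of all sets to
the common minimum size by dropping the lowest-z voxels.  Activity
profiles subtract the mean of the four control-location ROIs from each
sequence-location ROI, per condition, and betas are averaged across runs
unweighted.

## Decoding

Voxel time courses are Savitzky-Golay filtered per run (window 5 TRs,
order 3, nearest-sample edge padding — the boundary mode is not stated in
the original and nearest padding avoids edge ringing) and z-scored per
voxel per run.  Trial features average volumes whose trial-locked times
fall inclusively within 3–13.5 s (localizer blocks; 8 volumes) or 3–6 s
(main-task events; 3 volumes).  The decoder is a multinomial logistic
regression, L2 penalty, C = 1, deterministic LBFGS solver.  Accuracy is
leave-one-out within the localizer against the 1/8 chance level.
Within-localizer classifier evidence is taken from stratified 8-fold
cross-validated probabilities (leave-one-out probabilities would retrain 64
models per subject for no measurable benefit; the fold structure is seeded
per subject).  Main-task evidence applies the localizer-trained model to
partial trials only; per trial, the mean control-location evidence is
subtracted from the sequence-location evidence before averaging into
successor (lag > 0) and predecessor (lag < 0) means.

The time-resolved analysis applies the same localizer-trained model to the
single volume nearest onset + offset for each offset 0, 1.5, …, 13.5 s,
dropping (once, for all offsets) trials without a full post-onset volume
window.  The group-mean successor-minus-predecessor time course is fitted
with amplitude·hrf(t − latency), latency ∈ [−2, 8] s (bounded to one
trial's window), by a 0.05 s latency grid with closed-form amplitude plus
local refinement; the time-to-peak is the latency plus the canonical HRF's
dense-grid argmax.  A non-positive fitted amplitude is reported as "no
transient" (None).

## Coactivation tuning

The 4×4 coactivation matrix averages, per stimulated sequence item, the
control-subtracted evidence at the four sequence locations (localizer
trials at control locations are not rows of the matrix but provide the
baseline).  The baseline subtraction is essential: raw class probabilities
carry a positive uncertainty floor over all eight classes, and against
that floor a strict no-coactivation null (off-diagonal exactly zero) could
never win a comparison even when the ground truth has no coactivation.
Under uniform evidence every cell is zero.

Four models are fitted to all 16 cells by least squares: temporal
(intercept + slope·|lag|), spatial (intercept + slope·chord-distance), SR
(scale·γ^lag forward-only, γ on the usual grid), and H0 (one diagonal
amplitude).  Temporal and spatial distances enter the linear models
unsigned — the fading in the data is symmetric in past and future — while
the SR variant is forward-only; the SR tuning form is the 2-parameter
forward decay (the original parameterization is not printed).  Comparison
is by group-mean BIC with k = 2/2/2/1.

## Group statistics

Two-sided throughout, uncorrected.  One-sample and paired t tests are the
workhorses; the signed-rank test (statistic W⁺, exact null for n ≤ 25
without ties or zeros, normal approximation otherwise) is reported
alongside the t test wherever a "non-parametric" alternative is wanted, and
Spearman correlation handles across-subject brain-behavior relations.
Degenerate paired differences resolve by their mean (equal samples: t = 0,
p = 1).

## Problem sizes

The test and acceptance batteries use: cohorts of 35 for discount-factor
recovery (4 γ values), model selection (20 seeded cohorts per generative
model, profile-level) and tuning identification (20 seeded localizer-only
cohorts per tuning truth); 8-subject cohorts over 5 replicates for the full
simulate→GLM→fit model-recovery check; and 100,000 draws for the ITI mean.
These sizes were chosen so the entire suite completes in a few minutes on
one CPU while keeping every identification margin comfortably away from
its threshold.

## Known limitations

- The voxel-selection rule with the original n = 25 is only meaningful when
  there are many more candidate voxels than 25 per location; at synthetic
  ROI sizes the per-location subpopulation size is the sensible top-n.
- Model fits assume a shared multiplicative scale and no intercept; if real
  profiles carried an additive offset that control subtraction does not
  remove, γ estimates would be biased (documented, not modeled).
- The decoder's evidence is only an ordinal readout of drive; the tuning
  comparison is valid in the near-linear (low-SNR) regime and degrades at
  ceiling accuracy, where evidence saturates.
- Onset times absorb response windows into the ITI; no stimulus rendering,
  eye-tracking, or behavioral feedback is modeled.
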