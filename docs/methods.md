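# Methods

This note documents the models, procedures and numerical conventions
implemented in `pev`, the choices made where the design was genuinely open,
and what the synthetic-data tests do and do not establish about real data.

## Trial structure and the synthetic generator

The generator emulates a passive audio-tactile protocol at a 30 Hz imaging
frame rate. Each trial is 8 s (240 frames): a 2 s baseline, a 50 ms start
cue, 1 s until sound onset, a 1 s sound, then a whisker stimulus at
intensity 10–90% (in steps that the hardware could deliver: {10, 30, 50, 70,
90}). Trials are stored back to back; the inter-trial interval is omitted
because no computation here uses it. An experiment is a *pairing* session
(default 160–200 trials; sound A and sound B each paired with an intensity
set) followed by two *interleaved* sessions (200 trials each) in which
exactly `round(0.15 × n_trials)` trials — positions drawn uniformly without
replacement — replace one sound's paired intensity with a mismatch intensity
(90% for positive, 10% for negative mismatches). Variable pairings draw the
intensity i.i.d. uniform from their set on every matched trial.

Each neuron carries a ground-truth class: mismatch-responsive in session 1,
session 2, or both; matched-responsive; pairing-responsive; negatively
modulated; or null. Per interleaved session the mismatch-responsive
prevalence defaults to 10% of the population (configurable in the 8–12%
band). Responsive neurons receive a calcium-like transient locked to the
whisker onset of their preferred trial type: a difference-of-exponentials
kernel (rise 50 ms, decay 400 ms — generator conventions resembling a fast
indicator, not measured values) normalised so its mean over the first second
equals 1, which makes a planted amplitude *a* recoverable as a windowed
response of *a* (exactly at zero noise). Raw fluorescence is
`F = B·(1 + ΔF/F_planted) + B·noise_sd·ε` with per-neuron baseline `B`
uniform in 100 ± 20 a.u. and i.i.d. Gaussian frame noise (`noise_sd` is a
ΔF/F fraction; default 0.02, a generator convention since single-neuron
noise levels are not otherwise constrained — it is exposed in every config).

What the generator deliberately does **not** model: photon/shot noise,
neuropil contamination, motion, slow drift, correlated noise across neurons,
behavioural (whisker-position) covariates, spike-to-calcium nonlinearity,
habituation across sessions. Consequently, classifier sensitivity and
false-positive rates measured on this data characterise the *statistical
procedure* under clean assumptions, not expected performance on real
recordings, where all of the above inflate the null's tails.

## ΔF/F and windowed responses

ΔF/F = (F − F₀)/F₀, with F₀ the mean of the 1 s (30-frame) window
immediately before the start cue, computed **per trial**. Windows are
half-open frame ranges `[start, start + n)`; seconds convert to frames by
round-half-up, so the late-window offset 0.65 s → 20 frames at 30 Hz (the
choice is logged in the window metadata and asserted in tests). The scalar
trial response is the mean ΔF/F over the 1 s window at the configured offset
from stimulus onset minus the mean over the 1 s immediately before stimulus
onset; the late window keeps that same pre-stimulus baseline. Window means
are computed by summing each window independently (not as cumulative-sum
differences), so identical window contents give bit-identical means and a
constant trace yields exactly zero statistics. Population-average traces are
per-neuron trial averages, baseline-corrected by their 1 s pre-stimulus
mean, then averaged across neurons — the pre-stimulus second of the result
is zero by construction.

## Responsiveness classification

Each neuron's single-trial responses on a trial type are compared against
its own null of 1000 window statistics placed uniformly at random positions
of the session's ΔF/F trace (each statistic computed exactly like a trial
response). Positions may fall anywhere that leaves room for the window and
its 1 s baseline — including real stimulus windows, the most literal reading
of "random events"; a flag restricts placement to non-event frames for
sensitivity analyses. Significance is a two-sided Mann–Whitney U test at
α = 0.05 per neuron with **no multiple-testing correction across neurons**
(deliberately mirroring the per-neuron criterion of the analysis this
reproduces); the sign of (median response − median null) separates
positively from negatively modulated neurons, and only positive ones are
kept downstream. The scalar path uses the exact U distribution below 25
total observations and the tie-corrected normal approximation above; the
vectorised bulk path always uses the normal approximation (appropriate
against a 1000-value null). All-tied inputs return `not_responsive` with
p = 1 rather than an error.

The shuffled-population check draws, many times, a random 8–12% of the
neurons, averages one null value per drawn neuron, and reports the
2.5th/97.5th percentiles of those means. A measured mismatch-population mean
outside this interval cannot plausibly be a chance alignment of null
activity.

## Group statistics

Mismatch responses of the two interleaved sessions are compared with the
two-sided Wilcoxon–Mann–Whitney test on **non-overlapping** neurons (those
responsive in only one session) and with the two-sided Wilcoxon signed-rank
test on **overlapping** neurons when at least two exist (with one or zero,
the paired test is skipped with a logged notice). No normality is assumed
anywhere. The permutation robustness check shuffles group labels **within
mouse** and uses the difference of group means as the statistic with
`p = (1 + #{|T_perm| ≥ |T_obs|}) / (n_perm + 1)`; both the statistic and the
stratification are configurable because the procedure is not pinned down
further by its source. Mixed-effects model fits are out of scope — the
permutation test is the in-scope nested-structure check.

## Circuit models

The four models and their equations are in the README. Fixed parameters:
E(s) = 5, positive-mismatch stimulus 9, negative-mismatch stimulus 1,
σ₀² = 1 (keeps the divisive terms finite), σₛ = 0 (fixed) or 1.6 (variable;
the population SD of the uniform {3, 5, 7} intensity representation,
√(8/3) ≈ 1.63). At σₛ = 0 all four models reduce to the same expression —
exactly, not approximately — so only the variable condition discriminates.

Each circuit carries two positive weights, `w_stim` on the stimulus term and
`w_pred` on the prediction term; the source material says only that
"synaptic weights" were sampled per circuit, so a single-gain alternative
(one weight scaling the rectified unweighted difference) is available behind
`weight_mode="single_gain"`. Weights are drawn log-normally with log-SD 1.0
("shape" in the scipy sense; the pre-normalisation scale is irrelevant) and
the whole simulated population — 50 pPE plus 50 nPE circuits — is rescaled
jointly so its single largest weight is exactly 0.05. Weights are sampled
once and reused across the fixed and variable conditions, so each circuit
experiences both.

The optional nPE modulation multiplies negative-error activity by a
variability factor. The literal reading (×σₛ) zeroes all fixed-condition nPE
activity, which is hard to reconcile with large fixed-condition negative
mismatch responses in data; since the intended factor is ambiguous, all
three readings are implemented (`sigma_s`, `sigma_total` = σ,
`sigma_s_floor1` = max(σₛ, 1)) and `sigma_s` — the default — emits a loud
warning about the zeroing. Simulation outputs carry both the modulated and
pre-modulation activities so direction-of-effect properties can be checked
on the un-modulated quantity.

## Model selection and recovery

Each candidate model contributes four condition cells (pPE/nPE × fixed/
variable), each compared to the matching reference distribution with a
two-sided two-sample KS test. The default selection rule operationalises
"consistent with the data in every condition": prefer models with zero
rejected cells at α, break ties by larger minimum p, then smaller mean KS
statistic, then model id; the rule is recorded in the report and a
Fisher-combined-p alternative is selectable. Comparisons default to raw
values; `align="scale"` multiplies each model's pooled samples by one factor
matching its pooled mean to the reference's, for references in ΔF/F % whose
scale model activity (≤ 0.05 × ~32 ≈ 1.6) does not reach.

Model recovery validates the procedure: per replicate, a reference
population is simulated from a generator model with fresh weights, candidate
populations are simulated independently for all four models, and the winner
is recorded; frequencies over replicates form a confusion matrix. Two
structural facts bound what recovery can achieve at n = 50 circuits. First,
P and I share the pPE equations and S and D share theirs (as do the pairs
P/D and S/I for nPE), so each pairwise discrimination rests on at most two
cells and P-vs-D / S-vs-I on a single one. Second, max-normalising
log-normal weights pins the largest weight but leaves the *bulk* scale of
each finite population jittering between draws, which both triggers false
KS rejections of the true model and occasionally masks the σ² ≈ 3.56 scale
separation between model groups. Diagonal dominance is therefore the pass
criterion for individual models, while the {P, I} vs {S, D} group
separation — the scientifically meaningful distinction, since the groups
differ in whether the variable-condition positive error explodes — sits
around 0.9 at the default parameters (recomputed by the acceptance script).

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the binomial
error of each estimated rate small relative to its assertion band: 2000
signal-free neurons for the false-positive rate, 30 planted neurons × 30
mismatch trials for sensitivity, 1000 repeats for KS null calibration, 100
replicates (25 per generator) for recovery, 20 weight populations for the
direction-of-effect sweep. The end-to-end pipeline default is 120 neurons
and 160/200/200-trial sessions. Determinism: every stochastic stage takes an
explicit seed (numpy `default_rng` / `SeedSequence`); run manifests hash
artifact contents (HDF5 files are hashed over datasets and attributes rather
than raw bytes, which carry library metadata), and identical configs yield
identical manifests. Boxplots use the convention: median line, 25th/75th
percentile box, whiskers to the extreme observations within 1.5 *standard
deviations* of the mean (not the usual IQR rule), outliers crossed.

## Known limitations

- The generator's noise model is white and Gaussian; real two-photon noise
  is heteroscedastic and temporally correlated, so real-data false-positive
  rates will exceed the clean-data calibration measured here.
- The shuffle null drawn from a trace that contains stimulus-evoked
  transients is slightly inflated for strongly driven populations; the
  event-exclusion flag quantifies this.
- Model selection treats neurons as exchangeable samples (pooled across
  animals); per-mouse aggregation is not implemented.
- KS-based selection is distributional only — no likelihoods, no parameter
  fitting; conclusions are about consistency, not posterior evidence.
- With `npe_modulation="sigma_s"` the fixed-condition nPE cell is degenerate
  (all zeros), so it carries no information in selection.
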