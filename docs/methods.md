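# Methods

`eegresp` implements an analysis of resting-state EEG as a biomarker of
response to transcranial direct current stimulation (tDCS) in PTSD. Two
questions drive the design: *did* treatment change band-limited cortical
power differently in responders and non-responders (group statistics on
pre-to-post change rates), and *can* responder status be predicted from
pre-treatment power alone (cross-validated SVM with channel selection)?
Because no raw clinical recordings are distributable, the package ships a
synthetic cohort generator that reproduces the acquisition geometry and
plants controllable group structure, so every stage is testable end to end.

## Responder labeling

Subjects carry CAPS-5-like totals: severity (Sev) and symptom count (Sx),
before and after treatment. A subject is a **responder** when the fractional
improvement `(pre − post) / pre` strictly exceeds 50% on *both* totals.
The conjunctive reading is a deliberate choice where either-scale readings
would also be defensible; `label_responders(rule="sev")` switches to a
severity-only rule. Subjects with a zero pre-treatment score have an
undefined improvement fraction and are excluded with a logged warning.

## Signal conditioning

Recordings are 62-channel (extended 10-20 montage), 1,000 Hz, 150 s
eyes-closed segments. The conditioning chain, in fixed order and recorded in
each recording's provenance:

1. **Common-average re-reference** — subtract the instantaneous
   across-channel mean.
2. **Baseline removal** — subtract each channel's temporal mean.
3. **Band-pass** 1–50 Hz Butterworth. The order is not dictated by the
   analysis itself; we use order 4 applied forward–backward
   (`sosfiltfilt`), i.e. zero phase and a squared magnitude response —
   common EEG practice. Both order and cutoffs are arguments.
4. **Segmentation** — the leading contiguous window of the target length
   (configurable offset). Placement within a longer recording is otherwise
   arbitrary; leading-window is the reproducible default.

ICA-based artifact rejection is out of scope: it is a human-in-the-loop
step, and the synthetic generator never injects artifacts.

## Spectral features

PSDs are estimated with Welch's method: 1 s segments, 50% overlap, Hamming
window, one-sided density normalization, no per-segment detrending (the
chain has already demeaned the signal). A 150 s recording therefore averages
299 periodograms on a 1 Hz grid. **Band power** is the *mean* PSD density
(µV²/Hz) over in-band bins — not the integral — which matches the sub-unity
magnitudes this literature reports for single channels; an integral variant
would only rescale bands by their widths. Bands are half-open, `[f_low,
f_high)`, so the five defaults — delta 1–4, theta 4–8, low alpha 8–10, high
alpha 10–12, beta 12–30 Hz — never double-count a shared edge bin; beta's
30 Hz edge is excluded.

Parseval consistency (integrated PSD ≈ variance, within 3%) and scaling
equivariance (k·x ⇒ k²·PSD) are enforced by tests.

## Change-rate statistics

The treatment-effect statistic per subject, channel and band is

    P_change = (P_pre − P_post) / P_pre

positive when power decreased after treatment, and invariant to common
rescaling of both sessions. Entries with nonpositive `P_pre` are flagged
invalid and excluded.

Channel-wise responder vs non-responder comparisons are gated on
assumptions, mirroring small-sample practice: a Kolmogorov–Smirnov normality
check on each group — implemented as the Lilliefors variant, since the
normal's mean and SD are estimated from the sample — then Levene's test
(mean-centered) for variance equality, all at α = 0.05. Normal data take a
two-sample t (pooled df, or Welch–Satterthwaite fractional df when variances
differ); otherwise a two-sided Mann–Whitney U with tie correction. Groups
smaller than 4 cannot support the Lilliefors test and are routed to the rank
test. Channels with zero variance in both groups are degenerate and excluded
with a note.

P-values are Benjamini–Hochberg adjusted **within one band across its
62 channels** (310 global tests would be the alternative family; per-band is
our default and configurable by calling `fdr_adjust` over any family). The
BH implementation is the plain step-up with monotonicity enforcement and is
tested against an independent brute-force oracle and statsmodels.

## Classification

Prediction uses pre-treatment band powers only. The classifier is an
RBF-kernel SVM under stratified 5-fold cross-validation with responders
(the minority class) as positives:

* **Nested hyperparameter search.** Within each training fold, (C, γ) are
  chosen by an inner stratified-CV grid search over logarithmic decades
  {10⁻³ … 10²} (the searched range 0.001–100; spacing is ours, since only
  the range is fixed by the problem), scored by inner accuracy with a
  deterministic tie-break toward smallest C then smallest γ. A naive
  variant — picking hyperparameters once on all data and then
  cross-validating — would leak test information into model selection; the
  nested scheme is the honest default here.
* **Scaling discipline.** Features are standardized with training-fold
  statistics only.
* **Pooled scoring.** Held-out decision values from all folds are pooled
  into one ROC (more stable at n = 48 than averaging five 9–10-subject
  ROCs). AUC is the rank statistic of the pooled scores; sensitivity and
  specificity are taken at decision threshold 0, and balanced accuracy is
  their mean, exactly.
* Folds come from a deterministic round-robin stratified splitter keyed by
  `cv_seed`, so identical specs give identical results.

**Single-channel screen**: one d = 1 cross-validated SVM per channel.
**Forward channel selection**: step 1 keeps the AUC-best single channel;
every later step tentatively adds each unused channel, re-runs the full
nested CV, and commits the maximizer (ties resolve to the earliest channel
in montage order). The hyperparameter grid is re-searched at every tentative
addition — costlier than freezing parameters, but cleaner. The reported
subset is the earliest prefix attaining the maximal AUC. `max_steps`
truncates the search; the default continues until all channels are used.

**Permutation significance** of a fixed channel subset: labels are shuffled
`n_perm` times (default 1,000) and the *entire* fitting procedure — folds,
standardization, inner grid search — is re-run per draw, so the null
distribution reflects everything the analyst did. The p-value uses the
add-one estimator `p = (1 + #{null ≥ observed}) / (n_perm + 1)`, with floor
`1/(n_perm + 1)`. A "cluster-based" variant is sometimes named in this
context but has no defined cluster-forming statistic for a classifier AUC;
the plain label-permutation test is the interpretation implemented here.

## Synthetic cohorts

Each subject-session recording is a stationary Gaussian process with
one-sided PSD

    S(f) = Σ_b P_b · e(group, session, channel, b) · u · v · w  +  A²/f

with per-band baselines `P_b`, configured multiplicative effect factors `e`,
and lognormal variability factors: `u` between subjects (trait, shared by
both sessions; log-SD `subject_sd` = 0.30), `v` between sessions within a
subject (state; `session_sd` = 0.15), `w` per channel (`channel_sd` = 0.10).
The trait/state split matters: with trait variability alone, pre/post power
ratios would be nearly noiseless (Welch estimation error only) and the group
tests degenerate. `A` is `pink_noise_level` (default 0.2, a weak 1/f floor).

Realizations are synthesized directly in the frequency domain — complex
Gaussian rFFT coefficients scaled to the target density, inverse FFT — which
is distributionally identical to summing band-pass-filtered white-noise
components over the (disjoint) bands, and makes the expected Welch band
power exactly the configured density. The spectrum extends the lowest band's
level down to 0 Hz and the highest band's level 4 Hz past its upper edge
("shoulders"), so Hamming-window smearing at the outer edges does not bias
the realized band means. At interior band edges a level step is smeared
across one bin (≈ midpoint bias on that bin); with 1 s Welch segments this
can bias the narrow 2-bin alpha sub-bands by up to ~5% when neighboring
levels differ strongly, and vanishes as segment length grows — calibration
tests on the sharpest contrasts therefore either isolate a band or use a
finer grid.

Default study conditions: 17 responders vs 31 non-responders; baseline
densities (µV²/Hz, arbitrary units — only relative effects are calibrated,
as no absolute reference scale exists) delta 1.2, theta 0.9, low alpha 1.1,
high alpha 0.9, beta 0.45, an eyes-closed-like profile. Default planted
effects: responders' post-treatment theta/beta power × 0.84,
non-responders' × 1.12 (change-rate group separation of roughly 1.5 SD,
t-statistics near 4–5 at n = 48); session-independent responder offsets in a
few channels (delta × 1.5 at CZ/O1/FC2/FC1/F2, beta × 0.65 at PZ/CP5, theta
× 1.35 at FCZ/POZ/CPZ) make pre-treatment classification possible without
pre/post leakage.

Clinical scores: pre-treatment Sev ≈ N(42, 8²) clipped to [20, 70], Sx ≈
N(14, 3²) clipped to [6, 20]; post scores apply a noisy group-specific
improvement fraction (responder center 0.70, non-responder 0.20, SD 0.08)
clipped away from the 50% boundary and integer-clamped so rounding can never
flip the intended label. Subscale totals (B/C/D/E) are split from the totals
with fixed proportions and never drive labeling.

Random streams are keyed by `(seed, subject index)` with fixed sub-keys for
trait/pre/post/clinical draws, so enlarging a cohort never reshuffles
earlier subjects and pre/post recordings share their trait factors.

What the generator does **not** emulate: eye blinks, muscle and cardiac
artifacts, evoked activity, volume-conduction correlation between channels
(channels are spatially independent here), and non-Gaussian or non-stationary
dynamics. Passing tests therefore demonstrate correctness of the *methods*
under a controlled, honest null/effect model — not clinical performance on
real EEG.

## Numerical and operational choices

* Band edges on the discrete Welch grid are half-open; empty bands error.
* Zero-variance feature columns standardize to zero (SD replaced by 1).
* AUC uses average ranks under ties; degenerate single-class folds raise.
* Heavy simulation studies (selection recovery, permutation calibration) use
  a reduced hyperparameter grid (C ∈ {1, 10}, γ = 0.5, 2 inner folds) and a
  truncated 4-step selection; these sizes are stated in each test and keep
  the nested-CV structure intact.
* The acceptance study runs the full 62-channel, 17 + 31 cohort at 500 Hz /
  60 s — spectrally equivalent for the 1–30 Hz bands, with proportionally
  fewer Welch segments.
* Pipeline outputs are plain CSV/JSON with full double precision; manifests
  echo the config (minus the output path) so a rerun with the same config
  and seed is byte-identical.

## Known limitations

* Greedy forward selection is a wrapper heuristic: channels informative
  only through interactions with no marginal signal (pure XOR) cannot be
  found by any greedy-first procedure; the recovery tests plant structure
  with moderate marginal and strong joint information.
* With 1 s Welch segments the 2-bin alpha sub-bands carry the largest
  band-edge smearing bias (see above).
* Pooled-fold ROC mixes decision scores across folds; scores are comparable
  only because each fold's SVM is trained on standardized features, and the
  alternative (per-fold ROC averaging) is not currently exposed.
* The permutation test fixes the channel subset chosen by forward selection;
  it quantifies the significance of *that model*, not of the selection
  procedure as a whole (re-running selection inside every permutation would
  be the stricter, far costlier variant).
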