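# Methods

`odorbarrel` implements the analysis chain used to ask whether odors
modulate population activity in the whisker region of primary
somatosensory cortex (barrel cortex, wS1): trial-structured ΔF/F₀
preprocessing of two-photon calcium-imaging ROI traces, single-cell
modulation statistics calibrated against a trial-label shuffle null,
whisking/breathing kinematics from band-limited analytic signals, and
population decoding with cross-condition transfer tests. Because the
package is developed and validated entirely on synthetic sessions, this
note spells out the generative model, the analysis conventions, and what
the passing tests do and do not establish about real recordings.

## Stimulation protocol

The default session crosses two grating orientations (0°, 90°) with two
odors (amyl acetate AA, ethyl butyrate EB): four bimodal conditions
(10 repetitions each), each grating alone and each odor alone (20 each),
and a blank (30), i.e. 150 trials in a seeded pseudo-random order. Trials
last 11 s and are imaged at 31.5 Hz; stimuli last 2 s starting at
`stim_onset_s` (default 4 s into the trial). All analysis windows are
half-open `[start, end)` in seconds relative to stimulus onset; the
stimulation epoch is (0, 2) s and the baseline epoch (−2, −1) s.
A multi-odor variant (five monomolecular odors plus binary AA/EB mixtures
encoded as e.g. `AA80:EB20`) supports the 5-class decoding and mixture
categorization analyses. Behavior channels run at 500 Hz (whisker pad,
breathing) and 20 Hz (facial video motion energy).

## Synthetic sessions

**Neural.** Each cell's mean evoked amplitude per condition (in ΔF/F
units) is a sum of: a non-negative tactile response (log-normal across
tactile-responsive cells, median 0.4, shape 0.5) on grating trials; an
orientation-tuning term `±orientation_coef · u` along a random unit
discriminant `u`; a signed odor-modulation effect on odor-bearing trials
(log-normal magnitude, median 0.25, sign set by the enhanced/suppressed
label); and an odor-identity term along per-odor unit loading vectors
placed at a configurable principal angle to `u` (90° = orthogonal
subspace). Mixture conditions combine pure-odor loadings linearly by
their ratios. The field provides no canonical effect-size distribution
for odor modulation; the log-normal is a stand-in chosen to give a
realistic long right tail, and results that depend on its exact shape
should not be over-read.

Amplitudes are convolved with a GCaMP6s-like single-exponential decay
(τ = 1.5 s) applied to a 2-s boxcar, scaled so that the transient's mean
over the stimulation epoch equals the injected amplitude; a cell with
effect +e therefore shows a stimulus-epoch ΔF/F difference of exactly e
after preprocessing in the noiseless case, which makes end-to-end
recovery testable without tolerance gymnastics. The transient outlasts
the 2-s epoch, as calcium transients do. ΔF/F is clipped at −0.95
(fluorescence cannot drop below zero), so very large suppressions
saturate.

Fluorescence is assembled as `F = B + r·F_n_true + B·dff + ε` and
`F_n = F_n_true + ε'`, where `F_n_true` is a neuropil baseline plus a
shared slow fluctuation (Gaussian noise smoothed to a 0.5-s timescale)
and r = 0.7. The ROI thus contains the neuropil signal at exactly the
coefficient the correction subtracts, so `F − 0.7·F_n` recovers
`B(1 + dff)` exactly when noise is zero. White noise (σ = 5 a.u. against
baselines of ~100 a.u.) is added to both channels.

**Orofacial.** Whisker-pad angle is `setpoint + A·sin(φ(t))` with a
default 8-Hz whisking rhythm and sine amplitude 7.5° (so the per-cycle
range of motion is 15°); curvature oscillates in phase and gains a
contact component on grating trials during the stimulation epoch;
breathing pressure is a 6-Hz oscillation with inhalations as negative
deflections. From stimulus onset of odor trials, whisking amplitude and
setpoint, curvature, and breathing amplitude/frequency change by
configurable gains (defaults: whisking ×1.3, setpoint +2°, curvature
×1.2, breathing amplitude ×0.7, frequency ×1 — odors increase whisking
and depress sniff amplitude). Gains of 1 make odor trials statistically
identical to the rest, which is the null used for calibration tests.

**Facial.** Motion energy is a low-rank matrix (smooth temporal
components × orthonormal pixel patterns, geometric energy decay) plus
optional white noise; when odor-informative, each pure odor adds its own
pattern of component amplitudes during the stimulation epoch.

## Preprocessing conventions

Neuropil correction is `F_cor = F − 0.7·F_n`. F₀ is the 8th percentile of
the *corrected* trace per cell per trial, using linear interpolation
between order statistics; the correction-before-normalization order
follows the processing sequence, and the percentile convention is a
documented choice since only "8th percentile" is specified by the
procedure itself. ΔF/F₀ = (F_cor − F₀)/F₀, then the scalar mean over the
(−2, −1) s baseline epoch is subtracted from the whole trial, so every
valid cell/trial has zero baseline mean by construction. Cell/trials
with F₀ ≤ 0 cannot be normalized; they are flagged, excluded from
downstream statistics, and dropped (with a warning) from decoding
features. Note that for strongly suppressed cells the 8th percentile can
land inside the suppressed period, biasing F₀ low; this is a property of
the percentile-baseline method itself, not of the simulation.

## Modulation statistics

Responsiveness is a Kruskal–Wallis test across the conditions of the
stimulus-epoch ΔF/F means (α = 0.05). Odor modulation is a two-sided
Mann–Whitney U between odor-bearing and odor-free trial groups, pooling
different odors within a group; the modulation index is
MI = (m_odor − m_no-odor)/m_no-odor, undefined when the denominator is
~0. Both use `scipy.stats`, which applies the exact U distribution for
small untied samples and the tie-corrected normal approximation with
continuity correction otherwise — this matters, because at the session's
group sizes the test's achievable level is slightly below the nominal 5%
(~4.85% at 40 vs 40 trials, ~4.97% at 40 vs 30 for independent samples),
and the shuffle-calibrated proportions inherit exactly that level.

Flagged proportions are interpreted against a trial-label shuffle null
(default 100 shuffles per session, configurable) rather than a per-cell
multiple-testing correction. One reason this is the right reference and
not a convenience: in the bimodal-vs-grating-only contrast both groups
contain *exactly* balanced orientation compositions, a blocked design
under which the unpaired Mann–Whitney is conservative when cells are
orientation-tuned (the orientation variance inflates within-group spread
but never the group difference). Shuffling the labels breaks the balance
and restores the iid reference level, so the real-vs-shuffled comparison
is meaningful even though the raw test is not operating at its nominal
level. Session-level inference uses paired Wilcoxon signed-rank tests
(real vs shuffled proportion; enhanced vs suppressed percentage),
percentile-bootstrap CIs of means (1000 resamples), a Kolmogorov–Smirnov
comparison of real vs shuffled MI distributions, and a chi-square test
for comparing flagged proportions between condition pairs.

## Orofacial kinematics

Angle and pressure are band-pass filtered with a 2nd-order Butterworth
filter (4–30 Hz for whisking, 4–20 Hz for breathing) applied
forward-backward (zero-phase, so landmark timing is unbiased; the squared
magnitude response is what attenuation tests check against). The Hilbert
transform provides envelope and unwrapped phase; cycles are delimited by
phase crossings of odd multiples of π. Within each whisking cycle the raw
angle's maximum (protraction) and minimum (retraction) are refined by a
parabola through the three samples around each extremum — we interpolate
the angle extrema, not the phase; the alternative reading exists but
changes sub-sample timing only. Amplitude is max − min, setpoint their
midpoint. Breathing amplitude is the mean analytic envelope per cycle and
frequency the inverse cycle duration; cycles whose rate falls outside the
filter band (±15% edge tolerance) are discarded. Curvature is rectified
*before* baselining: |κ| minus its per-trial mean over the (−2, −1) s
window (the order is testable — a sign-flipping κ of constant magnitude
must give zero). Per-trial epoch statistics assign cycles to the 2-s
stimulation window by cycle midpoint; odor/no-odor contrasts use a
Mann–Whitney across trials within sessions and a paired Wilcoxon across
session means. The package consumes whisker-pad-averaged traces; a
`combine_whiskers` helper averages per-whisker traces and `resample`
converts between channel rates.

## Decoding

Population vectors are ΔF/F means in 1-s bins (11 bins per trial), one
feature per cell per bin. Pseudo-populations pool cells across sessions
by matching trials on (condition, repetition index) after undoing each
session's pseudo-random order — the matching rule is a package choice;
any rule that pairs like with like is equally defensible since sessions
are independent. The decoders are a nearest-centroid classifier
(Euclidean distance, a package choice) and one-vs-rest linear SVMs, with
an RBF-kernel SVM for mixture categorization, all through scikit-learn
with seeded stratified k-fold cross-validation, k = 10 by default
(configurable; a 20-fold variant exists in the literature on these
designs). Significance is the location of the real accuracy in the
distribution over label shuffles: p = #{shuffled ≥ real}/n, floored at
1/n. This is one-sided as a procedure even where a two-sided reading is
colloquial; a `two-sided` alternative (exceedance of the absolute
deviation from the shuffle mean) is exposed. Feature standardization can
be requested either globally (the `z_score` flag, matching the
definition of z-scored features) or inside the cross-validation
(`standardize=True`, fitted on training folds only) — the latter avoids
leakage and is what decoding comparisons should use.

The linear-SVM regularization rule follows the stated constraint
optimization: grid over C, keep values whose baseline-epoch accuracy
stays within the binomial 95% CI of chance, and among those pick the one
maximizing stimulation-epoch accuracy; if none qualifies the smallest C
is used with a warning. Mixture categorization trains the RBF SVM on
pure-odor trials only and reports, per mixture ratio, the fraction of
trials assigned to each component. Facial decoding reduces the motion
matrix by truncated SVD (default 500 components, truncated to the rank
bound with a warning), averages the temporal components per trial bin,
and decodes odor identity with the linear SVM.

**Transfer tests and why the asymmetry emerges.** A decoder is trained
under one context (e.g. gratings without odors) and scored both by CV
within its training set and on unseen trials from the other context.
With an orthogonal odor subspace and a dominant tactile signal the
asymmetry arises from estimation noise, not from geometry alone: the
learned discriminant is the true coding axis plus sampling noise spread
over all cells, and the out-of-domain context shift (the large tactile
response vector) projects onto that noise component as a common bias for
every test trial. For the strong tactile signal the bias from the weak
odor vector is negligible, so orientation decoding transfers; for the
weak odor signal the 10× larger tactile shift swamps the class
separation and pushes all test trials to one side of the boundary —
chance performance. This reproduces the robustness/fragility pattern
without any built-in nonlinear interaction.

## Problem sizes and determinism

Every stochastic step takes an explicit seed (trial order, population
draw, noise, fold assignment, shuffles), and identical configuration plus
seed gives bit-identical outputs. The validation suite runs at deliberate
desk scale — typically 4–8 sessions of 60–200 cells with 33–100 shuffles
— with Monte-Carlo tolerances computed from each run's own spread; the
reference shuffle-null levels are recomputed by `scripts/acceptance.py`
at 20 sessions × 200 cells × 100 shuffles per contrast.

## Limitations

The generator draws iid white noise per cell and trial: no slow drift,
no correlated network variability beyond the shared neuropil term, no
bursting or spiking statistics, and no motion artifacts — so passing
calibration tests show the *analysis* is correct under its assumptions,
not that real recordings satisfy them. Raw video, ROI segmentation,
registration, and spike deconvolution are out of scope; analyses that
would use a deconvolved signal operate on ΔF/F here. Whisker mechanics
are phenomenological (a sinusoid with gains), not biophysical. The
suppression clip at −0.95 ΔF/F makes very large injected suppressions
non-recoverable by design.
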