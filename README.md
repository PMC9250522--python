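# odorbarrel

Analysis of odor-evoked modulation of barrel-cortex population activity,
for systems neuroscientists working with trial-structured two-photon
calcium imaging and orofacial behavior. Rodents explore objects with
whiskers and nose together, and odors leave a footprint in the whisker
area of primary somatosensory cortex (wS1, "barrel cortex") — both by
changing whisking itself and through whisking-independent signals. This
package implements the full analysis chain needed to detect and
characterize that footprint, together with a synthetic-session generator
with complete ground truth, so every stage is testable without any
recorded data.

The chain, per session:

1. **Preprocess** — neuropil correction `F_cor(t) = F(t) − 0.7·F_n(t)`;
   ΔF/F₀ = (F_cor − F₀)/F₀ with F₀ the 8th percentile of the trial's
   corrected trace; subtraction of the mean ΔF/F over the 1–2 s
   pre-stimulus baseline from each trial.
2. **Modulation statistics** — per cell, Kruskal–Wallis responsiveness
   across the nine stimulation conditions and a two-sided Mann–Whitney U
   between odor-bearing and odor-free trials on 2-s stimulus-epoch means
   (α = 0.05); modulation index
   MI = (ΔF/F_odor − ΔF/F_no odor)/ΔF/F_no odor. Flagged proportions are
   calibrated against a trial-label **shuffle null** (the achievable level
   of the test, ≈4.8–5.0% at these group sizes), with bootstrap CIs and
   paired Wilcoxon tests across sessions.
3. **Orofacial kinematics** — whisking amplitude/setpoint per cycle from
   the Hilbert phase of the band-passed (2nd-order Butterworth, 4–30 Hz)
   whisker-pad angle, with quadratic interpolation of the raw-angle
   extrema; breathing amplitude/frequency in the 4–20 Hz band; rectified,
   baseline-subtracted curvature |Δκ|.
4. **Decoding** — nearest-centroid and linear-SVM classifiers on ΔF/F
   means in 1-s bins with stratified 10-fold CV, shuffle p-values
   (floored at 1/n_shuffles), cross-condition transfer tests
   (train-without-odors → test-with-odors and vice versa), RBF-SVM
   categorization of binary odor mixtures, and odor decoding from facial
   motion-energy principal components.

## Worked example

```python
import odorbarrel as ob
from odorbarrel.synth import simulate_population, PopulationParams
from odorbarrel.preprocess import neuropil_correct, compute_dff, epoch_average
from odorbarrel.modstats import score_modulation, shuffle_null_proportion

# 150-trial session: 2 gratings x 2 odors, unimodal conditions, blank
protocol = ob.make_protocol(seed=1)
params = PopulationParams(n_cells=200, frac_modulated=0.2, mod_effect_median=0.5)
fluor, truth = simulate_population(protocol, params, seed=1)

dff = compute_dff(neuropil_correct(fluor.F, fluor.F_n), protocol)
em = epoch_average(dff, protocol.stim_epoch_s)

odor = protocol.trials_where(category="bimodal")
no_odor = protocol.trials_where(category="grating_only")
res = score_modulation(em, odor, no_odor)
null = shuffle_null_proportion(em, odor, no_odor, n_shuffles=100, seed=1)

print(f"flagged as odor-modulated: {res.proportion_flagged:.1f}% "
      f"({res.n_enhanced} enhanced, {res.n_suppressed} suppressed)")
print(f"shuffle null:              {null.mean:.2f}% "
      f"(95% band {null.ci()[0]:.2f}-{null.ci()[1]:.2f})")
print(f"true modulated fraction:   {100*truth.odor_modulated.mean():.1f}%")
```

prints

```
flagged as odor-modulated: 28.1% (29 enhanced, 27 suppressed)
shuffle null:              4.62% (95% band 0.74-17.09)
true modulated fraction:   25.5%
```

The flagged proportion recovers the injected fraction plus the test's
~5% false-positive floor on the unmodulated cells, and sits far above
the shuffle null — the comparison that separates real odor modulation
from the level the test flags by chance.

The same analyses run end to end from the command line:

```bash
odorbarrel run --config config.yaml --seed 1 --out myrun
odorbarrel report myrun
```

which simulates the configured sessions, writes per-stage tables
(HDF5 sessions, per-cell CSV, kinematics CSV, decoding JSON) under
`myrun/`, and prints a summary of the headline comparisons.

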