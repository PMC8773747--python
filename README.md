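# nirstress

Analysis pipeline for separating **eustress** (low, performance-enhancing
stress) from **distress** (high, performance-impairing stress) using
prefrontal fNIRS hemodynamics, built for researchers working with
event-related optical neuroimaging of stress.

Stress groups are screened physiologically by salivary alpha-amylase
(sAA, KU/L): control < 28, stress > 33, the latter subdivided into
eustress (33–44) and distress (> 44). During an emotional
stimulus-response task (two 1220 s sessions, 20 trials of five
warning/anticipation/target/feedback repetitions followed by 35 s rest,
with an exact 30/70 valence split of the 100 target images per session),
prefrontal ΔHbO is recorded on a 15-channel montage (channels 1–7 right,
9–15 left, 8 midline; 780/850 nm; 8.138 Hz). The pipeline:

1. converts two-wavelength optical-density changes to ΔHbO/ΔHbR via the
   modified Beer–Lambert law, ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ);
2. band-pass filters at 0.01–0.02 Hz with a zero-phase 6th-order
   Chebyshev-I filter (the task fundamental is 1/61 s ≈ 0.0164 Hz);
3. epochs [−1, 60] s around each task onset, baseline-corrects on [−1, 0) s,
   and grand-averages trials then participants;
4. computes the **laterality index for stress**

   LIS = (R − L) / (R + L),  LIS ∈ [−1, 1],

   where R and L are the maximum absolute ΔHbO amplitudes over the right
   and left channel sets (positive = right-hemisphere dominance, the
   stress-typical pattern);
5. runs the group statistics: Levene + independent t (two groups), one-way
   ANOVA with Dunnett T3 post hoc on the studentized maximum modulus
   (three groups, unequal variances), and two-tailed Pearson correlations
   between sAA and behaviour.

A first-class synthetic-data module generates cohorts and event-locked,
hemisphere-lateralized recordings with known ground truth (per-group
right-hemisphere gain g, so the noiseless LIS is (g − 1)/(g + 1) in closed
form), making every stage testable without any data download.

## Worked example

```python
from nirstress import PipelineConfig, run_synthetic_pipeline
from nirstress.synthetic import SimulationParams

gains = {"control": 1.2, "eustress": 1.7, "distress": 1.01}
res = run_synthetic_pipeline(PipelineConfig(n_per_group=2, seed=0),
                             SimulationParams().noiseless(),
                             sessions=(1,), right_gains=gains)
for r in sorted(res.lis_three_group, key=lambda r: -r.lis):
    print(r.group, round(r.lis, 6))
```

prints

```
eustress 0.259259
control 0.090909
distress 0.004975
```

i.e. exactly (g − 1)/(g + 1) for each group's gain: the full signal chain
(filter → epoch → baseline → grand average → hemisphere amplitudes) is
linear, so it preserves the designed asymmetry. With the default noise
model (`python examples/05_full_pipeline.py`) the same ordering appears
with realistic scatter, e.g. session-1 LIS ≈ 0.24 (eustress), 0.11
(control), −0.02 (distress) with per-participant standard errors ≈ 0.01 —
the eustress group shows clear right lateralization, the distress group
essentially none, which is what lets the index subdivide the stress group.

The `examples/` directory has one short script per capability: paradigm
construction, simulation + preprocessing, the laterality index, the
statistics battery, and the full pipeline with on-disk artifacts.

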