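# Methods

## Experimental paradigm model

A session is modelled as exactly 20 trials of 61 s: a 1 s trial-number
display, five stimulus-response repetitions of (warning 0.5 s,
anticipation 2 s, target 2 s, feedback 0.5 s) and a 35 s rest, for a
1220 s session ("approximately 20 minutes" is fixed to the sum of the
component durations). The 100 target events per session carry an exact
30/70 valence split assigned by a seeded random permutation — the 30% is
treated as a design ratio, not a binomial probability — with the minority
class matching the session's warning face (positive in session 1,
negative in session 2).

**Task onset** is defined as the start of a trial's first warning stimulus
(1 s into the trial), not the trial-number display. The [−1, 60] s epoch
around this onset then spans the 25 s stimulus-response block plus the
35 s rest, i.e. a full task-plus-recovery cycle. Response timing is
assumed not to truncate the nominal 2 s target window.

## Modified Beer–Lambert conversion

ΔOD(λ) = [ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR]·d·DPF(λ), solved per channel and
sample as a 2×2 linear system (both directions: forward for simulation,
inverse for measured data). Defaults: d = 25 mm; DPF = 6.0 at both
wavelengths; extinction coefficients compiled from the Prahl/Cope-Delpy
tabulations, stored in 1/(µM·mm) so concentrations read in µM. The
acquisition device's DPF and unit conventions are not published, so these
are editable configuration; the laterality index is a ratio of amplitudes
and therefore invariant to d, DPF and the extinction scale (with DPF = 1
the outputs simply read as µM·mm path products).

## Band-pass filter

6th-order Chebyshev type-I prototype, 1 dB passband ripple, passband
0.01–0.02 Hz, applied forward–backward (zero phase; effective order 12).
Type I with modest ripple is the common biosignal reading of an otherwise
unqualified "Chebyshev" filter, and ripple is a configuration knob. The
passband brackets the 61 s trial period (≈ 0.0164 Hz), removing drift
below and Mayer-wave (~0.1 Hz), respiratory (~0.25 Hz) and cardiac
oscillations above; a 0.01–0.1 Hz wide band is available as the
configuration alternative. At a 0.01 Hz band on an 8.138 Hz record, the
transfer-function realisation is numerically unstable, so the filter runs
in second-order sections with odd-reflection edge padding of 3/low_hz
seconds (three times the impulse-response scale). Measured behaviour of
the default design: a 0.015 Hz tone is preserved within ~1% over the
central half of a 1220 s record, a 0.2 Hz tone attenuated by ~56 dB, DC
suppressed below 1e-13.

## Epoching, baseline, averaging

The sample of t = 0 is floor(onset·fs). An epoch takes floor(fs) samples
before it and floor(60·fs) after it, ends inclusive — 8 + 1 + 488 = 497
samples at 8.138 Hz for the [−1, 60] s window. The baseline interval is
half-open [−1, 0) so t = 0 belongs to the task; its per-trial, per-channel
mean is subtracted once (double correction is rejected). Grand averages
pool trials within participant, then participants. `temporal_mean` (the
per-channel [0, 60] s scalar mean) is provided for summary time courses,
but the laterality index uses maximum absolute amplitudes, not means.
Only ΔHbO feeds the laterality and statistics stages; ΔHbR is carried
through preprocessing but never enters the index.

## Laterality index

LIS = (R − L)/(R + L) on the group-level grand average, with R and L the
maximum absolute ΔHbO amplitudes of the right (channels 1–7) and left
(channels 9–15) sets over [0, 60] s; midline channel 8 is excluded.
"Maximum absolute amplitude" over a channel set is ambiguous between the
single most active channel (max of per-channel maxima) and the
hemisphere-average of per-channel maxima; both are implemented (`max` is
the default, `mean` selectable), and the reproduction script reports both.
The group LIS is computed from the pooled grand average (one value per
group/session); a per-participant LIS supplies the standard error across
participants. The amplitude window ([0, 60] s vs the full epoch) is
configurable; [0, 60] s is the default. R + L = 0 raises an explicit
undefined-laterality error rather than returning 0.

## Synthetic cohorts and recordings

sAA levels are drawn per group from normals truncated to (0, ∞) — control
12.73 ± 9.76, eustress 37.82 ± 3.49, distress 61.82 ± 18.07 KU/L — and
kept inside each group's defining interval (< 28, 33–44, > 44) by
rejection, so threshold classification recovers the true group exactly.
Note the interval truncation shifts sample means away from the nominal
ones (most visibly for distress, whose truncated mean is ≈ 67 KU/L).
Behavioural covariates follow the inverted-U: eustress most accurate
(96.9 ± 0.8%) and fastest, distress slowest; accuracies use the reported
group means, reaction-time and breaths-per-minute models are free choices
at plausible magnitudes.

The hemodynamic response is the target-stimulation boxcar convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, undershoot ratio
1/6) — the field-standard response model, since none is prescribed for
this paradigm. Right-hemisphere channels carry a per-group gain g
(defaults: eustress 1.70, control 1.20, distress 1.01, placing the
noiseless LIS at 0.259, 0.091, 0.005 — inside the reported 0.2–0.3 /
0.06–0.12 / ≈ 0.004 ranges); the left carries 1.0 and the midline the
mean of both. The gain is per participant and session-independent, so the
generator reproduces the reported between-group ordering but not the
reported session-1 vs session-2 differences within a group. ΔHbR is
−1/3 × the noiseless ΔHbO component (typical amplitude ratio, opposite
sign) plus its own noise.

Nuisance: a half-cycle drift over the record (amplitude 2 µM), Mayer
(0.1 Hz, 1 µM), respiration (0.25 Hz, 0.5 µM) and cardiac (1.1 Hz, 0.5 µM)
sinusoids with per-channel random phase and 5% frequency jitter, plus
white noise (SD 6 µM against a 1 µM response amplitude — event-related
fNIRS is a low-SNR technique and the narrow task band plus averaging is
what recovers the response). Cardiac aliasing at 8.138 Hz is accepted as
realistic. These levels put the per-participant LIS standard error near
0.01–0.02, small relative to the eustress–distress separation, consistent
with group error bars visibly smaller than the group differences. The
generator does **not** model motion artifacts, short-separation channels,
photon-transport physics, or session-dependent gains; passing tests
demonstrate correctness of the analysis under these statistical
assumptions, not robustness to artifacts real recordings may contain.

## Statistics

Levene's test gates the two-sample t-test: Welch when Levene rejects at
0.05, pooled otherwise (the conventional coupling; the original battery
runs Levene without stating which t-variant follows). Three-group
contrasts use one-way ANOVA with Dunnett T3 post hoc: pairwise Welch
statistics referred to the studentized maximum modulus distribution with
k = number of pairs, evaluated by adaptive quadrature (absolute/relative
tolerance 1e-9; the k = 1 case reproduces the two-sided t CDF to 1e-9,
and T3 p-values are never smaller than the uncorrected pairwise Welch p).
sAA thresholds use strict inequalities, so 28–33 and the boundary values
28/33/44 KU/L are "unclassified" — the enrolment design has no one there.
Pearson correlations are two-tailed with t-distributed p on n − 2 df;
zero-variance input raises an explicit degenerate-data error.

## Replicate studies and problem sizes

`nirstress.validation` packages the calibration experiments: type-I error
of the t and ANOVA batteries (6000 null replicates — enough that the
Monte-Carlo SD of the rate, ≈ 0.28%, sits well inside a ±1.5% band),
correlation recovery at r = 0.484 with n = 44 over 2000 replicates, a
power check of the two-group comparison at the reported trait-anxiety
means/SDs, and laterality-ordering recovery over 200 replicate cohorts of
11 participants per group. The ordering study exploits the pipeline's
linearity: filtering the participant-mean recording equals averaging
per-participant processed epochs (verified against the per-participant
route to 1e-10 in the test suite), which makes 200 full-cohort replicates
tractable on one core in a few minutes.

## Known limitations

* The deposited-dataset adapter reads the package's own CSV/SNIRF models;
  it has not been validated against the original repository's file layout.
* Group LIS is session-independent by construction of the single gain;
  emulating session-specific lateralization would need a (group, session)
  gain table, which the current generator does not implement.
* The SNIRF reader covers single-block processed-concentration files only.
* No motion-artifact or short-channel handling (not part of the analysis
  being modelled).
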