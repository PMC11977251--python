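# Methods

This note documents the models, parameter choices and numerical decisions
behind `flowphys`, and what the synthetic cohorts do and do not establish
about real recordings.

## Session model and phase partitioning

A session holds one subject's multimodal recording (EEG 250 Hz, two IMUs at
50 Hz, GSR 500 Hz, HR/SpO2 at 1 Hz) and five phase markers — eyes-open
baseline, eyes-closed baseline, and the boredom / flow / frustration game
conditions — as half-open `[start, end)` intervals in seconds from
recording start.  Seconds-based markers shared across modalities avoid
off-by-one ambiguity between sampling rates.  The analysis uses fixed
block lengths: 60 s per baseline and 480 s per condition.  A marker
interval longer than its block is trimmed symmetrically — the block starts
`(L − T)/2` after the marker — so the same amount of unused data precedes
and succeeds every analysis block; sample offsets are floored per modality,
making the extraction deterministic and aligned across modalities to
within one sample period of the slowest stream.  Intervals shorter than
the target are a per-phase error, not a silent truncation.

HR and SpO2 are fixed at 1 Hz.  The wearable's PPG unit reports derived
values at 1 BPM / 1 % resolution; 1 Hz makes every minute window hold
exactly 60 samples and matches typical wearable output.

The on-disk format is a JSON manifest plus one tab-separated file per
modality (header of channel labels, one row per sample), chosen to be
human-inspectable and language-neutral.  Floats are written with
shortest-round-trip representations, so a write/read cycle is bit-exact.
An optional EDF export covers the EEG block only; the 16-bit encoding
quantizes to (physical range)/2^16, which readback tests bound at 1e-3
relative.

## EEG pathway

Filtering is a second-order Butterworth band-pass, 0.5–30 Hz, applied
forward–backward.  The zero-phase pass avoids phase distortion within the
60-s epochs; its effective magnitude response is the square of the
second-order design, which the passband/stopband tests measure directly.

Bad channels are screened automatically — flat if the channel SD falls
below 0.1 µV, extreme if it exceeds 10× the median channel SD — with a
per-subject manual override list that always wins.  The thresholds are a
reproducible stand-in for visual inspection; the override file preserves
the manual workflow where curation notes exist.

Blink removal uses FastICA with as many components as good channels.  A
component is rejected when its mixing pattern correlates with the
Fp-dominant blink topography (|r| > 0.8) *and* its source is heavy-tailed
(excess kurtosis > 2), or when it is extremely heavy-tailed on its own
(kurtosis > 8); at most one component is removed per block.  The pattern
test alone is deliberately not trusted: with four channels, a Gaussian
background yields arbitrary mixing directions and four-point correlations
exceed 0.8 by chance, so an ungated pattern rule would strip genuine
signal from blink-free blocks.  Full FastICA convergence is not required —
rotations within a Gaussian subspace are unidentifiable and the solver may
cycle there indefinitely — because the heavy-tailed blink axis stabilizes
early and the reconstruction `S Aᵀ + mean` inverts exactly for any
rotation.  The decomposition is seeded and therefore deterministic; a
failed decomposition passes the block through with an audit flag.  ICA is
fitted per phase block (filtering state differs across phases; fitting per
block also keeps blocks independent units of processing).

Band power of each mean-removed 1-minute segment is the sum of the plain
one-sided periodogram (no taper, no Welch averaging; bin width 1/60 Hz)
over the band's bins: half-open `low ≤ f < high` for delta/theta/alpha and
upper-edge-inclusive for beta at 30 Hz, so shared edges are assigned
deterministically and the 7–8 / 12–13 Hz gaps stay unassigned.  The
scaling makes bins sum to the signal variance (a unit-amplitude sinusoid
contributes 0.5).  Tests pin this to a brute-force DFT summation at 1e-9
relative tolerance.

Statistics on EEG use the per-subject mean over minutes of
`log(P_minute / P_baseline)` per channel and band.  Percent changes can be
negative, so a log of the corrected value is undefined; the log
baseline-ratio reconciles a log-scale test statistic with percent-change
reporting, and the figures/curves keep the percent scale.  One consequence
is worth stating plainly: in a *paired* contrast the baseline term cancels
(`log(P_a/P_BL) − log(P_b/P_BL) = log(P_a/P_b)`), so the eyes-open- and
eyes-closed-referenced EEG contrasts coincide by construction even though
their curves differ.  Both are still reported, for schema fidelity.

## Autonomic and motion variables

SpO2 validity is the fixed device range [70, 100] %.  HR validity combines
per-subject bounds (default 30–220 BPM, overridable per subject) with a
robust z-score rule, `|x − median| / (1.4826 · MAD) > 4`, standing in for
per-subject manual thresholding.  Invalid samples are replaced by the mean
of the nearest valid left and right values; runs share the same two
flanks; boundary runs use the single available flank; a series with no
valid sample is unusable.  Repair never alters valid samples, and the
repair log (indices, originals, replacements, rule) fully determines the
operation.

A minute is deemed unusable when more than half of its samples had to be
replaced — neighbor interpolation cannot reconstruct a mostly missing
minute — and any unusable minute marks the subject × phase incomplete for
that variable family, excluding it from aggregation and testing for that
phase only.  GSR receives no artifact repair (none is defined for it) and
is analyzed in raw ohms at the device's 0.61 Ω resolution, without
conversion to conductance.

Minute statistics are the sample mean and the n−1 sample SD.  IMU activity
is the per-minute SD of the Euclidean norm of the raw accelerometer and
gyroscope triplets per device; gravity is not subtracted, since a constant
offset shifts the norm's mean but not its SD, and no IMU filtering is
applied.

## Baseline correction and cohort statistics

`x_BC = (x − x_BL)/x_BL · 100 %` with the eyes-closed baseline for all
modalities and additionally the eyes-open baseline for EEG.  A zero
baseline makes the percent change undefined; such cells are logged and
dropped rather than propagated.

Condition contrasts are one-sample t-tests on within-subject differences
of phase-level values (the mean of the 8 minute values), i.e. paired
t-tests on pairwise-complete subjects — the repeated-measures design
implies exactly one value per subject per condition.  Before testing, the
difference vector is screened for outliers: each value is studentized
against the leave-one-out mean and SD and compared with the two-sided t
threshold at level 0.05 Bonferroni-corrected for the vector length,
iterated at most twice.  This automates QQ-plot-based screening of a
location model; under the null it flags in ≈ 5 % of samples familywise,
which the calibration test verifies.  Curve aggregation applies the same
screening per condition × variable cell on phase means before
cross-subject averaging.  No multiple-testing correction is applied across
comparisons — the full table is emitted alongside the significant one so
corrections can be applied downstream.  Zero-variance difference vectors
are reported with an infinite-t sentinel and flagged degenerate rather
than raising.

## Synthetic cohorts

The generator emulates what the devices emit, not the underlying biology:

* **EEG**: shared band-limited oscillation sources (Gaussian noise
  band-passed per band, unit RMS, scaled by µV amplitudes) projected
  through fixed near-uniform scalp weights, plus a shared 1/f background
  (exponent 1, 3 µV RMS), a small channel-independent 1/f sensor-noise
  term (1 µV), and stereotyped biphasic ~0.4 s blink transients with the
  Fp-dominant topography at 12/min.  The shared-source structure reflects
  volume conduction between closely spaced frontal electrodes and is what
  makes a 4-channel ICA model well-posed; with fully channel-independent
  content, blink rejection would necessarily remove genuine variance.
  Narrowband noise rather than pure sinusoids gives realistic spectra and
  avoids bin-edge sensitivity.
* **HR/SpO2**: AR(1) noise (coefficient 0.6) scaled to the target
  stationary SD around a condition mean plus optional linear trend,
  quantized to 1 BPM; spikes of +60–80 BPM for 1–3 samples at 1/min.
  SpO2 ≈ 97 % quantized to 1 %, with sub-70 % dropouts of 1–5 samples.
* **GSR**: level + drift·t + slow (~0.1 Hz) smoothed noise, quantized to
  0.61 Ω.
* **IMU**: unit gravity vector with small fixed tilt, per-axis sensor
  noise (0.005 g / 0.2 dps), and Poisson-count movement bursts with a
  shared smooth envelope across axes and between accelerometer and
  gyroscope.

The `paper_like` preset encodes the study conditions as eyes-closed-
relative power multipliers — boredom delta 5 / theta 6 / alpha 2 / beta 2;
flow 2.5 / 3 / 1.8 / 2.2; frustration 0.8 / 1.1 / 0.8 / 2.0; eyes-open
alpha 0.5 (alpha blocking) — with HR 72/70.5/74 BPM and HR SD 3.5/2.0/4.5
(baseline 70/3), movement 4/0.5/3 bursts/min (baseline 0.2), and mild GSR
level decreases largest in frustration.  Magnitudes reproduce the
qualitative condition ordering, not any specific cohort's printed values.
Subject-level traits (HR offset, GSR offset, per-band gain) are shared
across phases and cancel in paired contrasts; per-phase state variability
(band amplitude lognormal σ 0.15, HR mean ±1 BPM, HR SD lognormal σ 0.15,
SpO2 ±0.5 %, GSR ±1000 Ω) is drawn independently per phase, keeping the
`null` preset exchangeable across conditions while holding t statistics to
realistic magnitudes.  Phase intervals are generated as the analysis block
plus 1–5 s of random slack per side, which exercises centered partitioning
without carrying the unused bulk of full 10-minute game blocks.  Generated
samples are rounded to device-scale precision (EEG 0.001 µV, acc 1e-5 g,
gyro 0.001 dps, GSR 0.61 Ω, HR/SpO2 integers), which keeps the text
session files compact and the disk round trip exact.

What passing tests show — and don't.  The synthetic cohorts establish that
the chain recovers injected parameters (band multipliers to within the
periodogram's chi-squared noise, HR SD, drift, burst ordering), that
artifact repair restores minute means to ≤ 0.5 BPM, that the paired test
is calibrated (type-I ≈ 5 %), and that the qualitative condition ordering
propagates to the significant table with correct signs.  They do not
establish robustness to real-world pathologies absent from the generator:
non-stereotyped artifacts (EMG, electrode pops, motion-coupled EEG),
non-stationary baselines, missing markers, or drift in device calibration.
Bad-channel screening and per-subject HR bounds are exercised only via
constructed cases and overrides.

## Problem sizes and runtime choices

Default test and acceptance runs use cohorts of 8–24 subjects, 10-subject
effect-recovery sweeps, 2000 replicate null comparisons (HR pathway), and
100-segment spectral-oracle checks; these sizes give stable estimates
(e.g. the null rejection rate varies by ±0.01 across seeds) while keeping
a full run in the one-to-two-minute range on a single CPU.  The type-I
calibration runs the real test code path on the autonomic pathway, where
null cohorts are cheap to synthesize in bulk.

## Known limitations

* Only one ICA component is ever rejected per block; multiple concurrent
  stereotyped artifacts would need a generalized criterion.
* The QQ-screening stand-in and the robust HR rule are principled
  automations of manual steps; they will not reproduce any particular
  analyst's judgment calls.
* HRV here is the SD of the 1 Hz HR series; frequency-domain indices
  (LF/HF) are out of scope.
* The EEG open/closed contrast identity noted above means baseline choice
  affects curves and single-condition summaries, never the paired tables.
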