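# Methods

This note documents the signal model, the algorithmic and numerical
choices, and what the synthetic tests do and do not establish about real
recordings.

## Signal model and synthetic generator

The generator emulates a resting, normally breathing adult instrumented
with a chest ECG and a dorsoventral accelerometer.

**RR intervals.** Beat onsets follow respiratory sinus arrhythmia (RSA):

    RR_i = (60 / hr_mean) · (1 + rsa_depth · sin(2π f_resp t_i)),

evaluated at each beat's onset time. `rsa_depth` defaults to 0.08 and
`resp_rate` to 15 breaths/min — mid-range values for young healthy adults
at rest. `rsa_depth ≥ 1` is rejected (RR could go non-positive).

**Respiration.** Lung volume is a raised cosine at the respiratory rate
(tidal volume 0.5 L) and flow is its analytic derivative. The volume is
phased so that inspiration (flow > 0) coincides with the shorter-RR half
of the RSA cycle — heart rate rises during inspiration, as it does
physiologically. Respiratory phase is labelled four ways: INS/EXP by the
sign of flow (zero flow ties to EXP, an arbitrary but fixed rule) and
HLV/LLV by volume relative to the mid-range (mean of min and max).

**ECG.** Each beat contributes a narrow positive R deflection (Gaussian,
σ = 6 ms, 1 mV) and a small negative Q deflection (σ = 4 ms, −0.2 mV)
fixed 30 ms before R — inside the physiologic QR interval. P and T waves
are deliberately absent: only Q and R are consumed downstream, and a
biophysically complete ECG is out of scope.

**SCG.** Each beat is the sum of two Gaussian-windowed cosine packets:
the AO (aortic opening) complex, 20 Hz carrier, σ = 15 ms, 3 milli-g,
centred `pep_ms` after Q; and the smaller AC (aortic closure) complex,
30 Hz carrier, σ = 12 ms, 1.5 milli-g, centred `lvep_ms` after AO. Cosine
carriers put each packet's maximum exactly at its planted fiducial. PEP
and LVEP get independent per-beat Gaussian jitter (SD 2 ms). Baseline
wander (1 milli-g at the respiratory rate) and white noise (SD 0.2
milli-g) are added.

**Two-regime morphology.** Beats are assigned regime 1 during inspiration
and regime 2 otherwise. Regime-2 beats rescale the AO packet by
(1 − 0.5·m), the AC packet by (1 + m), and add a mid-systolic packet
(25 Hz, 80 ms after AO) of amplitude 0.6·m·AO, where m =
`cluster_mod_depth` (default 0.3). This plants a known cluster structure
that survives per-beat normalization (it changes relative, not just
absolute, amplitudes), giving the clustering stage a recoverable truth.

**Posture presets.** PEP/LVEP/heart-rate presets are supine 70/300 ms at
62 bpm, 45° tilt 74/286.9 ms at 65 bpm, sitting 80.6/272 ms at 67 bpm —
PEP lengthens and LVEP shortens from supine to upright, and heart rate
rises a few percent, matching the orthostatic pattern in healthy resting
adults. Cohorts add per-subject Gaussian offsets (SD 9 ms PEP, 17 ms
LVEP, 5 bpm HR) that persist across postures and sessions, so paired
posture comparisons see consistent within-subject effects.

**Determinism.** All draws come from one `numpy` generator seeded by
`GeneratorConfig.seed`; identical configs give bit-identical recordings.
In cohort runs each record's seed is `crc32("subject|posture|session")`
mixed with the global seed, kept below 2³¹.

**What the generator does not emulate.** Real SCG beats have richer
fiducial structure (MC, IM, RE waves), inter-subject morphology
differences far beyond amplitude offsets, non-stationary noise, motion
artifacts, and imperfect sensor re-positioning between sessions. Passing
the planted-truth tests shows the pipeline's stages are correct and
internally consistent, not that its accuracy transfers unchanged to
clinical recordings.

## Conditioning

The band-pass is a Chebyshev type-II design with stop-band edges at 0.5
and 50 Hz and 40 dB stop-band attenuation (a standard biosignal choice;
configurable), applied forward-backward so the chain is exactly
zero-phase. "4th order" is interpreted as the low-pass prototype order
(the realized band-pass is 8th order); both the order and attenuation are
arguments. Note that with the stop-band edges *at* 0.5/50 Hz the type-II
pass-band droops near the upper edge (single-pass gain ≈ 0.96 at 20 Hz,
≈ 0.41 at 30 Hz): the filter is kept as specified rather than silently
widening the band, and the droop is accounted for in tests.

The moving average (order 5, must be odd) is centred, with window
truncation at the record edges — the record is processed offline and the
chain is already non-causal, so a centred window avoids adding group
delay; truncation avoids padding transients. Decimation (10 kHz → 1 kHz)
uses a zero-phase FIR anti-alias filter.

Zero-phase IIR filtering still rings near the record boundaries (the
0.5 Hz edge has a multi-second transient), so the pipeline drops beats
overlapping the first and last 2 s of a record. Without this guard, the
boundary beats register as a spurious morphology cluster in otherwise
noise-free recordings.

## Segmentation

R peaks come from the Pan-Tompkins stages: 5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, dual adaptive
signal/noise thresholds with a 200 ms refractory period and a search-back
pass at half threshold for gaps longer than 1.66× the running RR average.
Fiducials are refined to the local ECG maximum (±75 ms). A flat record
returns no detections rather than raising.

The Q point is the ECG minimum in [R − 50 ms, R) — the window covers the
physiologic QR interval at resting heart rate. A window that precedes the
record start leaves Q undefined (flagged); an argmin on the window's left
edge is flagged as degenerate but still reported.

Beats span [R_i − 0.1 s, R_{i+1} − 0.1 s) in half-open 0-based sample
windows, so consecutive beats tile the record exactly; the last R anchors
no beat, and a first R earlier than 0.1 s is dropped with a log message.
Normalization divides each beat by its own peak magnitude and retains the
raw milli-g waveform alongside.

## Clustering

DTW uses local cost |x_i − y_j|, unit-weight symmetric steps
{diagonal, up, right}, and a boundary-to-boundary path — the plain Θ(l²)
recurrence, chosen so that exact oracle tests (brute-force path
enumeration) are possible. No warping window is applied by default
(beats are 600–1200 samples at 1 kHz and the quadratic cost is
acceptable); an optional Sakoe-Chiba band is available for speed.

k-medoids (K = 2) alternates nearest-medoid assignment with the
within-cluster medoid update until no label changes. Ties in assignment
go to the lower cluster index, a medoid always belongs to its own cluster
(relevant only under exact distance ties), and an emptied cluster is
re-seeded with the beat farthest from the surviving medoid. The
objective (summed DTW to own medoid) is non-increasing across sweeps.
Initialization is a seeded random choice of two distinct beats; a
deterministic farthest-pair init is available. After convergence the
clusters are relabelled so cluster 1 has the higher mean heart rate,
which makes labels comparable across runs and matches the
inspiration-linked cluster under RSA.

Clustering operates on normalized beats; the reported intra/inter-cluster
distances are evaluated on the raw milli-g beats against the medoids' raw
waveforms, so the variability features carry physical units (a flag
restores normalized-scale output). The absolute scale of these distances
depends on beat length (DTW sums per-sample costs along the path), so
they are comparable within a fixed sampling-rate convention, not across
conventions.

One empirically important property: with RSA present, beat *length* is
itself respiration-coupled, and baseline wander adds phase-coupled
within-beat shape. DTW clustering picks this up even with zero planted
morphology modulation — so a "no coupling" null requires disabling RSA
and wander, not just the morphology modulation. On real data this means
the two clusters partly encode beat duration as well as waveform shape;
that is intrinsic to DTW on R-gated beats, not an artifact.

## Features

Spectral ratios use a rectangular-window periodogram of each medoid,
zero-padded to the next power of two ≥ 4× the beat length, binned into
contiguous half-open bands [0.5, 10.5), [10.5, 20.5), [20.5, 30.5),
[30.5, 40.5), [40.5, 50] Hz so the nominal bands tile the 0.5–50 Hz
reference exactly and the five ratios sum to one. Spectral leakage from
the rectangular window keeps ~2 % of even a pure in-band tone outside its
band; the tests assert dominance and ≥ 0.95 rather than a fictitious 1.0.

AO is the tallest local maximum in (R, R + 200 ms], AC the tallest in
(R + 250 ms, R + 450 ms] — windows bracketing physiologic systole at
resting heart rate, configurable. Candidate peaks need prominence ≥ 1 %
of the beat's peak so numerical ripple cannot stand in for a missing wave
complex; ties take the earlier peak; an empty window flags the fiducial
as undefined. PEP = AO − Q and LVEP = AC − AO are computed per medoid and
averaged across the two medoids.

## Statistics

Paired t uses t = μ√n/σ with the n−1 sample SD and two-tailed p on n−1
df; zero-variance differences are reported as undefined rather than ±∞.
Cohen's d uses the pooled SD and is reported as a magnitude (group order
must not change the effect size); the class scale is small < 0.2 ≤ medium
< 0.5 ≤ large < 0.8 ≤ very large, with boundary values assigned to the
higher class (the strict-inequality scale leaves them unassigned
otherwise). One-way ANOVA uses the standard between/within mean-square
ratio with df (k−1, N−k); all-identical data define F = 0. Bland–Altman
reports bias and bias ± 1.96·SD of the paired differences. No
multiple-testing correction is applied — the comparison tables are
descriptive, mirroring common practice in small-cohort SCG studies.

## Problem sizes and reproducibility

The test suite and the acceptance script run synthetic cohorts at 25–60 s
per recording (25–60 beats) and up to 19 subjects × 3 postures or 10–19
subjects × 5 sessions; these sizes give stable cluster structure and
statistics while keeping a full run to a few minutes on one CPU. DTW is
exact (no windowing) throughout. The CSV + JSON + YAML interchange
formats make a run fully described by its manifest: recordings as
`time_s, ecg, scg_dv, lung_volume, flow` CSV with a JSON metadata
sidecar, ground truth as JSON, configs and manifests as YAML.

## Known limitations

- The two recomputable published effect sizes are arithmetic checks of
  the statistics layer; the group-level clinical tables cannot be
  reproduced without the original recordings.
- The generator's two-regime modulation is a step function of
  respiratory phase; real morphology varies continuously within a
  breath, so real intra-cluster distances are relatively larger.
- Pan-Tompkins constants are tuned for clean resting ECG; heavy artifact
  or arrhythmia handling is out of scope (no ectopic-beat exclusion).
- The Chebyshev-II band placed exactly at 0.5–50 Hz attenuates genuine
  SCG content between ~25 and 50 Hz (see Conditioning); band-limited
  features inherit that shaping consistently across postures and
  sessions, so within-study comparisons remain valid.
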