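# scgvar

Postural and longitudinal variability analysis of seismocardiographic
(SCG) signals.

Seismocardiography records the low-frequency chest-surface accelerations
produced by cardiac mechanical activity (valve events, blood momentum
changes, myocardial contraction). SCG features — beat morphology, spectral
distribution, cardiac timing intervals — are candidates for non-invasive
longitudinal cardiac monitoring, but they carry substantial intra-subject
variability from respiration and posture. `scgvar` implements a complete
pipeline for quantifying that variability:

1. **Conditioning** — zero-phase Chebyshev-II band-pass (0.5–50 Hz),
   moving-average smoothing, anti-aliased decimation to 1 kHz.
2. **Segmentation** — Pan-Tompkins R-peak detection on the simultaneous
   ECG; each SCG event spans from 0.1 s before one R peak to 0.1 s before
   the next.
3. **Respiration declustering** — K = 2 k-medoids over dynamic-time-warping
   (DTW) distances between unit-peak-normalized beats. Respiration
   nonlinearly stretches and reshapes beats, so DTW, not Euclidean
   distance, measures morphological dissimilarity; each cluster is
   represented by its medoid

       C_j = argmin_{y in cluster j} Σ_i dtw(y, X_ij).

4. **Features** — intra-cluster distance (mean DTW of beats to their own
   medoid) and inter-cluster distance (to the opposite medoid), both in
   milli-g; energy ratios of five bands (0.5–10 … 41–50 Hz) to the total
   0.5–50 Hz spectral energy, averaged over the two medoids; PEP (ECG Q
   point → AO peak) and LVEP (AO → AC peak) from the medoids; per-cluster
   heart rate.
5. **Statistics** — pairwise paired t-tests and Cohen's d
   (`d = |μ₁ − μ₂| / σ_pooled`) between postures, one-way ANOVA across
   recording sessions, Bland–Altman limits of agreement.

Because clinical SCG recordings are rarely shareable, the package ships a
ground-truthed synthetic generator: RR intervals with respiratory sinus
arrhythmia, an ECG with Q/R deflections, SCG beats built from AO and AC
wave packets at configurable PEP/LVEP, two respiration-phase-linked
morphology regimes, baseline wander and noise. Every downstream stage is
tested against the generator's planted truth.

## Worked example

```python
import scgvar

cfg = scgvar.GeneratorConfig(duration_s=30, seed=1)   # supine defaults
record, truth = scgvar.generate_recording(cfg)
row = scgvar.process_record(record, cluster_seed=1)
print({k: round(v, 2) for k, v in row.items() if isinstance(v, float)})
```

prints (abridged):

```
{'intra': 16.2, 'inter': 25.77, 'pep_ms': 70.0, 'lvep_ms': 301.5,
 'pep_lvep_ratio': 0.23, 'hr_c1': 64.93, 'hr_c2': 59.25, 'hr_mean': 62.53,
 'ratio_0.5-10': 0.16, 'ratio_11-20': 0.59, 'ratio_21-30': 0.24, ...}
```

The planted PEP of 70 ms and LVEP of 300 ms come back through the full
chain (filtering, R/Q detection, clustering, fiducial detection) within
the generator's 2 ms beat-to-beat jitter; the intra-cluster distance is
smaller than the inter-cluster distance, indicating the two
respiration-linked morphology groups separated; and cluster 1 (the
inspiration-linked group) has the higher mean heart rate, as respiratory
sinus arrhythmia dictates.

From the shell:

```bash
scgvar simulate --subjects 19 --sessions 1 --duration 60 --seed 1 --out cohort/
scgvar run --manifest cohort/manifest.yaml --out results/
scgvar compare-postures --features results/features.csv
scgvar compare-sessions --features results/features.csv
```

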