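# mstates

Resting-state EEG **microstate** analysis for two-arm clinical studies,
with a ground-truth simulator.

Scalp EEG topographies do not drift continuously: they stay quasi-stable
for ~60–120 ms and then switch abruptly. These episodes — microstates —
fall into four canonical topographic classes (A: right-frontal to
left-posterior axis, B: its mirror image, C: anterior–posterior, D:
fronto-central maximum), and their temporal statistics (how long each
class dwells, how often it appears, what fraction of time it covers, and
the transition probabilities between classes) are widely used markers of
large-scale brain dynamics in psychiatric research. `mstates` implements
the full analysis chain of such a study, plus the statistics used to
compare patient and control groups, for people who want a tested,
scriptable alternative to GUI toolchains — and, critically, a simulator
that plants known dynamics so every stage can be validated against
ground truth.

## What it computes

Given average-referenced maps `x_t ∈ R^K` (K channels), the pipeline:

1. **Preprocessing** — zero-phase Butterworth band-passes (1–40 Hz, then
   2–20 Hz) on the continuous record, 2-s epochs, rejection of any epoch
   with |amplitude| > 100 μV, common average reference.
2. **GFP peaks** — global field power `GFP(t) = sqrt(1/K Σ_k (x_{t,k} − x̄_t)²)`;
   maps at strict local GFP maxima are kept (highest topographic SNR).
3. **T-AAHC clustering** — topographic atomize-and-agglomerate
   hierarchical clustering of the peak maps under polarity-invariant
   spatial correlation, down to k = 4; quality is the global explained
   variance `GEV = Σ_p (GFP_p·|corr(x_p, T_{a(p)})|)² / Σ_p GFP_p²`.
   Group templates re-cluster the pooled subject templates and are
   ordered A–D by exhaustive matching against reference maps.
4. **Backfitting & parameters** — every frame gets the label
   `argmax_c |corr(x_t, T_c)|`; segments of ≤ 20 time frames are
   dissolved into their flanks; per class the mean duration (ms),
   occurrence (/s), coverage (%) and the row-normalized transition matrix
   are extracted per subject.
5. **Statistics** — pooled-variance t tests and Yates χ² for
   demographics, ANCOVA per parameter with an education covariate
   (partial η² = SS_group/(SS_group+SS_resid)), Benjamini–Hochberg FDR
   within parameter families, HAMD-24 seven-factor scoring, and Pearson
   correlations with Fisher-z 95% CIs in the patient arm.

The **simulator** (`mstates.synthetic`) generates cohorts from a
semi-Markov state model (gamma dwell times, zero-diagonal transition
matrix) whose states project dipolar template topographies on an
alpha-band carrier with white sensor noise at a chosen SNR, along with a
clinical table whose symptom scores carry planted correlations to the
dynamics. Everything is exported with its ground truth.

## Worked example

```bash
python examples/02_cluster_templates.py
```

```
recording: 64 channels, 30 s at 500 Hz
epochs kept: 15/15
GFP peaks: 600 (20.0/s; a 10 Hz carrier yields ~20/s)
T-AAHC at k=4: GEV = 0.964
  class A: |corr| with planted template = 0.993
  class B: |corr| with planted template = 0.992
  class C: |corr| with planted template = 0.999
  class D: |corr| with planted template = 0.994
```

A 30-s synthetic subject at SNR 10 yields 600 GFP peaks (two per 10 Hz
carrier cycle); T-AAHC explains 96% of the GFP-weighted variance with
four maps, each matching its planted topography at |corr| ≥ 0.99 —
i.e. the clustering recovered the generating templates up to polarity.
The other examples cover cohort simulation and file export (`01`),
temporal parameters and the run-length identity coverage ≈ occurrence ×
duration (`03`), and the group ANCOVA/FDR/correlation report (`04`).

Typical temporal-parameter output (`03`, recovered vs ground truth in
parentheses): class C duration 80.2 ms (81.0), occurrence 3.60/s (3.47),
coverage 28.9% (28.1).

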