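# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `mstates`, and what the synthetic benchmarks do and
do not establish about real data.

## Signal model of the simulator

Brain states follow a **semi-Markov chain** over the four canonical
classes: dwell times are drawn per class from a gamma distribution with
the class's mean duration and a shape parameter (default 4), floored at
10 ms and rounded to whole frames (at least one); the successor class is
drawn from a zero-diagonal conditional transition matrix (default
uniform, 1/3 per destination). A semi-Markov construction is used
because microstate durations are far from geometric: the 60–120 ms
quasi-stability band implies a unimodal dwell distribution, which
gamma-with-shape-4 reproduces (CV = 0.5). Default class means are
(60, 60, 80, 70) ms — inside the quasi-stable band, with class C longest
to mirror the asymmetry typical of eyes-closed resting data.

Each state projects a fixed **template topography**: a smooth field from
one or two opposite-signed Gaussian sources on the unit-disc projection
of a standard 64-channel 10–20 cap (A: right-frontal positive vs
left-posterior negative; B mirrored; C anterior vs posterior on the
midline; D a focal fronto-central source whose surround negativity
comes from average referencing). Maps are average-referenced and
unit-normed; all pairwise polarity-invariant correlations are below 0.7
(largest: A–C and B–C at 0.53), so the classes are distinct but not
orthogonal — as on real scalps. A `jitter` parameter adds seeded
topographic noise for between-subject template variability (default 0).

The sensor signal is `x(t) = α sin(2πf t) · T_{s(t)} + ε(t)`: an
alpha-band carrier (f = 10 Hz, the eyes-closed spectral peak) modulating
the active template, plus spatially white Gaussian noise. α is set so
the state signal has a chosen per-channel RMS (default 10 μV) and the
noise RMS equals signal RMS / SNR. The carrier gives two GFP peaks per
cycle and periodic polarity reversals — precisely the structure that
motivates polarity-invariant clustering. Deliberately *not* modeled:
1/f background spectra, volume-conduction head geometry, and
ocular/muscle artifacts (the amplitude-rejection stage therefore rarely
fires on synthetic data; it is exercised by targeted unit tests).
Consequently, passing recovery benchmarks shows the pipeline is correct
and self-consistent under the stated generative model, not that it is
robust to every artifact class of real recordings.

**Cohorts.** Per-subject seeds are spawned deterministically from the
master seed, with separate streams for dynamics, sensor noise and
clinical scores, so sequence-level cohorts coincide with their full-EEG
counterparts. Between-subject variability multiplies each class's mean
duration by `1 + cv·z`, z ~ N(0,1) (default cv = 0.08, giving the
~10–15% between-subject duration SD seen in resting-state parameter
tables). The clinical table plants demographic moments per arm (age,
sex ratio, education) and, for patients, HAMD-24 items, HAMA and MADRS.
The target factor score (default anxiety/somatization, mean 5.50,
SD 2.61) is drawn bivariate-normally against the duration-jitter z of a
named class with correlation ρ (default −0.40 to class C), then rounded
and distributed over the factor's items (0–4 each); integer rounding
attenuates the planted ρ by well under 1%.

## Analysis pipeline

**Filtering.** Zero-phase forward–backward Butterworth band-passes
(4th order per pass), 1–40 Hz then 2–20 Hz, both applied to the
continuous record before epoching. No filter family is canonical in
this literature; Butterworth-filtfilt is the common choice and keeps
passband amplitude within 5% at 10 Hz while attenuating 50 Hz by more
than 20 dB.

**Epoching and rejection.** Consecutive non-overlapping 2-s epochs; an
epoch is rejected when any sample on any channel strictly exceeds
±100 μV ("exceeding" is read as a strict inequality, so a sample at
exactly 100 μV is kept). Rejection is applied before average
referencing. Visual inspection and ICA-based artifact removal are not
reproducible algorithmically and are out of scope; the quantitative
amplitude rule is the implemented criterion.

**GFP and peaks.** GFP is the *population* standard deviation across
channels of the average-referenced map (equivalently its RMS). Peaks
are strict local maxima computed within each epoch; epoch-edge frames
never qualify, and no peak can span a boundary.

**T-AAHC.** Maps are average-referenced and unit-normed, making the
spatial Pearson correlation a plain dot product. Starting from
singleton clusters, the cluster with the smallest GEV contribution
Σ(GFP·|corr|)² is dissolved and each orphan map joins the cluster whose
centroid it correlates with most strongly in absolute value (ties to
the lowest cluster index). Centroids are the polarity-aligned first
principal axis of the member maps — plain averaging would cancel under
the carrier's polarity reversals. The worst-cluster criterion is one of
several defensible readings of "atomize the worst cluster"; lowest GEV
contribution is chosen because GEV is the quantity the method reports.
Group templates re-cluster the pooled subject templates with unit
weights (subject maps are unit-norm, so GFP weighting is meaningless at
that level).

**Canonical ordering.** All 4! = 24 one-to-one pairings between
candidate and reference maps are scored by summed polarity-invariant
correlation and the maximum taken (deterministic tie-break toward the
lexicographically first permutation); signs are aligned to the
reference. The built-in reference set is the simulator's canonical
templates; an external reference can be supplied. Exhaustive search is
exact and trivially cheap at k = 4; the Hungarian algorithm serves as
an independent oracle in the tests, not as the implementation.

**Backfitting and smoothing.** Frames are labeled by maximal |corr|
with the templates; zero-variance frames inherit the nearest labeled
frame within their epoch. Segments of ≤ 20 time frames (20 ms at
1000 Hz; the `min_tf` parameter should be scaled with the sampling
rate) are dissolved shortest-first, each frame joining the flanking
segment whose template correlates better with that frame; the loop runs
to a fixed point, after which no interior segment is ≤ min_tf.
Epoch-edge segments are exempt — they are truncated by the epoch window,
not genuinely short. Frame-wise correlation-based reassignment is
chosen over splitting at the midpoint because it uses the data rather
than an arbitrary geometric rule; both appear in published toolchains.

**Parameters.** Segments never span epoch boundaries. Mean duration
averages segment lengths per class (a switch excludes edge-truncated
segments); occurrence divides segment counts by the *analyzed* time
(kept epochs only — rejected epochs carry no labels); coverage is the
labeled-frame share. Transition probabilities are row-normalized counts
of within-epoch segment boundaries; a jointly-normalized matrix is also
emitted since "probability across all observed transitions" admits both
readings. The run-length identity coverage = occurrence × mean duration
holds exactly on every sequence and is property-tested.

## Statistics

Demographics use Student's pooled-variance t (not Welch) and the
Yates-corrected χ² — the conventions that reproduce published
two-arm demographic tables (the uncorrected χ² for the reference sex
table would be ≈1.35 vs the printed 0.826). Note that t statistics
recomputed from 2-decimal summary moments can differ from values
computed on raw data by ~0.001–0.002; the package reports what the
printed moments imply.

The group ANCOVA fits `y = β₀ + β₁·arm + β₂·education` by OLS and tests
the arm effect by full-vs-reduced residual sums of squares, F(1, n−3);
partial η² = SS_arm/(SS_arm+SS_resid) = F/(F+df_resid) for this 1-df
effect. A constant covariate degrades gracefully to one-way ANOVA with
a warning. FDR families follow parameter type — duration, occurrence,
coverage (4 tests each) and the 12 transitions — since the family
structure is a reporting convention, it is configurable. Correlations
(patient arm only) default to FDR-surviving parameters with raw p, and
use Fisher-z 95% CIs, `tanh(atanh r ± 1.96/√(n−3))`, with p from
`t = r√(n−2)/√(1−r²)`.

HAMD-24 factor scoring uses the conventional seven-factor composition
(anxiety/somatization = psychic anxiety, somatic anxiety,
gastrointestinal, general somatic, hypochondriasis, insight; etc.);
item-to-factor maps vary across the literature, so the map is a
configurable `FactorMap` validated for disjointness.

## Open design choices

- **Pooled vs per-arm group templates.** Published descriptions are
  ambiguous about whether group templates come from all participants or
  per arm. Pooled is the default (identical templates make parameters
  directly comparable across arms); `template_mode="per_arm"` is
  available.
- **Benchmark problem sizes.** The recovery benchmark uses 10 subjects
  × 60 s at 1000 Hz and SNR 10; the type-I calibration uses 200
  replicate 70-subject cohorts simulated at sequence level (the
  calibration exercises the sampling noise of the dwell-time process
  and the ANCOVA, which do not require synthesizing sensor EEG).
  These sizes give stable estimates (recovery errors reproducible to
  ~1–2 percentage points across seeds) at desk-scale runtimes.
- **Recovery reference.** Recovered parameters are compared against the
  *realized* ground truth (the statistics of the finite planted
  sequence), not the asymptotic planted means, so the benchmark
  isolates pipeline error from sequence sampling error.

## Known limitations

- Duration recovery carries a small positive bias (typically 5–9% at
  60 ms planted means) because the ≤20-TF rejection dissolves genuinely
  short planted segments into their neighbors; this is a property of
  the standard analysis protocol, not an implementation artifact, and
  shrinks as planted durations grow.
- The simulator's white-noise, single-carrier model makes backfitting
  easier than on broadband real EEG; frame agreement of ~92% at SNR 10
  should not be read as an expected real-data accuracy.
- EDF export is not provided (no writer dependency); recordings are
  written as BrainVision, which round-trips losslessly at float32
  precision through the mne reader.
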