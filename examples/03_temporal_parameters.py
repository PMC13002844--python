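"""Backfitting and temporal microstate parameters.

Backfits the planted templates to a noisy synthetic subject, rejects
segments of 20 ms or less, and prints the per-class mean duration,
occurrence and coverage next to the ground truth, plus the transition
probability matrix.  Also demonstrates the run-length identity
coverage = occurrence x mean duration.
"""

import numpy as np

from mstates import (
    DynamicsSpec,
    PipelineConfig,
    extract_subject_parameters,
    make_canonical_templates,
    preprocess_recording,
    simulate_subject,
    standard_1020_montage,
)

montage = standard_1020_montage()
templates = make_canonical_templates(montage)
rec, truth = simulate_subject(templates, DynamicsSpec(snr=10.0), length_s=30.0, fs=500.0, seed=5)

cfg = PipelineConfig(min_tf=10)  # 20 ms at 500 Hz
ep = preprocess_recording(rec, cfg)
params, trans, labels = extract_subject_parameters(templates, ep, cfg)

print("class  duration_ms (true)  occurrence/s (true)  coverage% (true)")
for i, c in enumerate(params.classes):
    t = truth.realized
    print(
        f"  {c}    {params.duration_ms[i]:6.1f} ({t.duration_ms[i]:5.1f})      "
        f"{params.occurrence_hz[i]:5.2f} ({t.occurrence_hz[i]:5.2f})       "
        f"{params.coverage_pct[i]:5.1f} ({t.coverage_pct[i]:5.1f})"
    )

print("\nrun-length identity (coverage ~ occurrence x duration):")
for i, c in enumerate(params.classes):
    implied = params.occurrence_hz[i] * params.duration_ms[i] / 10.0  # %/s -> %
    print(f"  {c}: coverage {params.coverage_pct[i]:5.2f}%  implied {implied:5.2f}%")

print("\ntransition probabilities (row -> column):")
print("      " + "      ".join(trans.classes))
for i, c in enumerate(trans.classes):
    print(f"  {c} " + "  ".join(f"{v:0.3f}" for v in trans.conditional[i]))
print("rows sum to 1 over the three possible destinations (diagonal excluded).")
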