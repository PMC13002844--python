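"""From raw EEG to microstate templates.

Preprocesses one synthetic subject (band-pass, 2-s epochs, +/-100 uV
rejection, average reference), extracts scalp maps at GFP peaks,
clusters them with T-AAHC at k = 4 and orders the result canonically
(A-D).  The report shows the GFP-peak rate (two per alpha cycle), the
global explained variance of the clustering, and how well each template
matches the planted topography.
"""

import numpy as np

from mstates import (
    DynamicsSpec,
    PipelineConfig,
    assign_canonical_labels,
    cluster_peak_maps,
    gfp,
    gfp_peaks,
    make_canonical_templates,
    preprocess_recording,
    simulate_subject,
    standard_1020_montage,
)

montage = standard_1020_montage()
planted = make_canonical_templates(montage)
rec, truth = simulate_subject(planted, DynamicsSpec(snr=10.0), length_s=30.0, fs=500.0, seed=42)
print(f"recording: {rec.n_channels} channels, {rec.duration_s:.0f} s at {rec.sfreq:.0f} Hz")

cfg = PipelineConfig(min_tf=10)  # 10 frames = 20 ms at 500 Hz
ep = preprocess_recording(rec, cfg)
print(f"epochs kept: {ep.n_kept}/{ep.n_epochs}")

g = gfp(ep)
peaks = gfp_peaks(g)
print(f"GFP peaks: {peaks.size} ({peaks.size / (ep.n_kept * 2.0):.1f}/s; "
      "a 10 Hz carrier yields ~20/s)")

templates, assignment = cluster_peak_maps(ep, k_target=4)
templates = assign_canonical_labels(templates, planted)
print(f"T-AAHC at k=4: GEV = {templates.gev:.3f}")

sims = np.abs(np.einsum("ij,ij->i", templates.maps, planted.maps))
for label, s in zip(templates.labels, sims):
    print(f"  class {label}: |corr| with planted template = {s:.3f}")
print("values near 1 mean the clustering recovered the planted maps up to polarity.")
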