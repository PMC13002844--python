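"""End-to-end orchestration: recordings -> parameters -> statistics.

Chains the preprocessing, clustering, backfitting and parameter stages
with the defaults of a standard resting-state microstate study: 1-40 Hz
then 2-20 Hz zero-phase band-passes on the continuous record, 2-s epochs
with a +/-100 uV rejection rule, common average reference, GFP-peak
T-AAHC at k = 4 per subject, group templates from the pooled subject
maps, canonical A-D ordering, backfitting, and rejection of segments of
20 time frames or fewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .metrics import (
    LabelSequence,
    MicrostateParameters,
    TransitionMatrix,
    backfit,
    reject_short_segments,
    temporal_parameters,
    transition_matrix,
)
from .microstates import (
    TemplateSet,
    assign_canonical_labels,
    cluster_peak_maps,
    group_templates,
)
from .preprocess import EEGRecording, EpochSet, average_reference, bandpass, drop_channels, segment_epochs
from .synthetic import Cohort, make_canonical_templates

__all__ = ["PipelineConfig", "SubjectResult", "CohortAnalysis", "preprocess_recording", "extract_subject_parameters", "analyze_cohort"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters (defaults follow the standard protocol)."""

    broad_band: tuple[float, float] = (1.0, 40.0)
    microstate_band: tuple[float, float] = (2.0, 20.0)
    epoch_s: float = 2.0
    reject_uv: float | None = 100.0
    drop_channels: tuple[str, ...] = ()  # e.g. EOG electrodes
    k: int = 4
    min_tf: int = 20
    template_mode: str = "pooled"  # or "per_arm"
    exclude_truncated_duration: bool = False


@dataclass(frozen=True)
class SubjectResult:
    subject: str
    arm: str | None
    templates: TemplateSet
    labels: LabelSequence
    parameters: MicrostateParameters
    transitions: TransitionMatrix


@dataclass(frozen=True)
class CohortAnalysis:
    subjects: list[SubjectResult]
    group_templates: dict[str, TemplateSet]  # keyed by arm, or "pooled"
    params: pd.DataFrame = field(repr=False)
    transitions: pd.DataFrame = field(repr=False)


def preprocess_recording(rec: EEGRecording, config: PipelineConfig = PipelineConfig()) -> EpochSet:
    """Continuous recording -> clean average-referenced epochs."""
    if config.drop_channels:
        rec = drop_channels(rec, list(config.drop_channels))
    rec = bandpass(rec, *config.broad_band)
    rec = bandpass(rec, *config.microstate_band)
    ep = segment_epochs(rec, config.epoch_s, config.reject_uv)
    if ep.n_kept == 0:
        raise ValueError("no epochs survived artifact rejection")
    return average_reference(ep)


def extract_subject_parameters(
    templates: TemplateSet, ep: EpochSet, config: PipelineConfig = PipelineConfig()
) -> tuple[MicrostateParameters, TransitionMatrix, LabelSequence]:
    """Backfit templates, smooth short segments and summarize one subject."""
    ls = backfit(templates, ep)
    ls = reject_short_segments(ls, config.min_tf)
    params = temporal_parameters(ls, exclude_truncated_duration=config.exclude_truncated_duration)
    return params, transition_matrix(ls), ls


def analyze_cohort(cohort: Cohort, config: PipelineConfig = PipelineConfig()) -> CohortAnalysis:
    """Run the full pipeline over a simulated (or loaded) cohort.

    Subject templates are clustered per participant from GFP-peak maps;
    group templates come from the pooled subject maps (default) or from
    each arm separately (``template_mode="per_arm"``), are canonically
    ordered A-D against the built-in reference maps, and are backfitted
    to every subject of the corresponding pool.
    """
    epochs: dict[str, EpochSet] = {}
    subject_sets: dict[str, TemplateSet] = {}
    arms: dict[str, str | None] = {}
    for s in cohort.subjects:
        ep = preprocess_recording(s.recording, config)
        epochs[s.subject] = ep
        subject_sets[s.subject], _ = cluster_peak_maps(ep, config.k)
        arms[s.subject] = s.arm

    reference = make_canonical_templates(cohort.subjects[0].recording.montage)
    pools: dict[str, list[str]] = {}
    if config.template_mode == "per_arm":
        for sid, arm in arms.items():
            pools.setdefault(str(arm), []).append(sid)
    elif config.template_mode == "pooled":
        pools["pooled"] = list(subject_sets)
    else:
        raise ValueError(f"unknown template_mode {config.template_mode!r}")

    gts: dict[str, TemplateSet] = {}
    results: list[SubjectResult] = []
    for pool_name, sids in pools.items():
        gt = group_templates([subject_sets[s] for s in sids], config.k)
        gt = assign_canonical_labels(gt, reference)
        gts[pool_name] = gt
        for sid in sids:
            params, trans, ls = extract_subject_parameters(gt, epochs[sid], config)
            results.append(
                SubjectResult(
                    sid,
                    arms[sid],
                    subject_sets[sid],
                    ls,
                    MicrostateParameters(
                        params.classes,
                        params.duration_ms,
                        params.occurrence_hz,
                        params.coverage_pct,
                        params.n_segments,
                        subject=sid,
                    ),
                    TransitionMatrix(
                        trans.classes,
                        trans.counts,
                        trans.conditional,
                        trans.joint,
                        trans.has_transitions,
                        subject=sid,
                    ),
                )
            )
    results.sort(key=lambda r: r.subject)
    params_df = pd.concat([r.parameters.to_frame() for r in results], ignore_index=True)
    trans_df = pd.concat([r.transitions.to_frame() for r in results], ignore_index=True)
    return CohortAnalysis(results, gts, params_df, trans_df)
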