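"""Ground-truth EEG simulator for microstate analysis.

The generator plants the exact quantities the analysis pipeline is meant
to recover.  Brain states follow a semi-Markov model: dwell times are
drawn per class from a gamma law (floored at 10 ms), successors from a
zero-diagonal transition matrix.  Each state projects a fixed dipolar
scalp topography modulated by an alpha-band sinusoidal carrier, so the
recording shows GFP peaks twice per carrier cycle and polarity reversals
— exactly the structure polarity-invariant microstate clustering assumes.
Spatially white Gaussian sensor noise is added at a chosen SNR (RMS of
the state signal over RMS of the noise).

Cohorts add between-subject variability (per-subject jitter of the class
mean durations) and a clinical table whose named symptom score is drawn
with a planted Pearson correlation to a named planted dynamics parameter,
mirroring the correlation analyses of two-arm resting-state studies.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import LabelSequence, MicrostateParameters, TransitionMatrix, temporal_parameters, transition_matrix
from .microstates import CANONICAL_CLASSES, TemplateSet, normalize_maps
from .montage import Montage, standard_1020_montage
from .preprocess import EEGRecording
from .stats import DEFAULT_HAMD24_FACTORS

__all__ = [
    "DynamicsSpec",
    "GroundTruth",
    "ClinicalModel",
    "CohortSpec",
    "SubjectData",
    "Cohort",
    "make_canonical_templates",
    "simulate_state_sequence",
    "synthesize_recording",
    "simulate_subject",
    "simulate_cohort",
]

#: Gaussian sources (x, y, sigma, amplitude) of each canonical class on
#: the unit disc (+y anterior, +x right): A couples a right-frontal
#: maximum with a left-posterior minimum, B is its mirror image, C an
#: anterior-posterior axis, D a focal fronto-central maximum (average
#: referencing supplies its surround negativity).
_CANONICAL_SOURCES: dict[str, tuple[tuple[float, float, float, float], ...]] = {
    "A": ((0.70, 0.45, 0.45, 1.0), (-0.65, -0.55, 0.45, -1.0)),
    "B": ((-0.70, 0.45, 0.45, 1.0), (0.65, -0.55, 0.45, -1.0)),
    "C": ((0.00, 0.85, 0.55, 1.0), (0.00, -0.85, 0.55, -1.0)),
    "D": ((0.00, 0.20, 0.30, 1.0),),
}


@dataclass(frozen=True)
class DynamicsSpec:
    """Semi-Markov microstate dynamics of one study arm.

    ``mean_duration_ms`` and ``duration_shape`` parameterize the per-class
    gamma dwell-time law (shape 4 keeps realized durations in the quasi-
    stable 60-120 ms band for means in that range); ``transition`` is the
    4x4 conditional successor matrix with zero diagonal; ``carrier_hz``
    the oscillatory carrier (10 Hz, the eyes-closed alpha peak);  ``snr``
    the state-signal-to-noise RMS ratio.
    """

    mean_duration_ms: tuple[float, ...] = (60.0, 60.0, 80.0, 70.0)
    duration_shape: tuple[float, ...] = (4.0, 4.0, 4.0, 4.0)
    transition: np.ndarray = field(
        default_factory=lambda: (np.ones((4, 4)) - np.eye(4)) / 3.0
    )
    carrier_hz: float = 10.0
    snr: float = 10.0
    min_duration_ms: float = 10.0

    def __post_init__(self) -> None:
        tr = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "transition", tr)
        k = len(self.mean_duration_ms)
        if len(self.duration_shape) != k:
            raise ValueError("one shape parameter per class required")
        if any(m <= 0 for m in self.mean_duration_ms):
            raise ValueError("mean durations must be positive")
        if any(s <= 0 for s in self.duration_shape):
            raise ValueError("duration shapes must be positive")
        if tr.shape != (k, k):
            raise ValueError(f"transition matrix must be ({k}, {k})")
        if np.any(np.diag(tr) != 0):
            raise ValueError("transition diagonal must be zero")
        if np.any(tr < 0):
            raise ValueError("transition probabilities must be non-negative")
        rows = tr.sum(axis=1)
        if np.any(rows == 0):
            raise ValueError("degenerate all-zero transition row")
        if not np.allclose(rows, 1.0):
            raise ValueError("transition rows must sum to 1")
        if not self.snr > 0:
            raise ValueError("SNR must be positive")
        if self.carrier_hz <= 0:
            raise ValueError("carrier frequency must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.mean_duration_ms)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, and what the generated sequence actually realized."""

    labels: LabelSequence
    templates: TemplateSet | None
    planted_duration_ms: np.ndarray
    planted_transition: np.ndarray
    realized: MicrostateParameters
    realized_transition: TransitionMatrix

    def __post_init__(self) -> None:
        cov = np.nansum(self.realized.coverage_pct)
        if self.labels.n_frames and abs(cov - 100.0) > 1e-6:
            raise ValueError("realized coverages must sum to 100%")


@dataclass(frozen=True)
class ClinicalModel:
    """Generative model of the planted symptom-dynamics correlation.

    The named score (a HAMD-24 factor) is drawn bivariate-normally against
    the subject-level planted dynamics parameter — the z-scored jitter of
    ``dynamics_class``'s mean duration — with correlation ``rho``, then
    rounded and clipped to the instrument range.
    """

    score: str = "anxiety_somatization"
    mean: float = 5.50
    sd: float = 2.61
    rho: float = -0.40
    dynamics_class: str = "C"
    madrs_missing: int = 1  # ratings absent for this many patients

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|planted correlation| must be < 1")
        if self.sd <= 0 and self.rho != 0:
            raise ValueError("correlation target incompatible with zero score SD")


@dataclass(frozen=True)
class CohortSpec:
    """A two-arm cohort: sizes, per-arm dynamics, recording geometry, clinical model."""

    n_per_arm: tuple[int, int] = (30, 40)
    arms: tuple[str, str] = ("patient", "control")
    dynamics: tuple[DynamicsSpec, DynamicsSpec] = (DynamicsSpec(), DynamicsSpec())
    length_s: float = 180.0
    sfreq: float = 1000.0
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    between_subject_cv: float = 0.08
    template_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_arm):
            raise ValueError("each arm needs at least one subject")
        if self.sfreq <= 0 or self.length_s <= 0:
            raise ValueError("positive recording length and rate required")


@dataclass(frozen=True)
class SubjectData:
    subject: str
    arm: str
    recording: EEGRecording | None  # None in sequences-only cohorts
    ground_truth: GroundTruth


@dataclass(frozen=True)
class Cohort:
    subjects: list[SubjectData]
    clinical: pd.DataFrame
    templates: TemplateSet
    spec: CohortSpec


def _gaussian_field(montage: Montage, sources: tuple[tuple[float, float, float, float], ...]) -> np.ndarray:
    xy = montage.positions
    out = np.zeros(montage.n_channels)
    for cx, cy, sigma, amp in sources:
        d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        out += amp * np.exp(-d2 / (2.0 * sigma**2))
    return out


def make_canonical_templates(montage: Montage, seed: int = 0, jitter: float = 0.0) -> TemplateSet:
    """Four canonical dipolar template maps on the given montage.

    Each map is a smooth field from two opposite-signed Gaussian sources
    at the class's characteristic scalp positions, average-referenced and
    unit-normed.  ``jitter`` adds seeded Gaussian topographic noise (as a
    fraction of map norm) to emulate between-subject template variability;
    the default 0 gives deterministic canonical maps.
    """
    if montage.n_channels < 4:
        raise ValueError("need at least 4 channels for 4 template classes")
    maps = np.array([_gaussian_field(montage, _CANONICAL_SOURCES[c]) for c in CANONICAL_CLASSES])
    maps = normalize_maps(maps)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(maps.shape) / np.sqrt(montage.n_channels)
        maps = normalize_maps(maps + jitter * noise)
    return TemplateSet(maps, montage, CANONICAL_CLASSES)


def simulate_state_sequence(
    dyn: DynamicsSpec, length_s: float, fs: float, seed: int | np.random.Generator = 0
) -> tuple[LabelSequence, GroundTruth]:
    """Draw a semi-Markov label sequence and record its ground truth.

    Segment lengths come from the class's gamma law (floored at
    ``min_duration_ms``, rounded to at least one frame); successors from
    the class's transition row; the initial class is uniform.  The ground
    truth stores both the planted parameters and the statistics actually
    realized by the finite sequence (computed by run-length encoding).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = int(round(length_s * fs))
    k = dyn.n_classes
    mean_frames = np.asarray(dyn.mean_duration_ms) * fs / 1000.0
    if n_frames < 10 * mean_frames.mean():
        raise ValueError("sequence must cover at least ~10 mean dwell times")
    labels = np.empty(n_frames, dtype=int)
    pos = 0
    state = int(rng.integers(k))
    min_frames = dyn.min_duration_ms * fs / 1000.0
    while pos < n_frames:
        shape = dyn.duration_shape[state]
        if np.isinf(shape):  # degenerate gamma: deterministic dwell time
            dur = mean_frames[state]
        else:
            dur = rng.gamma(shape, mean_frames[state] / shape)
        nf = max(int(round(max(dur, min_frames))), 1)
        labels[pos : pos + nf] = state
        pos += nf
        state = int(rng.choice(k, p=dyn.transition[state]))
    ls = LabelSequence(labels, fs, ((0, n_frames),), CANONICAL_CLASSES[:k])
    gt = GroundTruth(
        labels=ls,
        templates=None,
        planted_duration_ms=np.asarray(dyn.mean_duration_ms, float),
        planted_transition=dyn.transition.copy(),
        realized=temporal_parameters(ls),
        realized_transition=transition_matrix(ls),
    )
    return ls, gt


def synthesize_recording(
    templates: TemplateSet,
    labels: LabelSequence,
    dyn: DynamicsSpec,
    seed: int | np.random.Generator = 0,
    rms_uv: float = 10.0,
) -> EEGRecording:
    """Project a label sequence through template topographies into sensor EEG.

    Each frame is ``carrier(t) * template(label(t)) + noise``: the carrier
    is a unit sinusoid at ``dyn.carrier_hz`` (constant amplitude within
    any segment, since segments share the global carrier), scaled so the
    state signal has per-channel RMS ``rms_uv``; the noise is spatially
    white Gaussian with RMS ``rms_uv / dyn.snr``.  An infinite SNR yields
    a noiseless recording.
    """
    if not dyn.snr > 0:
        raise ValueError("SNR must be positive")
    if templates.k < len(set(labels.labels[labels.labels >= 0])):
        raise ValueError("labels refer to more classes than there are templates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = labels.sfreq
    n = labels.n_frames
    t = np.arange(n) / fs
    carrier = np.sin(2.0 * np.pi * dyn.carrier_hz * t)
    k_ch = templates.montage.n_channels
    # unit-norm template -> per-channel RMS 1/sqrt(K); sinusoid RMS 1/sqrt(2)
    alpha = rms_uv * np.sqrt(2.0) * np.sqrt(k_ch)
    data = alpha * templates.maps[labels.labels].T * carrier[None, :]
    if np.isfinite(dyn.snr):
        data = data + rng.normal(0.0, rms_uv / dyn.snr, size=data.shape)
    return EEGRecording(data, fs, templates.montage, reference="nose")


def simulate_subject(
    templates: TemplateSet,
    dyn: DynamicsSpec,
    length_s: float,
    fs: float,
    seed: int | np.random.Generator,
    rms_uv: float = 10.0,
) -> tuple[EEGRecording, GroundTruth]:
    """One subject: sequence + recording, with templates attached to the truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ls, gt = simulate_state_sequence(dyn, length_s, fs, rng)
    rec = synthesize_recording(templates, ls, dyn, rng, rms_uv=rms_uv)
    return rec, replace(gt, templates=templates)


# ---------------------------------------------------------------------------
# clinical scores

_FACTOR_MOMENTS = {  # instrument-level moments used for non-target factors
    "anxiety_somatization": (5.50, 2.61),
    "weight": (0.63, 0.85),
    "cognitive_impairment": (5.00, 2.64),
    "diurnal_variation": (0.73, 0.64),
    "retardation": (2.37, 1.71),
    "sleep_disorder": (2.93, 1.62),
    "sense_of_despair": (5.90, 2.28),
}
_AGE_MOMENTS = {"patient": (26.40, 7.36), "control": (24.10, 5.99)}
_EDU_MOMENTS = {"patient": (14.30, 3.53), "control": (15.85, 2.55)}
_MALE_P = {"patient": 8 / 30, "control": 16 / 40}
_HAMA_MOMENTS = (18.47, 7.67)
_MADRS_MOMENTS = (22.10, 8.67)
_ITEM_MAX = 4


def _distribute_items(total: int, n_items: int, rng: np.random.Generator) -> np.ndarray:
    """Spread an integer factor score over its items (0..4 each)."""
    items = np.zeros(n_items, dtype=int)
    order = rng.permutation(n_items)
    left = int(min(total, n_items * _ITEM_MAX))
    i = 0
    while left > 0:
        ch = order[i % n_items]
        if items[ch] < _ITEM_MAX:
            items[ch] += 1
            left -= 1
        i += 1
    return items


def _clinical_row(
    arm: str,
    z_latent: float,
    model: ClinicalModel,
    rng: np.random.Generator,
) -> dict:
    """One subject's demographic and (patients only) symptom scores."""
    row: dict = {"arm": arm}
    am, asd = _AGE_MOMENTS[arm]
    em, esd = _EDU_MOMENTS[arm]
    row["age"] = float(np.clip(np.round(rng.normal(am, asd)), 16, 60))
    row["sex"] = "male" if rng.random() < _MALE_P[arm] else "female"
    row["education_years"] = float(np.clip(np.round(rng.normal(em, esd)), 5, 25))
    items = np.full(24, np.nan)
    row["hama"] = np.nan
    row["madrs"] = np.nan
    if arm == "patient":
        for name, (fm, fsd) in _FACTOR_MOMENTS.items():
            idx = DEFAULT_HAMD24_FACTORS[name]
            if name == model.score:
                raw = model.mean + model.sd * (
                    model.rho * z_latent + np.sqrt(1.0 - model.rho**2) * rng.standard_normal()
                )
            else:
                raw = rng.normal(fm, fsd)
            total = int(np.clip(np.round(raw), 0, len(idx) * _ITEM_MAX))
            vals = _distribute_items(total, len(idx), rng)
            for j, item in enumerate(idx):
                items[item - 1] = vals[j]
        row["hama"] = float(np.clip(np.round(rng.normal(*_HAMA_MOMENTS)), 0, 56))
        row["madrs"] = float(np.clip(np.round(rng.normal(*_MADRS_MOMENTS)), 0, 60))
    for i in range(24):
        row[f"hamd{i + 1:02d}"] = items[i]
    return row


def _subject_dynamics(
    base: DynamicsSpec, cv: float, rng: np.random.Generator
) -> tuple[DynamicsSpec, np.ndarray]:
    """Jitter per-class mean durations; returns the spec and the z-scores used."""
    if cv <= 0:
        return base, np.zeros(base.n_classes)
    z = rng.standard_normal(base.n_classes)
    means = np.asarray(base.mean_duration_ms) * (1.0 + cv * z)
    means = np.maximum(means, 2.0 * base.min_duration_ms)
    return replace(base, mean_duration_ms=tuple(means)), z


def simulate_cohort(
    spec: CohortSpec,
    montage: Montage | None = None,
    rms_uv: float = 10.0,
    sequences_only: bool = False,
) -> Cohort:
    """Generate a full two-arm cohort with clinical table and ground truth.

    Per-subject seeds are spawned deterministically from ``spec.seed``,
    with independent streams for dynamics, sensor noise and clinical
    scores (so ``sequences_only`` cohorts share their sequences and
    clinical tables with the corresponding full cohorts).  Subjects
    within an arm share the arm's :class:`DynamicsSpec` up to the
    between-subject jitter of mean durations; the jitter z-score of the
    clinical model's named class is the latent against which the target
    symptom score is planted.

    With ``sequences_only`` no sensor EEG is synthesized (recordings are
    None) — orders of magnitude cheaper, for studies of the planted
    dynamics and statistics alone.  Memory for full cohorts scales as
    ``sum(n) * length_s * sfreq * K * 8`` bytes — stream subjects via
    :func:`mstates.io.write_cohort` at full size.
    """
    montage = montage or standard_1020_montage()
    master = np.random.SeedSequence(spec.seed)
    tmpl_rng, clin_master, *subj_seeds = master.spawn(2 + sum(spec.n_per_arm))
    templates = make_canonical_templates(
        montage, seed=int(tmpl_rng.generate_state(1)[0] % (2**31)), jitter=spec.template_jitter
    )
    subjects: list[SubjectData] = []
    rows: list[dict] = []
    target_cls = CANONICAL_CLASSES.index(spec.clinical.dynamics_class)
    s_idx = 0
    for arm, n, dyn in zip(spec.arms, spec.n_per_arm, spec.dynamics):
        for _ in range(n):
            seq_seed, rec_seed, clin_seed = subj_seeds[s_idx].spawn(3)
            rng_dyn = np.random.default_rng(seq_seed)
            rng_clin = np.random.default_rng(clin_seed)
            sid = f"S{s_idx + 1:03d}"
            sdyn, z = _subject_dynamics(dyn, spec.between_subject_cv, rng_dyn)
            ls, gt = simulate_state_sequence(sdyn, spec.length_s, spec.sfreq, rng_dyn)
            gt = replace(gt, templates=templates)
            if sequences_only:
                rec = None
            else:
                rec = synthesize_recording(
                    templates, ls, sdyn, np.random.default_rng(rec_seed), rms_uv=rms_uv
                )
            subjects.append(SubjectData(sid, arm, rec, gt))
            row = _clinical_row(arm, z[target_cls], spec.clinical, rng_clin)
            row["subject"] = sid
            row["planted_duration_" + spec.clinical.dynamics_class] = sdyn.mean_duration_ms[target_cls]
            rows.append(row)
            s_idx += 1
    clinical = pd.DataFrame(rows)
    clin_rng = np.random.default_rng(clin_master)
    pat_idx = clinical.index[clinical["arm"] == "patient"]
    n_miss = min(spec.clinical.madrs_missing, len(pat_idx))
    if n_miss > 0:
        clinical.loc[clin_rng.choice(pat_idx, size=n_miss, replace=False), "madrs"] = np.nan
    lead = ["subject", "arm", "age", "sex", "education_years"]
    clinical = clinical[lead + [c for c in clinical.columns if c not in lead]]
    return Cohort(subjects, clinical, templates, spec)
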