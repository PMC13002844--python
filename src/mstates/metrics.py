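"""Backfitting and temporal microstate parameters.

Templates are backfitted to the continuous (epoched) EEG by labeling each
frame with the class of highest polarity-invariant spatial correlation.
Label sequences are then smoothed by dissolving short segments (at or
below a minimum number of time frames), and summarized per class as mean
duration (ms), occurrence (appearances per second of analyzed data) and
time coverage (%), plus first-order transition matrices.  Segments never
span epoch boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .microstates import TemplateSet, normalize_maps
from .preprocess import EpochSet

__all__ = [
    "LabelSequence",
    "Segment",
    "MicrostateParameters",
    "TransitionMatrix",
    "backfit",
    "segments_of",
    "reject_short_segments",
    "temporal_parameters",
    "transition_matrix",
]

UNLABELED = -1


@dataclass(frozen=True)
class LabelSequence:
    """Per-frame class labels with epoch boundaries.

    ``labels`` holds class indices into ``classes`` (-1 = unlabeled);
    ``epoch_bounds`` are half-open (start, stop) frame ranges, one per
    epoch; ``corr`` optionally carries the per-frame polarity-invariant
    correlation with each template (used by segment smoothing).
    """

    labels: np.ndarray = field(repr=False)
    sfreq: float
    epoch_bounds: tuple[tuple[int, int], ...]
    classes: tuple[str, ...]
    corr: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if labels.size and (labels.max() >= len(self.classes) or labels.min() < UNLABELED):
            raise ValueError("labels out of range for the class set")
        starts = [b[0] for b in self.epoch_bounds]
        if starts != sorted(starts):
            raise ValueError("epoch boundaries must be sorted")
        if self.epoch_bounds and self.epoch_bounds[-1][1] != labels.size:
            raise ValueError("epoch boundaries must cover the label array")
        if self.corr is not None and self.corr.shape != (labels.size, len(self.classes)):
            raise ValueError("corr must be (n_frames, n_classes)")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def analyzed_seconds(self) -> float:
        return self.n_frames / self.sfreq


@dataclass(frozen=True)
class Segment:
    """A maximal run of one class within a single epoch (half-open frames)."""

    class_index: int
    start: int
    stop: int
    sfreq: float
    truncated: bool  # touches an epoch edge
    epoch: int = 0

    @property
    def n_frames(self) -> int:
        return self.stop - self.start

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.sfreq


@dataclass(frozen=True)
class MicrostateParameters:
    """Per-class temporal parameters of one subject's label sequence."""

    classes: tuple[str, ...]
    duration_ms: np.ndarray  # nan where a class never occurs
    occurrence_hz: np.ndarray
    coverage_pct: np.ndarray
    n_segments: np.ndarray
    subject: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "class": list(self.classes),
                "duration_ms": self.duration_ms,
                "occurrence_hz": self.occurrence_hz,
                "coverage_pct": self.coverage_pct,
                "n_segments": self.n_segments,
            }
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """First-order transition statistics between classes.

    ``conditional[i, j]`` is p(next = j | current = i) over within-epoch
    segment boundaries (zero diagonal); ``joint`` normalizes the same
    counts by the total number of observed transitions.
    """

    classes: tuple[str, ...]
    counts: np.ndarray
    conditional: np.ndarray
    joint: np.ndarray
    has_transitions: bool
    subject: str | None = None

    def to_frame(self) -> pd.DataFrame:
        k = len(self.classes)
        rows = []
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                rows.append(
                    {
                        "subject": self.subject,
                        "from": self.classes[i],
                        "to": self.classes[j],
                        "probability": self.conditional[i, j],
                        "joint_probability": self.joint[i, j],
                        "count": int(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def backfit(templates: TemplateSet, ep: EpochSet) -> LabelSequence:
    """Label every frame with the best-correlated template class.

    Frames are compared with each template by polarity-invariant spatial
    correlation; zero-variance frames (no topography) inherit the label of
    the nearest labeled frame within the same epoch.
    """
    if ep.reference != "average":
        raise ValueError("backfit requires average-referenced epochs")
    maps = normalize_maps(templates.maps)  # idempotent for valid sets
    data = ep.kept_data  # (n_ep, K, T)
    n_ep, n_ch, n_t = data.shape
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)  # (n_ep, T)
    corr = np.abs(np.einsum("kc,ect->ekt", maps, centered))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(norms[:, None, :] > 0, corr / norms[:, None, :], 0.0)
    labels = np.argmax(corr, axis=1)  # (n_ep, T)
    flat = np.where(norms > 0, labels, UNLABELED)

    # nearest labeled neighbor fill, per epoch
    for e in range(n_ep):
        row = flat[e]
        bad = np.nonzero(row == UNLABELED)[0]
        good = np.nonzero(row != UNLABELED)[0]
        if bad.size and good.size:
            nearest = good[np.argmin(np.abs(bad[:, None] - good[None, :]), axis=1)]
            row[bad] = row[nearest]

    bounds = tuple((e * n_t, (e + 1) * n_t) for e in range(n_ep))
    return LabelSequence(
        labels=flat.ravel(),
        sfreq=ep.sfreq,
        epoch_bounds=bounds,
        classes=templates.labels,
        corr=np.moveaxis(corr, 1, 2).reshape(-1, templates.k),
    )


def segments_of(ls: LabelSequence) -> list[Segment]:
    """Run-length encode the sequence into within-epoch segments."""
    out: list[Segment] = []
    for e, (start, stop) in enumerate(ls.epoch_bounds):
        lab = ls.labels[start:stop]
        if lab.size == 0:
            continue
        change = np.nonzero(np.diff(lab))[0] + 1
        edges = np.concatenate([[0], change, [lab.size]])
        for a, b in zip(edges[:-1], edges[1:]):
            out.append(
                Segment(
                    class_index=int(lab[a]),
                    start=start + int(a),
                    stop=start + int(b),
                    sfreq=ls.sfreq,
                    truncated=(a == 0 or b == lab.size),
                    epoch=e,
                )
            )
    return out


def reject_short_segments(ls: LabelSequence, min_tf: int = 20) -> LabelSequence:
    """Dissolve segments of at most ``min_tf`` frames.

    Iteratively, the shortest interior segment no longer than ``min_tf``
    frames (earliest on ties) is dissolved: each of its frames joins the
    flanking segment whose template correlates higher with that frame
    (falling back to the nearer flank when no correlations are attached).
    Epoch-edge segments are exempt — they are truncated, not short.  The
    result has no interior segment of ``min_tf`` frames or fewer.
    """
    if min_tf < 1:
        return ls
    total = ls.n_frames
    if total <= min_tf:
        import warnings

        warnings.warn("sequence no longer than min_tf; returned unchanged")
        return ls
    labels = ls.labels.copy()
    for start, stop in ls.epoch_bounds:
        lab = labels[start:stop]
        while True:
            change = np.nonzero(np.diff(lab))[0] + 1
            edges = np.concatenate([[0], change, [lab.size]])
            lens = np.diff(edges)
            if lens.size <= 2:
                break
            interior = np.arange(1, lens.size - 1)
            short = interior[lens[interior] <= min_tf]
            if short.size == 0:
                break
            s = short[np.argmin(lens[short])]
            a, b = edges[s], edges[s + 1]
            left_cls, right_cls = int(lab[a - 1]), int(lab[b])  # interior: both flanks exist
            for i in range(a, b):
                if ls.corr is not None:
                    go_left = ls.corr[start + i, left_cls] >= ls.corr[start + i, right_cls]
                else:
                    go_left = (i - a) <= (b - 1 - i)
                lab[i] = left_cls if go_left else right_cls
    return replace(ls, labels=labels)


def temporal_parameters(ls: LabelSequence, exclude_truncated_duration: bool = False) -> MicrostateParameters:
    """Per-class mean duration, occurrence and coverage.

    Segments are computed per epoch and pooled.  Occurrence divides the
    segment count by the analyzed (kept-epoch) time; coverage is the share
    of labeled frames.  With ``exclude_truncated_duration`` epoch-edge
    segments still count toward occurrence and coverage but not toward the
    mean duration.
    """
    k = len(ls.classes)
    segs = segments_of(ls)
    secs = ls.analyzed_seconds
    dur = np.full(k, np.nan)
    occ = np.zeros(k)
    cov = np.zeros(k)
    nseg = np.zeros(k, dtype=int)
    for c in range(k):
        mine = [s for s in segs if s.class_index == c]
        nseg[c] = len(mine)
        if mine:
            occ[c] = len(mine) / secs
            cov[c] = 100.0 * sum(s.n_frames for s in mine) / ls.n_frames
            for_dur = [s for s in mine if not (exclude_truncated_duration and s.truncated)]
            if for_dur:
                dur[c] = float(np.mean([s.duration_ms for s in for_dur]))
    return MicrostateParameters(ls.classes, dur, occ, cov, nseg)


def transition_matrix(ls: LabelSequence) -> TransitionMatrix:
    """First-order transition counts and probabilities.

    Transitions are counted at within-epoch segment boundaries only;
    junctions between epochs are excluded.  ``conditional`` row-normalizes
    the counts (rows with no outgoing transition stay zero); ``joint``
    normalizes by the total transition count.
    """
    k = len(ls.classes)
    counts = np.zeros((k, k))
    segs = segments_of(ls)
    for prev, nxt in zip(segs[:-1], segs[1:]):
        if prev.epoch == nxt.epoch and prev.stop == nxt.start:
            if prev.class_index != UNLABELED and nxt.class_index != UNLABELED:
                counts[prev.class_index, nxt.class_index] += 1
    total = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conditional = np.where(row > 0, counts / row, 0.0)
        joint = counts / total if total > 0 else np.zeros_like(counts)
    return TransitionMatrix(ls.classes, counts, conditional, joint, has_transitions=total > 0)
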