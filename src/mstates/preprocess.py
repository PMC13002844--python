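"""Signal conditioning from continuous recording to clean average-referenced epochs.

The chain mirrors a standard resting-state pipeline: zero-phase band-pass
filtering of the continuous record (a broad 1-40 Hz stage followed by the
2-20 Hz stage used for microstate segmentation), segmentation into fixed
non-overlapping epochs with an amplitude-based rejection rule, and
re-referencing to the common average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .montage import Montage

__all__ = [
    "EEGRecording",
    "EpochSet",
    "bandpass",
    "segment_epochs",
    "average_reference",
    "drop_channels",
]


@dataclass(frozen=True)
class EEGRecording:
    """Continuous multichannel EEG.

    ``data`` is channels x samples in microvolts; ``reference`` names the
    recording reference ("average" or a channel/site label such as "nose").
    """

    data: np.ndarray = field(repr=False)
    sfreq: float
    montage: Montage
    reference: str = "nose"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data must be (n_channels={self.montage.n_channels}, n_samples), got {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite samples")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


@dataclass(frozen=True)
class EpochSet:
    """Ordered fixed-length epochs with per-epoch QC flags.

    ``data`` holds every extracted epoch (kept or not) as
    ``(n_epochs, n_channels, n_samples)``; ``kept`` and ``reject_reason``
    record the QC outcome.  Analyses run on :attr:`kept_data`.
    """

    data: np.ndarray = field(repr=False)
    sfreq: float
    montage: Montage
    kept: np.ndarray
    reject_reason: tuple[str, ...]
    reference: str = "nose"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_epochs, n_channels, n_samples)")
        if len(self.kept) != self.data.shape[0] or len(self.reject_reason) != self.data.shape[0]:
            raise ValueError("QC flags must match the number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.kept))

    @property
    def epoch_len(self) -> int:
        return self.data.shape[2]

    @property
    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]

    def qc_table(self):
        """Epoch-level QC report (epoch index, kept flag, reason)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "kept": np.asarray(self.kept, bool),
                "reason": list(self.reject_reason),
            }
        )


def drop_channels(rec: EEGRecording, names: list[str]) -> EEGRecording:
    """Remove channels (e.g. EOG electrodes) before analysis."""
    keep = [n for n in rec.montage.names if n not in set(names)]
    idx = [rec.montage.index(n) for n in keep]
    return EEGRecording(rec.data[idx], rec.sfreq, rec.montage.subset(keep), rec.reference)


def bandpass(rec: EEGRecording, low: float, high: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass of the continuous record.

    A forward-backward (filtfilt) pass of an ``order``-per-edge Butterworth
    design: DC and out-of-band components are suppressed while passband
    amplitude and phase are preserved.
    """
    nyq = rec.sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={rec.sfreq} Hz")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=rec.sfreq, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def segment_epochs(rec: EEGRecording, epoch_s: float = 2.0, reject_uv: float | None = 100.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs and flag amplitude artifacts.

    An epoch is rejected when any sample on any channel strictly exceeds
    ``reject_uv`` in absolute value (a sample exactly at the threshold is
    kept).  The trailing partial epoch is dropped.
    """
    n_per = int(round(epoch_s * rec.sfreq))
    if n_per < 1 or rec.n_samples < n_per:
        raise ValueError("recording shorter than one epoch")
    n_epochs = rec.n_samples // n_per
    data = rec.data[:, : n_epochs * n_per].reshape(rec.n_channels, n_epochs, n_per)
    data = np.ascontiguousarray(np.moveaxis(data, 1, 0))

    kept = np.ones(n_epochs, dtype=bool)
    reasons = [""] * n_epochs
    if reject_uv is not None:
        bad = np.max(np.abs(data), axis=(1, 2)) > reject_uv
        kept[bad] = False
        for i in np.nonzero(bad)[0]:
            reasons[i] = "amplitude"
    return EpochSet(data, rec.sfreq, rec.montage, kept, tuple(reasons), rec.reference)


def average_reference(ep: EpochSet) -> EpochSet:
    """Re-reference every epoch to the common average.

    After this the instantaneous mean across channels is zero at every
    sample; the operation is idempotent and erases whatever reference the
    data carried before.
    """
    if ep.montage.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = ep.data - ep.data.mean(axis=1, keepdims=True)
    return replace(ep, data=data, reference="average")
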