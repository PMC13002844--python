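"""File interfaces: BrainVision recordings, ground truth, tables, templates.

Recordings are written in the BrainVision triplet (.vhdr/.vmrk/.eeg,
multiplexed IEEE float32 in microvolts) and read back through mne, which
also provides the EDF reader.  Ground-truth label sequences travel as
run-length TSV (class, start_frame, end_frame; half-open, 0-based) with a
JSON sidecar of planted and realized parameters; clinical tables and
templates as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import LabelSequence, segments_of
from .microstates import TemplateSet
from .montage import Montage, standard_1020_montage
from .preprocess import EEGRecording
from .synthetic import Cohort, CohortSpec, GroundTruth, simulate_cohort

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "read_edf",
    "write_labels_tsv",
    "read_labels_tsv",
    "write_ground_truth",
    "write_templates_tsv",
    "read_templates_tsv",
    "write_cohort",
]


def write_brainvision(rec: EEGRecording, basename: str | Path) -> Path:
    """Write a recording as a BrainVision .vhdr/.vmrk/.eeg triplet.

    Data are stored multiplexed (sample-major) as IEEE float32 in
    microvolts with unit resolution.  Returns the header path.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.sfreq:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.montage.names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk.write_text(
        "\n".join(
            [
                "Brain Vision Data Exchange Marker File, Version 1.0",
                "",
                "[Common Infos]",
                "Codepage=UTF-8",
                f"DataFile={stem}.eeg",
                "",
                "[Marker Infos]",
                "Mk1=New Segment,,1,1,0,0",
            ]
        )
        + "\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def _montage_for(names: list[str]) -> Montage:
    try:
        return standard_1020_montage(tuple(names))
    except ValueError:
        # non 10-20 names: place channels on a circle so the container stays valid
        ang = 2 * np.pi * np.arange(len(names)) / len(names)
        return Montage(tuple(names), np.column_stack([np.cos(ang), np.sin(ang)]))


def _from_mne_raw(raw, reference: str) -> EEGRecording:
    data_uv = raw.get_data() * 1e6
    return EEGRecording(data_uv, raw.info["sfreq"], _montage_for(raw.ch_names), reference)


def read_brainvision(vhdr_path: str | Path, reference: str = "nose") -> EEGRecording:
    """Read a BrainVision recording (positions from the standard 10-20 layout)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="ERROR")
    return _from_mne_raw(raw, reference)


def read_edf(path: str | Path, reference: str = "nose") -> EEGRecording:
    """Read an EDF/EDF+ recording."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    return _from_mne_raw(raw, reference)


def write_labels_tsv(ls: LabelSequence, path: str | Path) -> None:
    """Run-length encode a label sequence to TSV (half-open, 0-based frames)."""
    rows = [
        {"class": ls.classes[s.class_index], "start_frame": s.start, "end_frame": s.stop}
        for s in segments_of(ls)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | Path, sfreq: float, classes: tuple[str, ...]) -> LabelSequence:
    df = pd.read_csv(path, sep="\t")
    n = int(df["end_frame"].max())
    labels = np.full(n, -1, dtype=int)
    for _, row in df.iterrows():
        labels[int(row["start_frame"]) : int(row["end_frame"])] = classes.index(row["class"])
    return LabelSequence(labels, sfreq, ((0, n),), classes)


def write_ground_truth(gt: GroundTruth, basename: str | Path) -> None:
    """Ground truth as run-length TSV plus a JSON parameter sidecar."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    write_labels_tsv(gt.labels, base.parent / (base.name + ".labels.tsv"))
    meta = {
        "classes": list(gt.labels.classes),
        "sfreq": gt.labels.sfreq,
        "n_frames": gt.labels.n_frames,
        "planted_duration_ms": gt.planted_duration_ms.tolist(),
        "planted_transition": gt.planted_transition.tolist(),
        "realized_duration_ms": gt.realized.duration_ms.tolist(),
        "realized_occurrence_hz": gt.realized.occurrence_hz.tolist(),
        "realized_coverage_pct": gt.realized.coverage_pct.tolist(),
        "realized_transition": gt.realized_transition.conditional.tolist(),
    }
    (base.parent / (base.name + ".json")).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def write_templates_tsv(ts: TemplateSet, path: str | Path) -> None:
    """Templates as a channel x class TSV (plus GEV in a JSON sidecar)."""
    df = pd.DataFrame(ts.maps.T, index=list(ts.montage.names), columns=list(ts.labels))
    df.index.name = "channel"
    df.to_csv(path, sep="\t")
    meta = {"labels": list(ts.labels), "gev": ts.gev}
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_templates_tsv(path: str | Path, montage: Montage | None = None) -> TemplateSet:
    df = pd.read_csv(path, sep="\t", index_col="channel")
    montage = montage or _montage_for(list(df.index))
    return TemplateSet(df.to_numpy().T, montage, tuple(df.columns))


def write_cohort(spec: CohortSpec, out_dir: str | Path, montage=None, rms_uv: float = 10.0) -> Cohort:
    """Simulate a cohort and write recordings, truth and clinical table.

    Creates ``<out_dir>/<subject>.vhdr`` triplets, per-subject ground
    truth, ``clinical.tsv`` and the planted ``templates.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(spec, montage=montage, rms_uv=rms_uv)
    for s in cohort.subjects:
        write_brainvision(s.recording, out / s.subject)
        write_ground_truth(s.ground_truth, out / f"{s.subject}.truth")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    write_templates_tsv(cohort.templates, out / "templates.tsv")
    return cohort
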