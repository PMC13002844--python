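"""Sensor layouts for scalp EEG.

A :class:`Montage` is the minimal geometric description the microstate
machinery needs: channel names plus 2-D positions obtained by azimuthal
(polar) projection of the scalp sphere onto the unit disc, with the nose
pointing to +y and the right ear to +x.  Standard 10-20 layouts are pulled
from mne's built-in montage definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "standard_1020_montage", "ACTICAP_64_NAMES"]

#: Channel names of a widely used 64-channel 10-20 cap (actiCAP layout).
ACTICAP_64_NAMES: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1",
    "C5", "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8",
    "P6", "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6",
    "AF8", "AF4", "F2", "Iz",
)


@dataclass(frozen=True)
class Montage:
    """Channel names and unit-disc positions of an EEG cap.

    Parameters
    ----------
    names
        Unique channel labels, in recording order.
    positions
        ``(K, 2)`` array of projected positions; anterior is +y, right
        is +x, and the head circumference maps near radius 1.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        if len(self.names) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if pos.shape != (len(self.names), 2):
            raise ValueError(f"positions must be ({len(self.names)}, 2), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, keep: list[str]) -> "Montage":
        """Montage restricted to ``keep`` (in the given order)."""
        idx = [self.index(n) for n in keep]
        return Montage(tuple(keep), self.positions[idx])


def _azimuthal_projection(xyz: np.ndarray) -> np.ndarray:
    """Project 3-D head-sphere coordinates to the unit disc.

    Uses the polar-angle (azimuthal equidistant) projection common for
    topographic maps: radius proportional to the angle from the vertex,
    scaled so the equator (ear level) lands at radius 1.
    """
    xyz = np.asarray(xyz, float)
    r = np.linalg.norm(xyz, axis=1)
    theta = np.arccos(np.clip(xyz[:, 2] / r, -1.0, 1.0))  # angle from vertex
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    rho = theta / (np.pi / 2.0)
    # mne head frame: +x right, +y nose — keep that orientation
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])


def standard_1020_montage(names: tuple[str, ...] | list[str] = ACTICAP_64_NAMES) -> Montage:
    """Build a :class:`Montage` for 10-20 channel names from mne's easycap layout."""
    import mne

    std = mne.channels.make_standard_montage("easycap-M1")
    pos3d = std.get_positions()["ch_pos"]
    missing = [n for n in names if n not in pos3d]
    if missing:
        raise ValueError(f"channels not in the standard 10-20 layout: {missing}")
    xyz = np.array([pos3d[n] for n in names])
    return Montage(tuple(names), _azimuthal_projection(xyz))
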