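"""Electrode montage for the 61-channel modified 10-20 recording layout.

Scalp positions live on the unit sphere (head-centered, +x right, +y anterior,
+z through the vertex). Four EOG channels are carried along for artifact
rejection only: they have no scalp position and never enter interpolation or
the common-average reference.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The 61 scalp channels of the modified international 10-20 layout, in cap order.
SCALP_CHANNELS: tuple[str, ...] = (
    "AF7", "Fp1", "Fpz", "Fp2", "AF8", "AF3", "AFz", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Two vertical + two horizontal EOG channels (bipolar pairs around the eyes).
DEFAULT_EOG: tuple[str, ...] = ("VEOGU", "VEOGL", "HEOGL", "HEOGR")

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class Montage:
    """Channel labels and unit-sphere positions of the scalp electrodes.

    Parameters
    ----------
    labels : tuple of str
        Scalp channel names (order defines the channel axis everywhere).
    positions : ndarray, shape (n_scalp, 3)
        Unit vectors on the head sphere, one row per scalp channel.
    eog_labels : tuple of str
        Names of the EOG channels appended after the scalp channels in
        epoch arrays.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    eog_labels: tuple[str, ...] = DEFAULT_EOG

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "eog_labels", tuple(self.eog_labels))
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.labels)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("scalp positions must lie on the unit sphere (|r|=1 within 1e-6)")
        all_labels = self.labels + self.eog_labels
        if len(set(all_labels)) != len(all_labels):
            raise ValueError("duplicate channel labels in montage")
        object.__setattr__(self, "positions", pos)

    @property
    def n_scalp(self) -> int:
        return len(self.labels)

    @property
    def n_channels(self) -> int:
        """Scalp + EOG channel count (the channel axis of an EpochSet)."""
        return len(self.labels) + len(self.eog_labels)

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.labels + self.eog_labels

    def index(self, label: str) -> int:
        """Index of a scalp channel on the channel axis."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown scalp channel {label!r}") from None

    def arc_distances_mm(self, head_radius_mm: float = 85.0) -> np.ndarray:
        """Pairwise great-circle distances between scalp electrodes, in mm."""
        cosang = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return head_radius_mm * np.arccos(cosang)


def make_default_montage() -> Montage:
    """The 61-channel modified 10-20 montage on an idealized sphere.

    Positions are taken from the standard easycap spherical layout bundled
    with :mod:`mne` (exact sphere, Cz at the vertex, left/right mirror
    symmetric) and normalized to unit radius.
    """
    import mne  # local import: mne is heavy and only needed here

    std = mne.channels.make_standard_montage("easycap-M1")
    ch_pos = std.get_positions()["ch_pos"]
    pos = np.array([ch_pos[ch] for ch in SCALP_CHANNELS], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(labels=SCALP_CHANNELS, positions=pos, eog_labels=DEFAULT_EOG)


def write_montage(montage: Montage, path: str | Path) -> None:
    """Write a montage as tab-separated text: label, x, y, z (unit sphere)."""
    path = Path(path)
    lines = ["# erprep montage: label\tx\ty\tz (unit sphere); EOG rows have nan positions"]
    for lab, p in zip(montage.labels, montage.positions):
        lines.append(f"{lab}\t{p[0]:.9f}\t{p[1]:.9f}\t{p[2]:.9f}")
    for lab in montage.eog_labels:
        lines.append(f"{lab}\tnan\tnan\tnan")
    path.write_text("\n".join(lines) + "\n")


def read_montage(path: str | Path) -> Montage:
    """Read a tab-separated montage file (``label x y z``; '#' comments allowed).

    Rows with non-finite coordinates are treated as EOG channels.
    """
    labels: list[str] = []
    pos: list[list[float]] = []
    eog: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage row: {raw!r}")
        xyz = [float(v) for v in parts[1:]]
        if np.all(np.isfinite(xyz)):
            labels.append(parts[0])
            pos.append(xyz)
        else:
            eog.append(parts[0])
    return Montage(labels=tuple(labels), positions=np.array(pos), eog_labels=tuple(eog))
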