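"""10-10 electrode geometry over the motor cortex and frozen channel selections.

The package works with the 64-electrode 10-10 montage used by the PhysioNet
motor movement/imagery recordings (all 10-10 positions except Nz, F9, F10,
FT9, FT10, A1, A2, TP9, TP10, P9 and P10).  Three selections are frozen:

* ``full64``  – the recording's native channel order, untouched;
* ``motor21`` – the 7x3 block of electrodes covering the motor strip
  (FC/C/CP rows, columns 5,3,1,z,2,4,6), traversed top to bottom then
  left to right;
* ``cross13`` – ``motor21`` minus the eight corner electrodes of the three
  3x3 sub-grids, leaving a cross (plus-sign) around each of C3, Cz and C4.

The same traversal produces the three 3x3 (9-electrode) and cross (5-electrode)
sub-grids centred on C3, Cz and C4, and the volume layouts used by the 3D
tensor representations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple, Union

__all__ = [
    "EEGMMIDB_CHANNELS",
    "ChannelSelection",
    "SubGrid",
    "VolumeGridSpec",
    "normalize_label",
    "selection",
    "subgrids",
    "volume_spec",
    "electrode_position",
]

# Native channel order of the PhysioNet 64-channel motor imagery recordings
# (EDF headers carry these names padded with trailing dots, e.g. "Fc5.").
EEGMMIDB_CHANNELS: Tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "Iz",
)

_CANONICAL = {label.lower(): label for label in EEGMMIDB_CHANNELS}

# Schematic scalp coordinates (x: left-negative lateral position in electrode
# spacings, y: anterior-posterior row).  Used for spatial falloff in the
# synthetic generator and as the geometric oracle for the frozen orderings.
_ROW_Y = {"Fp": 0.0, "AF": 1.0, "F": 2.0, "FT": 3.0, "FC": 3.0, "C": 4.0,
          "T": 4.0, "CP": 5.0, "TP": 5.0, "P": 6.0, "PO": 7.0, "O": 8.0,
          "I": 9.0}
_DIGIT_X = {"z": 0.0, "1": -1.0, "2": 1.0, "3": -2.0, "4": 2.0,
            "5": -3.0, "6": 3.0, "7": -4.0, "8": 4.0, "9": -5.0, "10": 5.0}


def _split_label(label: str) -> Tuple[str, str]:
    i = 0
    while i < len(label) and label[i].isalpha() and label[i] != "z":
        i += 1
    prefix, suffix = label[:i], label[i:]
    if suffix == "":  # Iz, Fpz style handled below
        prefix, suffix = label[:-1], label[-1]
    return prefix, suffix


def electrode_position(label: str) -> Tuple[float, float]:
    """Schematic (x, y) scalp position of a 10-10 electrode.

    x grows to the subject's right in electrode spacings (z-line at 0),
    y grows towards the back of the head (Fp row at 0).
    """
    label = normalize_label(label)
    prefix, suffix = _split_label(label)
    row = "I" if label == "Iz" else prefix
    return _DIGIT_X[suffix], _ROW_Y[row]


def normalize_label(raw: str) -> str:
    """Canonicalize an electrode label from an EDF header.

    Strips trailing dots/whitespace ("Fc5." -> "FC5") and is
    case-insensitive, including on the z suffix (CZ == Cz).
    """
    key = raw.strip().rstrip(".").strip().lower()
    try:
        return _CANONICAL[key]
    except KeyError:
        raise KeyError(f"unknown 10-10 electrode label: {raw!r}") from None


# Motor-strip grid: columns left to right, each column top (FC) to bottom (CP).
# "Top to bottom, left to right" traversal = column-major over this grid.
_MOTOR_COLUMNS: Tuple[Tuple[str, str, str], ...] = (
    ("FC5", "C5", "CP5"),
    ("FC3", "C3", "CP3"),
    ("FC1", "C1", "CP1"),
    ("FCz", "Cz", "CPz"),
    ("FC2", "C2", "CP2"),
    ("FC4", "C4", "CP4"),
    ("FC6", "C6", "CP6"),
)

MOTOR21_ORDER: Tuple[str, ...] = tuple(
    lbl for col in _MOTOR_COLUMNS for lbl in col
)

CROSS13_EXCLUDED: Tuple[str, ...] = (
    "FC5", "CP5", "FC1", "CP1", "FC2", "CP2", "FC6", "CP6"
)

CROSS13_ORDER: Tuple[str, ...] = tuple(
    lbl for lbl in MOTOR21_ORDER if lbl not in CROSS13_EXCLUDED
)

_SUBGRID_COLUMNS = {"C3": (0, 1, 2), "Cz": (2, 3, 4), "C4": (4, 5, 6)}


@dataclass(frozen=True)
class ChannelSelection:
    """An ordered electrode subset with a name and its complement."""

    name: str
    ordered_labels: Tuple[str, ...]
    excluded_labels: Tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.ordered_labels)

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "ordered_labels": list(self.ordered_labels),
            "excluded_labels": list(self.excluded_labels),
        })


@dataclass(frozen=True)
class SubGrid:
    """A 9- or 5-electrode grid centred on C3, Cz or C4."""

    center: str
    ordered_labels: Tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.ordered_labels)

    def to_json(self) -> str:
        return json.dumps({
            "center": self.center,
            "size": self.size,
            "ordered_labels": list(self.ordered_labels),
        })


@dataclass(frozen=True)
class VolumeGridSpec:
    """Layout of a depth x channels x time volume tensor.

    ``layout_labels`` lists the D*C slots in layer-major order; ``None``
    marks a zero-padded slot left by an excluded electrode.
    """

    depth: int
    channels_per_layer: int
    samples_per_channel: int
    layout_labels: Tuple[Optional[str], ...]

    @property
    def zero_positions(self) -> Tuple[Tuple[int, int], ...]:
        c = self.channels_per_layer
        return tuple(
            (i // c, i % c)
            for i, lbl in enumerate(self.layout_labels)
            if lbl is None
        )

    @property
    def real_labels(self) -> Tuple[str, ...]:
        return tuple(l for l in self.layout_labels if l is not None)

    def to_json(self) -> str:
        return json.dumps({
            "depth": self.depth,
            "channels_per_layer": self.channels_per_layer,
            "samples_per_channel": self.samples_per_channel,
            "layout_labels": list(self.layout_labels),
        })


_SELECTIONS = {
    "full64": ChannelSelection("full64", EEGMMIDB_CHANNELS),
    "motor21": ChannelSelection("motor21", MOTOR21_ORDER),
    "cross13": ChannelSelection("cross13", CROSS13_ORDER, CROSS13_EXCLUDED),
}


def selection(name: str) -> ChannelSelection:
    """Return a frozen channel selection: ``full64``, ``motor21`` or ``cross13``."""
    try:
        return _SELECTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown selection {name!r}; expected one of {sorted(_SELECTIONS)}"
        ) from None


def subgrids(size: int) -> Tuple[SubGrid, SubGrid, SubGrid]:
    """The three sub-grids centred on C3, Cz and C4, in that order.

    ``size`` 9 yields the full 3x3 grids; 5 yields the cross (plus-sign)
    grids with the four corner electrodes dropped.  Adjacent 9-grids share
    a full column of three electrodes; adjacent 5-grids share one.
    """
    if size not in (9, 5):
        raise ValueError(f"sub-grid size must be 9 or 5, got {size}")
    out = []
    for center in ("C3", "Cz", "C4"):
        cols = [_MOTOR_COLUMNS[i] for i in _SUBGRID_COLUMNS[center]]
        labels = [lbl for col in cols for lbl in col]
        if size == 5:
            # keep the plus-sign: middle of flanking columns + centre column
            labels = [lbl for lbl in labels if lbl not in CROSS13_EXCLUDED]
        out.append(SubGrid(center, tuple(labels)))
    return tuple(out)


def volume_spec(source: Union[ChannelSelection, SubGrid]) -> VolumeGridSpec:
    """Volume layout for a selection or sub-grid.

    motor21 -> 7x3x640 with no padding; cross13 -> 7x3x640 with zeros at the
    eight excluded electrodes' grid slots; 9-grid -> 3x3x640 with no padding;
    5-grid -> 3x3x640 with the four corner slots zeroed.
    """
    if isinstance(source, ChannelSelection):
        if source.name == "motor21":
            return VolumeGridSpec(7, 3, 640, MOTOR21_ORDER)
        if source.name == "cross13":
            layout = tuple(
                lbl if lbl not in CROSS13_EXCLUDED else None
                for lbl in MOTOR21_ORDER
            )
            return VolumeGridSpec(7, 3, 640, layout)
        raise ValueError(
            f"no volume layout for selection {source.name!r} "
            "(expected motor21 or cross13)"
        )
    if isinstance(source, SubGrid):
        cols = [_MOTOR_COLUMNS[i] for i in _SUBGRID_COLUMNS[source.center]]
        full = tuple(lbl for col in cols for lbl in col)
        if source.size == 9:
            return VolumeGridSpec(3, 3, 640, full)
        layout = tuple(
            lbl if lbl in source.ordered_labels else None for lbl in full
        )
        return VolumeGridSpec(3, 3, 640, layout)
    raise TypeError(f"expected ChannelSelection or SubGrid, got {type(source)}")
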