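"""Annotated EEG recordings and fixed-length epoch extraction.

A :class:`Recording` is one subject/run of the 64-channel, 160 Hz motor
imagery protocol: a channels x time matrix in microvolts plus an ordered
annotation track whose labels are T0 (rest), T1 (left-fist motor imagery)
and T2 (right-fist motor imagery).  Epoching cuts the first 4 s
(640 samples) after each annotation onset; annotations with fewer than 640
samples remaining before end-of-file are skipped, never zero-padded.

No filtering, re-referencing or artifact rejection is applied anywhere —
the representations downstream consume the raw signal as recorded.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np

from .montage import EEGMMIDB_CHANNELS, normalize_label

__all__ = [
    "LABELS",
    "SAMPLING_RATE",
    "EPOCH_SAMPLES",
    "Annotation",
    "Recording",
    "Epoch",
    "MontageMismatchError",
    "read_recording",
    "extract_epochs",
    "EpochExtraction",
    "corpus_class_counts",
    "save_epochs",
    "load_epochs",
    "EXCLUDED_SUBJECTS",
]

LABELS: Tuple[str, str, str] = ("T0", "T1", "T2")
SAMPLING_RATE = 160.0
EPOCH_SECONDS = 4.0
EPOCH_SAMPLES = 640  # 4 s x 160 Hz

#: Subjects excluded from the real corpus because of incomplete annotations.
EXCLUDED_SUBJECTS: Tuple[int, ...] = (88, 92, 100, 104)


class MontageMismatchError(ValueError):
    """A file does not match the expected 64-channel / 160 Hz protocol."""


@dataclass(frozen=True)
class Annotation:
    onset: float      # seconds from recording start
    duration: float   # seconds
    label: str        # T0 | T1 | T2

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError(f"annotation onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(
                f"annotation duration must be > 0, got {self.duration}")
        if self.label not in LABELS:
            raise ValueError(
                f"annotation label must be one of {LABELS}, got {self.label!r}")


@dataclass
class Recording:
    """One subject/run: multichannel signal plus its annotation track."""

    subject_id: str
    run_id: str
    fs: float
    channel_names: Tuple[str, ...]
    samples: np.ndarray            # [n_channels x n_timepoints], microvolts
    annotations: Tuple[Annotation, ...]

    def __post_init__(self):
        if self.fs != SAMPLING_RATE:
            raise MontageMismatchError(
                f"sampling rate: expected {SAMPLING_RATE} Hz, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[0] != 64:
            raise MontageMismatchError(
                f"channel count: expected 64, got {self.samples.shape[0]}")
        if len(self.channel_names) != 64:
            raise MontageMismatchError(
                f"channel names: expected 64, got {len(self.channel_names)}")
        if len(set(self.channel_names)) != 64:
            raise MontageMismatchError("channel names are not unique")
        self.annotations = tuple(
            sorted(self.annotations, key=lambda a: a.onset))
        dur = self.samples.shape[1] / self.fs
        for a in self.annotations:
            if a.onset + a.duration > dur + 1e-9:
                raise ValueError(
                    f"annotation [{a.onset}, {a.onset + a.duration}] s exceeds "
                    f"recording duration {dur} s")

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_timepoints / self.fs

    def channel_index(self, label: str) -> int:
        return self.channel_names.index(normalize_label(label))


@dataclass(frozen=True)
class Epoch:
    """A labeled 4 s, 640-sample segment of all 64 channels."""

    subject_id: str
    run_id: str
    label: str
    data: np.ndarray               # [64 x 640], microvolts
    channel_names: Tuple[str, ...]

    def __post_init__(self):
        if self.data.shape != (64, EPOCH_SAMPLES):
            raise ValueError(
                f"epoch data must be 64x{EPOCH_SAMPLES}, got {self.data.shape}")
        if self.label not in LABELS:
            raise ValueError(f"bad epoch label {self.label!r}")

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_names.index(normalize_label(label))]


def read_recording(path) -> Recording:
    """Read an annotated EDF+ recording.

    Channel label aliases are normalized (trailing dots stripped, case
    folded) to canonical 10-10 labels.  Raises
    :class:`MontageMismatchError` when the sampling rate is not 160 Hz or
    the montage does not have 64 channels, and ``OSError`` for unreadable
    files.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if fs != SAMPLING_RATE:
        raise MontageMismatchError(
            f"sampling rate: expected {SAMPLING_RATE} Hz, got {fs} in {path}")
    if len(raw.ch_names) != 64:
        raise MontageMismatchError(
            f"channel count: expected 64, got {len(raw.ch_names)} in {path}")
    names = tuple(normalize_label(n) for n in raw.ch_names)
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    anns = tuple(
        Annotation(float(on), float(du), str(desc))
        for on, du, desc in zip(raw.annotations.onset,
                                raw.annotations.duration,
                                raw.annotations.description)
        if str(desc) in LABELS
    )
    stem = os.path.splitext(os.path.basename(path))[0]
    subject_id, run_id = _ids_from_stem(stem)
    return Recording(subject_id=subject_id, run_id=run_id, fs=fs,
                     channel_names=names,
                     samples=np.ascontiguousarray(data_uv),
                     annotations=anns)


def _ids_from_stem(stem: str) -> Tuple[str, str]:
    # PhysioNet naming: S001R04 -> subject S001, run R04
    if len(stem) >= 7 and stem[0] == "S" and "R" in stem[1:]:
        r = stem.index("R", 1)
        return stem[:r], stem[r:]
    return stem, ""


class EpochExtraction(NamedTuple):
    epochs: List[Epoch]
    n_skipped: int


def extract_epochs(rec: Recording, epoch_seconds: float = EPOCH_SECONDS
                   ) -> EpochExtraction:
    """Cut one epoch per annotation, in annotation order.

    Each epoch takes the first ``epoch_seconds * fs`` samples after the
    annotation onset (onset converted with ``round(onset * fs)``).
    Annotations with fewer samples remaining before end-of-file are skipped
    and counted in the returned tally.
    """
    n_samp = int(round(epoch_seconds * rec.fs))
    epochs: List[Epoch] = []
    skipped = 0
    for ann in rec.annotations:
        start = int(round(ann.onset * rec.fs))
        if start + n_samp > rec.n_timepoints:
            skipped += 1
            continue
        epochs.append(Epoch(
            subject_id=rec.subject_id, run_id=rec.run_id, label=ann.label,
            data=np.array(rec.samples[:, start:start + n_samp]),
            channel_names=rec.channel_names,
        ))
    return EpochExtraction(epochs, skipped)


def corpus_class_counts(epochs: Sequence[Epoch]) -> Dict[str, int]:
    """Per-class epoch tally; always reports all three labels."""
    counts = {label: 0 for label in LABELS}
    for ep in epochs:
        counts[ep.label] += 1
    return counts


def save_epochs(path, epochs: Sequence[Epoch]) -> None:
    """Serialize epochs to an NPZ container.

    Layout: ``data`` float64 [n x 64 x 640] microvolts, ``labels`` /
    ``subjects`` / ``runs`` string arrays of length n, ``channels`` the
    shared 64-label order.
    """
    if not epochs:
        raise ValueError("no epochs to save")
    channels = epochs[0].channel_names
    np.savez_compressed(
        path,
        data=np.stack([e.data for e in epochs]),
        labels=np.array([e.label for e in epochs]),
        subjects=np.array([e.subject_id for e in epochs]),
        runs=np.array([e.run_id for e in epochs]),
        channels=np.array(channels),
    )


def load_epochs(path) -> List[Epoch]:
    with np.load(path, allow_pickle=False) as z:
        channels = tuple(str(c) for c in z["channels"])
        return [
            Epoch(subject_id=str(s), run_id=str(r), label=str(l),
                  data=d, channel_names=channels)
            for s, r, l, d in zip(z["subjects"], z["runs"],
                                  z["labels"], z["data"])
        ]
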