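"""Synthetic 64-channel motor-imagery EEG corpora.

The generator emulates the structure of the PhysioNet motor imagery task-2
runs: 64 channels at 160 Hz, ~120 s per run, 30 annotated ~4 s intervals of
which half are rest (T0) and the rest alternate between left-fist (T1) and
right-fist (T2) imagery.  The class signal is a physiologically motivated
event-related desynchronization (ERD): two mu-band oscillatory sources over
the left (C3) and right (C4) sensorimotor cortex whose amplitude drops by a
configurable attenuation factor contralaterally to the imagined hand —
during T1 the source near C4 is attenuated, during T2 the source near C3,
during T0 both run at full amplitude.  Background activity is 1/f noise.

Two deliberate stylizations (see docs/methods.md): the hemispheric sources
sit at slightly different peak frequencies (``mu_freq`` -/+
``hemisphere_freq_offset``, both inside the 8-12 Hz mu band) and the
per-channel source weights are normalized to unit sum, so that the class is
decodable from any single channel — which the single-channel (1D) pipeline
requires.  Real scalp EEG offers neither guarantee.

All draws flow from one seeded generator per (seed, subject, run), so the
corpus is reproducible file by file.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .montage import EEGMMIDB_CHANNELS, electrode_position
from .recording import Annotation, Recording, SAMPLING_RATE

__all__ = ["SyntheticSpec", "generate_recording", "generate_corpus",
           "iter_corpus", "write_corpus"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the emulated study design and its class signal.

    Defaults are the small CI profile (8 subjects x 1 run); the full
    emulated study design (105 x 3 x 30) is :meth:`study_design`.
    """

    n_subjects: int = 8
    runs_per_subject: int = 1
    intervals_per_run: int = 30
    rest_intervals_per_run: int = 15
    interval_seconds: float = 4.0
    fs: float = SAMPLING_RATE
    mu_freq: float = 10.0                 # Hz, centre of the mu band
    hemisphere_freq_offset: float = 0.5   # Hz, left source at -, right at +
    mu_base_amplitude: float = 12.0       # microvolts, oscillation amplitude
    erd_attenuation: float = 0.4          # contralateral amplitude factor
    spatial_sigma: float = 3.0            # electrode spacings, source falloff
    noise_exponent: float = 1.0           # 1/f^exponent background slope
    noise_amplitude: float = 6.0          # microvolts RMS of the background
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.erd_attenuation < 1):
            raise ValueError("erd_attenuation must be in (0, 1)")
        if self.rest_intervals_per_run > self.intervals_per_run:
            raise ValueError("rest_intervals_per_run exceeds intervals_per_run")
        if self.interval_seconds < 4:
            raise ValueError("interval_seconds must be >= 4 (epoch length)")
        if self.fs != SAMPLING_RATE:
            raise ValueError(f"fs must be {SAMPLING_RATE}")

    @classmethod
    def study_design(cls, seed: int = 0) -> "SyntheticSpec":
        """The emulated full corpus: 105 subjects x 3 runs x 30 intervals."""
        return cls(n_subjects=105, runs_per_subject=3, seed=seed)

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * self.runs_per_subject

    def to_dict(self) -> dict:
        return asdict(self)


def _source_weights(sigma: float) -> Tuple[np.ndarray, np.ndarray]:
    """Unit-sum (left, right) mu-source weights per channel."""
    pos = np.array([electrode_position(c) for c in EEGMMIDB_CHANNELS])
    p3 = np.array(electrode_position("C3"))
    p4 = np.array(electrode_position("C4"))
    wl = np.exp(-np.sum((pos - p3) ** 2, axis=1) / (2 * sigma ** 2))
    wr = np.exp(-np.sum((pos - p4) ** 2, axis=1) / (2 * sigma ** 2))
    total = wl + wr
    return wl / total, wr / total


def _interval_labels(spec: SyntheticSpec, rng: np.random.Generator
                     ) -> List[str]:
    """Alternate rest/task until one tally runs out, then fill the other."""
    labels = []
    rest_left = spec.rest_intervals_per_run
    task_left = spec.intervals_per_run - spec.rest_intervals_per_run
    for i in range(spec.intervals_per_run):
        take_rest = (i % 2 == 0 and rest_left > 0) or task_left == 0
        if take_rest:
            labels.append("T0")
            rest_left -= 1
        else:
            labels.append("T1" if rng.random() < 0.5 else "T2")
            task_left -= 1
    return labels


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, rms: float, fs: float) -> np.ndarray:
    """1/f^exponent noise by frequency-domain shaping of white noise."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def generate_recording(spec: SyntheticSpec, subject: int, run: int
                       ) -> Recording:
    """One synthetic subject/run, fully determined by (seed, subject, run).

    ``subject`` is 1-based; ``run`` is the 1-based task-run index (mapped to
    PhysioNet-style run numbers 4, 8, 12, ...).
    """
    rng = np.random.default_rng([abs(int(spec.seed)), int(subject), int(run)])
    n_samples = int(round(spec.intervals_per_run * spec.interval_seconds
                          * spec.fs))
    labels = _interval_labels(spec, rng)
    data = _pink_noise(rng, 64, n_samples, spec.noise_exponent,
                       spec.noise_amplitude, spec.fs)

    wl, wr = _source_weights(spec.spatial_sigma)
    f_left = spec.mu_freq - spec.hemisphere_freq_offset
    f_right = spec.mu_freq + spec.hemisphere_freq_offset
    e = spec.erd_attenuation
    # contralateral attenuation: T1 (left fist) quiets the right-hemisphere
    # source (C4 neighbourhood), T2 the left-hemisphere source
    attenuation = {"T0": (1.0, 1.0), "T1": (1.0, e), "T2": (e, 1.0)}

    annotations = []
    for i, label in enumerate(labels):
        onset = i * spec.interval_seconds
        start = int(round(onset * spec.fs))
        stop = min(int(round((onset + spec.interval_seconds) * spec.fs)),
                   n_samples)
        t = np.arange(start, stop) / spec.fs
        phase_l, phase_r = rng.uniform(0, 2 * np.pi, size=2)
        att_l, att_r = attenuation[label]
        osc_l = att_l * np.sin(2 * np.pi * f_left * t + phase_l)
        osc_r = att_r * np.sin(2 * np.pi * f_right * t + phase_r)
        data[:, start:stop] += spec.mu_base_amplitude * (
            wl[:, None] * osc_l[None, :] + wr[:, None] * osc_r[None, :])
        annotations.append(
            Annotation(onset, spec.interval_seconds, label))

    return Recording(
        subject_id=f"S{subject:03d}", run_id=f"R{4 * run:02d}",
        fs=spec.fs, channel_names=EEGMMIDB_CHANNELS,
        samples=data, annotations=tuple(annotations))


def iter_corpus(spec: SyntheticSpec) -> Iterator[Recording]:
    """Lazily yield the full corpus, one recording at a time."""
    for subject in range(1, spec.n_subjects + 1):
        for run in range(1, spec.runs_per_subject + 1):
            yield generate_recording(spec, subject, run)


def generate_corpus(spec: SyntheticSpec,
                    out_dir: Optional[str] = None) -> List[Recording]:
    """Materialize the corpus; optionally also write EDF+ files.

    Files are laid out PhysioNet-style: ``<out_dir>/S001/S001R04.edf``.
    """
    recordings = list(iter_corpus(spec))
    if out_dir is not None:
        write_corpus(spec, out_dir, recordings)
    return recordings


def write_corpus(spec: SyntheticSpec, out_dir: str,
                 recordings: Optional[Sequence[Recording]] = None) -> List[str]:
    from .edfplus import write_edf

    paths = []
    for rec in (recordings if recordings is not None else iter_corpus(spec)):
        subject_dir = os.path.join(out_dir, rec.subject_id)
        os.makedirs(subject_dir, exist_ok=True)
        path = os.path.join(subject_dir, f"{rec.subject_id}{rec.run_id}.edf")
        write_edf(path, rec)
        paths.append(path)
    return paths
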