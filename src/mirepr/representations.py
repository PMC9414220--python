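"""The catalogue of motor-imagery data representations.

Every representation starts from 4 s / 640-sample epochs of the 64-channel
recording and produces one of:

* ``spec-single``          — 32x32 RGB spectrogram per channel (64/epoch);
* ``spec-stack-{64,21,13}``— per-channel spectrograms stacked vertically in
  selection order, one image per epoch;
* ``spec-stack-{9,5}``     — the same over each C3/Cz/C4 sub-grid (3/epoch);
* ``raw2d-{64,21,13}``     — raw channels x 640 matrix in selection order;
* ``raw2d-{9,5}``          — raw sub-grid matrices (3/epoch);
* ``vol-{21,13,9,5}``      — depth x channels x 640 volume tensors laid out
  like the scalp grid, zero-padded where the layout has gaps;
* ``raw1d``                — one length-640 vector per channel (64/epoch).

Raw representations carry the signal untouched — no filtering, scaling or
detrending.  Each build produces a :class:`DatasetManifest` whose per-class
counts must equal the emitted sample tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np

from . import montage
from .montage import ChannelSelection, SubGrid, VolumeGridSpec
from .recording import Epoch, LABELS, Recording, extract_epochs
from .spectral import SpectrogramParams, render_power_image, stft_power

__all__ = [
    "REPRESENTATION_IDS",
    "SpectrogramImage",
    "EpochMatrix2D",
    "VolumeTensor",
    "Vector1D",
    "DatasetManifest",
    "single_channel_image",
    "stacked_image",
    "epoch_matrix",
    "to_volume",
    "volume_to_matrix",
    "split_subgrids",
    "to_vectors",
    "samples_per_epoch",
    "sample_shape",
    "build_dataset",
    "build_manifest",
]


# ---------------------------------------------------------------------------
# sample types

@dataclass(frozen=True)
class SpectrogramImage:
    pixels: np.ndarray          # [H x W x 3] uint8
    label: str
    source: Tuple               # (subject, run, epoch index, channel/selection)

    def __post_init__(self):
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 3 \
                or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 uint8 array")


@dataclass(frozen=True)
class EpochMatrix2D:
    values: np.ndarray          # [n_channels x 640] microvolts
    channel_order: Tuple[str, ...]
    label: str
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self):
        if self.values.shape != (len(self.channel_order), 640):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.channel_order)} channels x 640")


@dataclass(frozen=True)
class VolumeTensor:
    values: np.ndarray          # [D x C x 640]
    zero_mask: np.ndarray       # [D x C] bool, True where zero-padded
    grid: VolumeGridSpec
    label: str
    subject_id: str = ""
    run_id: str = ""


@dataclass(frozen=True)
class Vector1D:
    values: np.ndarray          # [640] microvolts
    channel: str
    label: str
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self):
        if self.values.shape != (640,):
            raise ValueError(f"expected length-640 vector, got {self.values.shape}")


@dataclass
class DatasetManifest:
    representation_id: str
    sample_shape: Tuple[int, ...]
    counts: Dict[str, int]
    provenance: Dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "representation_id": self.representation_id,
            "sample_shape": list(self.sample_shape),
            "counts": dict(self.counts),
            "total": self.total,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# per-epoch constructors

def single_channel_image(ep: Epoch, channel: str,
                         params: Optional[SpectrogramParams] = None
                         ) -> SpectrogramImage:
    """32x32 RGB spectrogram image of one channel of one epoch."""
    params = params or SpectrogramParams()
    x = ep.channel(channel)     # raises KeyError/ValueError for unknown labels
    _, _, power = stft_power(x, params)
    rgb = render_power_image(power, params, size=params.image_size)
    return SpectrogramImage(rgb, ep.label,
                            (ep.subject_id, ep.run_id, channel))


def stacked_image(ep: Epoch, sel: Union[ChannelSelection, SubGrid],
                  params: Optional[SpectrogramParams] = None,
                  size: Optional[Tuple[int, int]] = None) -> SpectrogramImage:
    """Vertically stacked per-channel spectrograms, one image per epoch.

    Channel blocks run top to bottom in selection order, frequency
    increasing downward within each block.  The native pre-render extent is
    (81 * n_channels) x 31; ``size`` optionally resizes the rendered image.
    """
    params = params or SpectrogramParams()
    blocks = [stft_power(ep.channel(c), params)[2]
              for c in sel.ordered_labels]
    stacked = np.concatenate(blocks, axis=0)
    rgb = render_power_image(stacked, params, size=size)
    name = sel.name if isinstance(sel, ChannelSelection) else f"grid-{sel.center}"
    return SpectrogramImage(rgb, ep.label, (ep.subject_id, ep.run_id, name))


def epoch_matrix(ep: Epoch, sel: Union[ChannelSelection, SubGrid]
                 ) -> EpochMatrix2D:
    """Rows of the epoch reordered to the selection order, values untouched."""
    idx = [ep.channel_names.index(c) for c in sel.ordered_labels]
    return EpochMatrix2D(np.array(ep.data[idx]), tuple(sel.ordered_labels),
                         ep.label, ep.subject_id, ep.run_id)


def to_volume(m: EpochMatrix2D, grid: VolumeGridSpec) -> VolumeTensor:
    """Reshape a channels x 640 matrix into its depth x 3 x 640 volume.

    Layer k holds rows 3k..3k+2 of the zero-augmented matrix; flattening
    the unmasked slots in layer-major order reproduces the matrix exactly.
    """
    if len(m.channel_order) != len(grid.real_labels):
        raise ValueError(
            f"matrix has {len(m.channel_order)} rows but grid expects "
            f"{len(grid.real_labels)} real channels")
    if tuple(m.channel_order) != grid.real_labels:
        raise ValueError("matrix channel order does not match grid layout")
    d, c, ns = grid.depth, grid.channels_per_layer, grid.samples_per_channel
    values = np.zeros((d * c, ns), dtype=m.values.dtype)
    mask = np.ones(d * c, dtype=bool)
    row = 0
    for slot, lbl in enumerate(grid.layout_labels):
        if lbl is not None:
            values[slot] = m.values[row]
            mask[slot] = False
            row += 1
    return VolumeTensor(values.reshape(d, c, ns), mask.reshape(d, c),
                        grid, m.label, m.subject_id, m.run_id)


def volume_to_matrix(v: VolumeTensor) -> EpochMatrix2D:
    """Inverse of :func:`to_volume` on the unmasked slots."""
    flat = v.values.reshape(-1, v.grid.samples_per_channel)
    keep = ~v.zero_mask.reshape(-1)
    return EpochMatrix2D(np.array(flat[keep]), v.grid.real_labels,
                         v.label, v.subject_id, v.run_id)


def split_subgrids(ep: Epoch, size: int) -> List[EpochMatrix2D]:
    """Three sub-grid matrices (C3, Cz, C4 centres) from one epoch."""
    return [epoch_matrix(ep, sg) for sg in montage.subgrids(size)]


def to_vectors(ep: Epoch) -> List[Vector1D]:
    """One length-640 vector per channel, all carrying the epoch label."""
    return [Vector1D(np.array(ep.data[i]), c, ep.label,
                     ep.subject_id, ep.run_id)
            for i, c in enumerate(ep.channel_names)]


# ---------------------------------------------------------------------------
# dataset builder

REPRESENTATION_IDS: Tuple[str, ...] = (
    "spec-single",
    "spec-stack-64", "spec-stack-21", "spec-stack-13",
    "spec-stack-9", "spec-stack-5",
    "raw2d-64", "raw2d-21", "raw2d-13", "raw2d-9", "raw2d-5",
    "vol-21", "vol-13", "vol-9", "vol-5",
    "raw1d",
)

_SELECTION_FOR = {"64": "full64", "21": "motor21", "13": "cross13"}


def _check_id(representation_id: str) -> None:
    if representation_id not in REPRESENTATION_IDS:
        raise ValueError(
            f"unknown representation id {representation_id!r}; "
            f"expected one of {REPRESENTATION_IDS}")


def samples_per_epoch(representation_id: str) -> int:
    """How many samples one 64-channel epoch contributes."""
    _check_id(representation_id)
    if representation_id in ("spec-single", "raw1d"):
        return 64
    if representation_id.endswith(("-9", "-5")):
        return 3
    return 1


def sample_shape(representation_id: str,
                 params: Optional[SpectrogramParams] = None
                 ) -> Tuple[int, ...]:
    _check_id(representation_id)
    params = params or SpectrogramParams()
    n_freq = params.nperseg // 2 + 1
    n_frames = (640 - params.nperseg) // params.step + 1
    if representation_id == "spec-single":
        w, h = params.image_size
        return (h, w, 3)
    if representation_id.startswith("spec-stack-"):
        n_ch = int(representation_id.rsplit("-", 1)[1])
        return (n_freq * n_ch, n_frames, 3)
    if representation_id.startswith("raw2d-"):
        return (int(representation_id.rsplit("-", 1)[1]), 640)
    if representation_id.startswith("vol-"):
        n = representation_id.rsplit("-", 1)[1]
        return (7, 3, 640) if n in ("21", "13") else (3, 3, 640)
    return (640,)   # raw1d


def _epoch_samples(ep: Epoch, representation_id: str,
                   params: SpectrogramParams) -> Iterable:
    kind, _, suffix = representation_id.partition("-")
    if representation_id == "spec-single":
        return [single_channel_image(ep, c, params) for c in ep.channel_names]
    if representation_id == "raw1d":
        return to_vectors(ep)
    if representation_id.startswith("spec-stack-"):
        n = representation_id.rsplit("-", 1)[1]
        if n in _SELECTION_FOR:
            return [stacked_image(ep, montage.selection(_SELECTION_FOR[n]),
                                  params)]
        return [stacked_image(ep, sg, params)
                for sg in montage.subgrids(int(n))]
    if kind == "raw2d":
        if suffix in _SELECTION_FOR:
            return [epoch_matrix(ep, montage.selection(_SELECTION_FOR[suffix]))]
        return split_subgrids(ep, int(suffix))
    # vol-*
    if suffix in ("21", "13"):
        sel = montage.selection(_SELECTION_FOR[suffix])
        return [to_volume(epoch_matrix(ep, sel), montage.volume_spec(sel))]
    return [to_volume(epoch_matrix(ep, sg), montage.volume_spec(sg))
            for sg in montage.subgrids(int(suffix))]


def build_dataset(corpus: Iterable[Recording], representation_id: str,
                  params: Optional[SpectrogramParams] = None
                  ) -> Tuple[List, DatasetManifest]:
    """Materialize every sample of a representation over a corpus.

    Iteration order is deterministic: corpus order, then annotation order,
    then sub-sample (channel / sub-grid) order.  The manifest's per-class
    counts equal the emitted tallies by construction and are verified.
    """
    _check_id(representation_id)
    params = params or SpectrogramParams()
    samples: List = []
    counts = {label: 0 for label in LABELS}
    n_recordings = 0
    n_skipped = 0
    for rec in corpus:
        n_recordings += 1
        epochs, skipped = extract_epochs(rec)
        n_skipped += skipped
        for ep in epochs:
            new = list(_epoch_samples(ep, representation_id, params))
            samples.extend(new)
            counts[ep.label] += len(new)
    manifest = DatasetManifest(
        representation_id, sample_shape(representation_id, params), counts,
        provenance={"n_recordings": n_recordings,
                    "skipped_annotations": n_skipped,
                    "spectrogram_digest": params.digest()})
    assert manifest.total == len(samples)
    return samples, manifest


def export_samples(samples, manifest: DatasetManifest, out_dir) -> List[str]:
    """Write samples under ``{repr}/{subject}/{run}/{epoch}[_{sub}]``.

    Images become PNG files with a sidecar ``.json`` carrying the label and
    provenance; raw matrices, volumes and vectors become NPZ containers
    with the label stored alongside the payload.  The manifest is written
    as ``manifest.json`` at the representation root.
    """
    import json as _json
    import os

    from PIL import Image

    root = os.path.join(str(out_dir), manifest.representation_id)
    counters: Dict[Tuple[str, str], int] = {}
    paths = []
    for s in samples:
        if isinstance(s, SpectrogramImage):
            subject, run, sub = s.source
        else:
            subject, run = s.subject_id, s.run_id
            sub = getattr(s, "channel", None)
            if sub is None and isinstance(s, EpochMatrix2D) \
                    and len(s.channel_order) in (9, 5):
                sub = s.channel_order[len(s.channel_order) // 2]
            if sub is None and isinstance(s, VolumeTensor) \
                    and s.grid.depth == 3:
                sub = s.grid.layout_labels[4]
        per_epoch = samples_per_epoch(manifest.representation_id)
        key = (subject, run)
        serial = counters.get(key, 0)
        counters[key] = serial + 1
        epoch_idx, sub_idx = divmod(serial, per_epoch)
        stem = f"{epoch_idx:04d}" + (f"_{sub}" if per_epoch > 1 else "")
        d = os.path.join(root, subject, run)
        os.makedirs(d, exist_ok=True)
        meta = {"label": s.label, "subject": subject, "run": run,
                "epoch": epoch_idx, "sub": sub}
        if isinstance(s, SpectrogramImage):
            path = os.path.join(d, stem + ".png")
            Image.fromarray(s.pixels, mode="RGB").save(path)
            with open(os.path.join(d, stem + ".json"), "w") as f:
                _json.dump(meta, f)
        else:
            path = os.path.join(d, stem + ".npz")
            payload = s.values
            np.savez_compressed(path, values=payload,
                                meta=np.array(_json.dumps(meta)))
        paths.append(path)
    with open(os.path.join(root, "manifest.json"), "w") as f:
        _json.dump(manifest.to_dict(), f, indent=2)
    return paths


def build_manifest(corpus: Iterable[Recording], representation_id: str,
                   params: Optional[SpectrogramParams] = None
                   ) -> DatasetManifest:
    """Stream a corpus and tally the manifest without materializing samples.

    Counts are exact because every representation emits a fixed number of
    samples per qualifying epoch; recordings can be generated lazily, so
    the full 105 x 3 x 30 study design fits in constant memory.
    """
    _check_id(representation_id)
    params = params or SpectrogramParams()
    mult = samples_per_epoch(representation_id)
    counts = {label: 0 for label in LABELS}
    n_recordings = 0
    n_skipped = 0
    for rec in corpus:
        n_recordings += 1
        epochs, skipped = extract_epochs(rec)
        n_skipped += skipped
        for ep in epochs:
            counts[ep.label] += mult
    return DatasetManifest(
        representation_id, sample_shape(representation_id, params), counts,
        provenance={"n_recordings": n_recordings,
                    "skipped_annotations": n_skipped,
                    "spectrogram_digest": params.digest()})
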