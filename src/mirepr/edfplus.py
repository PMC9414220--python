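"""Minimal EDF+C writer with an EDF Annotations channel.

Writes continuous 16-bit EDF+ files: one data record per second, each EEG
channel sampled at 160 Hz, plus one annotation signal carrying the
time-stamped annotation lists (TALs) for the T0/T1/T2 event track.  The
reader side of the round-trip goes through MNE, which keeps this writer
honest: everything written here must survive an independent parser.

Samples are quantized to the 16-bit digital range against a per-channel
symmetric physical range, so a write/read round-trip reproduces the signal
up to half a quantization step.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .recording import Recording

__all__ = ["write_edf"]

_ANNOTATION_SAMPLES_PER_RECORD = 60  # 120 bytes of TAL space per record


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_time(seconds: float) -> str:
    # shortest exact-ish decimal representation, EDF+ style ("+4", "+4.1")
    s = f"{seconds:.7f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _phys_str(v: float) -> str:
    # decimal form of the physical range, rounded UP (never below the true
    # peak, so no sample clips) and at most 7 chars to leave room for "-"
    for prec in (6, 5, 4, 3, 2):
        s = f"{v * (1 + 10.0 ** (1 - prec)):.{prec}g}"
        if len(s) <= 7:
            return s
    raise ValueError(f"cannot format physical range {v}")


def write_edf(path, rec: Recording) -> None:
    """Write a :class:`Recording` as a 16-bit EDF+C file.

    The recording length must be a whole number of seconds (the writer uses
    1 s data records and does not pad).
    """
    fs = int(rec.fs)
    n_samples = rec.n_timepoints
    if n_samples % fs != 0:
        raise ValueError(
            f"recording length {n_samples} is not a whole number of "
            f"1 s records at fs={fs}")
    n_records = n_samples // fs
    n_sig = 65  # 64 EEG + EDF Annotations

    data = np.asarray(rec.samples, dtype=np.float64)
    # symmetric per-channel physical range -> digital -32767..32767; the
    # range is rounded to its on-disk decimal form BEFORE quantizing so the
    # reader's scaling matches the writer's exactly
    true_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_str = [_phys_str(v) for v in true_max]
    phys_max = np.array([float(s) for s in phys_str])
    scale = 32767.0 / phys_max
    digital = np.clip(np.rint(data * scale[:, None]), -32767, 32767
                      ).astype("<i2")

    # --- per-record annotation payloads (TALs) ----------------------------
    ann_bytes_per_record = 2 * _ANNOTATION_SAMPLES_PER_RECORD
    tal_records = []
    events = list(rec.annotations)
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")  # record timestamp TAL
        for a in events:
            if r <= a.onset < r + 1:
                tal += (f"+{_fmt_time(a.onset)}\x15{_fmt_time(a.duration)}"
                        f"\x14{a.label}\x14\x00").encode("ascii")
        if len(tal) > ann_bytes_per_record:
            raise ValueError(
                f"annotation TAL for record {r} exceeds "
                f"{ann_bytes_per_record} bytes")
        tal_records.append(tal.ljust(ann_bytes_per_record, b"\x00"))

    # --- header -----------------------------------------------------------
    header_bytes = 256 * (1 + n_sig)
    h = b""
    h += _field("0", 8)                                   # version
    h += _field(f"X X X {rec.subject_id or 'X'}", 80)     # patient id
    h += _field(
        f"Startdate 01-JAN-2000 X X {rec.run_id or 'X'}", 80)  # recording id
    h += _field("01.01.00", 8)                            # start date
    h += _field("00.00.00", 8)                            # start time
    h += _field(header_bytes, 8)
    h += _field("EDF+C", 44)
    h += _field(n_records, 8)
    h += _field(1, 8)                                     # record duration s
    h += _field(n_sig, 4)

    # channel labels carry trailing dots, as in the PhysioNet headers
    labels = [f"{name:.<16}"[:16] for name in rec.channel_names]
    labels.append("EDF Annotations ")
    h += b"".join(lab.encode("ascii") for lab in labels)
    h += b"".join(_field("Synthetic EEG" if i < 64 else "", 80)
                  for i in range(n_sig))                  # transducer
    h += b"".join(_field("uV" if i < 64 else "", 8)
                  for i in range(n_sig))                  # physical dimension
    h += b"".join(_field("-" + phys_str[i] if i < 64 else -1, 8)
                  for i in range(n_sig))                  # physical min
    h += b"".join(_field(phys_str[i] if i < 64 else 1, 8)
                  for i in range(n_sig))                  # physical max
    h += b"".join(_field(-32767 if i < 64 else -32768, 8)
                  for i in range(n_sig))                  # digital min
    h += b"".join(_field(32767, 8) for _ in range(n_sig))  # digital max
    h += b"".join(_field("", 80) for _ in range(n_sig))   # prefiltering
    h += b"".join(_field(fs if i < 64 else _ANNOTATION_SAMPLES_PER_RECORD, 8)
                  for i in range(n_sig))                  # samples per record
    h += b"".join(_field("", 32) for _ in range(n_sig))   # reserved
    assert len(h) == header_bytes, (len(h), header_bytes)

    with open(path, "wb") as f:
        f.write(h)
        for r in range(n_records):
            f.write(digital[:, r * fs:(r + 1) * fs].tobytes(order="C"))
            f.write(tal_records[r])
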