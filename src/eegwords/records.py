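"""Reading and writing multichannel EEG records and seizure annotations.

Records travel as EDF (European Data Format, 16-bit) or as a plain CSV
matrix (one row per channel) with a JSON sidecar for the sampling rate and
channel labels.  Seizure annotations are (start_s, end_s) intervals in
seconds from record start, half-open [start_s, end_s).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class FormatError(ValueError):
    """Raised when a file does not parse in the named format."""


@dataclass(frozen=True, order=True)
class SeizureAnnotation:
    """One seizure interval, seconds from record start, half-open."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if self.start_s < 0:
            raise FormatError(f"annotation start {self.start_s} < 0")
        if self.end_s <= self.start_s:
            raise FormatError(f"annotation end {self.end_s} <= start {self.start_s}")

    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecord:
    """A multichannel scalp EEG recording.

    data is a channels x samples matrix in microvolts; fs the sampling
    rate in Hz.  All channels share the sample count and every annotation
    interval must lie inside [0, samples/fs].
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("record data must be a 2-D channels x samples matrix")
        if self.data.shape[0] == 0:
            raise FormatError("record has zero channels")
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError("channel_labels length does not match channel count")
        self.validate_annotations()

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate_annotations(self) -> None:
        for ann in self.annotations:
            if ann.end_s > self.duration_s + 1e-9:
                raise FormatError(
                    f"annotation [{ann.start_s}, {ann.end_s}) extends beyond "
                    f"record end at {self.duration_s:.3f} s"
                )


# ---------------------------------------------------------------------------
# EDF
#
# EDF stores a 256-byte fixed header, 256 bytes per signal, then the data
# records as contiguous little-endian int16 blocks, one block per channel
# per record.  Physical values map affinely from the digital range; with
# 16-bit encoding the round trip is exact to within one quantization step.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF field {value!r} longer than {width} chars")
    return s.ljust(width).encode("ascii")


def _edf_float(value: float, width: int = 8) -> str:
    """Format a float into an 8-char EDF numeric field, widest precision
    that fits."""
    for fmt in (f"{{:.{p}g}}" for p in range(10, 0, -1)):
        s = fmt.format(value)
        if len(s) <= width:
            return s
    raise FormatError(f"cannot format {value} in {width} chars")


def _write_edf(record: EEGRecord, path: Path) -> None:
    data = record.data
    n_ch, n_samp = data.shape
    fs = record.fs
    # one-second records when the length allows it, else a single record
    if float(fs).is_integer() and n_samp % int(fs) == 0:
        spr, n_rec, rec_dur = int(fs), n_samp // int(fs), 1.0
    else:
        spr, n_rec, rec_dur = n_samp, 1, n_samp / fs

    pmins, pmaxs, scaled = [], [], []
    for ch in range(n_ch):
        x = data[ch]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        # re-parse the ASCII representation so writer and reader agree on
        # the exact affine mapping
        lo = float(_edf_float(lo))
        hi = float(_edf_float(hi))
        if hi <= lo:
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        dig = np.round(
            (x - lo) / (hi - lo) * (_EDF_DIG_MAX - _EDF_DIG_MIN) + _EDF_DIG_MIN
        )
        scaled.append(np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2"))

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(record.subject_id or "X", 80),
            _edf_field("Startdate 01-JAN-2000", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(_edf_float(rec_dur), 8),
            _edf_field(n_ch, 4),
        ]
    )
    labels = [lab[:16] for lab in record.channel_labels]
    sig_header = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field("uV", 8) for _ in labels),
            b"".join(_edf_field(_edf_float(p), 8) for p in pmins),
            b"".join(_edf_field(_edf_float(p), 8) for p in pmaxs),
            b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in labels),
            b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field(spr, 8) for _ in labels),
            b"".join(_edf_field("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path) -> EEGRecord:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne scales uV channels to volts
    with open(path, "rb") as fh:
        subject_id = fh.read(88)[8:].decode("ascii", "replace").strip()
    return EEGRecord(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# CSV (one row per channel) + JSON sidecar holding fs / labels / subject


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _write_csv(record: EEGRecord, path: Path) -> None:
    np.savetxt(path, record.data, delimiter=",", fmt="%.10g")
    meta = {
        "fs": record.fs,
        "channel_labels": record.channel_labels,
        "subject_id": record.subject_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta) + "\n")


def _read_csv(path: Path) -> EEGRecord:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric value") from exc
    if not rows:
        raise FormatError(f"{path}: zero channels")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    return EEGRecord(
        data=np.array(rows, dtype=float),
        fs=float(meta["fs"]),
        channel_labels=list(meta.get("channel_labels") or [f"CH{i+1:02d}" for i in range(len(rows))]),
        subject_id=str(meta.get("subject_id", "")),
    )


def read_record(path, format: str = "edf") -> EEGRecord:
    """Read an EEG record from `path` in the named format ("edf" or "csv")."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "edf":
        return _read_edf(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_record(record: EEGRecord, path, format: str = "edf") -> None:
    """Write a record to `path`; EDF output uses 16-bit sample encoding."""
    record.validate_annotations()
    path = Path(path)
    if format == "edf":
        _write_edf(record, path)
    elif format == "csv":
        _write_csv(record, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Annotations

def merge_intervals(annotations) -> list[SeizureAnnotation]:
    """Sort intervals by start and merge overlapping/touching ones."""
    anns = sorted(annotations, key=lambda a: (a.start_s, a.end_s))
    merged: list[SeizureAnnotation] = []
    for a in anns:
        if merged and a.start_s <= merged[-1].end_s:
            if a.end_s > merged[-1].end_s:
                merged[-1] = SeizureAnnotation(merged[-1].start_s, a.end_s)
        else:
            merged.append(SeizureAnnotation(a.start_s, a.end_s))
    return merged


_SUMMARY_START = re.compile(r"^Seizure(?: \d+)? Start Time:\s*([0-9.]+)\s*sec", re.I)
_SUMMARY_END = re.compile(r"^Seizure(?: \d+)? End Time:\s*([0-9.]+)\s*sec", re.I)


def parse_annotations(text: str, dialect: str = "interval_csv") -> list[SeizureAnnotation]:
    """Parse seizure intervals from an annotation document.

    dialect "interval_csv": one "start_s,end_s" pair per line (optional
    "start*" header line skipped).  dialect "chbmit_summary": the plain-text
    summary format with "Seizure Start Time: N seconds" / "Seizure End
    Time: N seconds" line pairs; unrecognised lines are ignored.  Output is
    sorted and pairwise disjoint (overlaps merged).
    """
    anns: list[SeizureAnnotation] = []
    if dialect == "interval_csv":
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.lower().startswith("start"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"line {ln}: expected 'start,end', got {line!r}")
            try:
                start, end = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {ln}: non-numeric interval") from exc
            anns.append(SeizureAnnotation(start, end))
    elif dialect == "chbmit_summary":
        pending_start: float | None = None
        for line in text.splitlines():
            line = line.strip()
            m = _SUMMARY_START.match(line)
            if m:
                pending_start = float(m.group(1))
                continue
            m = _SUMMARY_END.match(line)
            if m:
                if pending_start is None:
                    raise FormatError("seizure end time without a preceding start time")
                anns.append(SeizureAnnotation(pending_start, float(m.group(1))))
                pending_start = None
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return merge_intervals(anns)


def write_annotations(annotations, path) -> None:
    """Write intervals as a two-column start_s,end_s CSV."""
    lines = ["start_s,end_s"] + [f"{a.start_s:g},{a.end_s:g}" for a in annotations]
    Path(path).write_text("\n".join(lines) + "\n")
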