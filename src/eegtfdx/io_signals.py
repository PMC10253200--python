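"""Reading and writing multichannel EEG recordings and dataset manifests.

Three on-disk formats are supported:

* ``matrix`` — a dependency-free plain-text format: one header line
  ``fs=<Hz> channels=<n>`` followed by one whitespace-delimited row per
  channel.  Subject/label/condition metadata and channel names travel in a
  JSON sidecar next to the file (``<path>.json``).
* ``edf`` / ``bdf`` — the standard 16-bit (EDF) and 24-bit BioSemi (BDF)
  biosignal containers.  Files are written by a minimal encoder in this
  module and read back through :mod:`mne`, so the writer is always checked
  against an independent reader.

Samples are carried as microvolt-scaled arbitrary units; no rescaling is
performed on read beyond undoing the container's integer quantisation.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LABELS = ("MD", "HC", "UNKNOWN")
CONDITIONS = ("R", "A", "V", "UNKNOWN")

__all__ = [
    "MultichannelRecording",
    "DatasetManifest",
    "read_recording",
    "write_recording",
    "load_manifest",
    "save_manifest",
]


@dataclass
class MultichannelRecording:
    """A labelled, condition-tagged EEG sample matrix.

    ``samples`` has shape ``(n_channels, n_samples)``; one row is the x(t)
    that the time-frequency transforms operate on.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""
    label: str = "UNKNOWN"
    condition: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        n_ch, n_s = self.samples.shape
        if n_ch < 1 or n_s < 1:
            raise ValueError("recording needs at least one channel and one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(n_ch)]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "MultichannelRecording":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# matrix text format
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    return path + ".json"


def _write_sidecar(rec: MultichannelRecording, path: str) -> None:
    meta = {
        "subject_id": rec.subject_id,
        "label": rec.label,
        "condition": rec.condition,
        "channel_names": rec.channel_names,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_sidecar(path: str) -> dict:
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            return json.load(fh)
    return {}


def _write_matrix(rec: MultichannelRecording, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"fs={rec.fs:g} channels={rec.n_channels}\n")
        np.savetxt(fh, rec.samples, fmt="%.10g")
    _write_sidecar(rec, path)


def _read_matrix(path: str) -> MultichannelRecording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty file, no 'fs=... channels=...' header")
        fields = dict(
            tok.split("=", 1) for tok in header.split() if "=" in tok
        )
        if "fs" not in fields or "channels" not in fields:
            raise ValueError(
                f"{path}: malformed header {header!r}; expected 'fs=<Hz> channels=<n>'"
            )
        fs = float(fields["fs"])
        n_ch = int(fields["channels"])
        try:
            data = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:  # ragged rows etc.
            raise ValueError(f"{path}: could not parse sample rows ({exc})") from exc
    if data.size == 0:
        raise ValueError(f"{path}: header present but no sample rows")
    if data.shape[0] != n_ch:
        raise ValueError(
            f"{path}: header says channels={n_ch} but found {data.shape[0]} rows"
        )
    meta = _read_sidecar(path)
    return MultichannelRecording(
        samples=data,
        fs=fs,
        channel_names=meta.get("channel_names", []),
        subject_id=meta.get("subject_id", ""),
        label=meta.get("label", "UNKNOWN"),
        condition=meta.get("condition", "UNKNOWN"),
    )


# ---------------------------------------------------------------------------
# EDF / BDF
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_bounds(chan: np.ndarray) -> tuple[float, float]:
    lo, hi = float(chan.min()), float(chan.max())
    if hi <= lo:
        lo, hi = lo - 1.0, hi + 1.0
    # round outward so the 8-char ASCII header fields hold them exactly
    span = hi - lo
    step = 10.0 ** (math.floor(math.log10(span)) - 4)
    lo = math.floor(lo / step) * step
    hi = math.ceil(hi / step) * step
    return lo, hi


def _write_edf_bdf(rec: MultichannelRecording, path: str, kind: str) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"{kind} writer needs an integer sampling rate, got {fs}")
    fs_i = int(round(fs))
    if rec.n_samples % fs_i != 0:
        raise ValueError(
            f"{kind} writer uses 1 s data records; sample count {rec.n_samples} "
            f"is not a multiple of fs={fs_i}"
        )
    n_records = rec.n_samples // fs_i
    n_ch = rec.n_channels
    if kind == "edf":
        dig_min, dig_max = -32768, 32767
        magic = b"0       "
        reserved = b" " * 44
        bytes_per_sample = 2
    else:
        dig_min, dig_max = -8388608, 8388607
        magic = b"\xffBIOSEMI"
        reserved = b"24BIT".ljust(44)
        bytes_per_sample = 3

    header_bytes = 256 * (1 + n_ch)
    head = bytearray()
    head += magic
    head += _ascii(rec.subject_id or "X", 80)
    head += _ascii(f"Startdate 01-JAN-2000 {rec.label} {rec.condition}", 80)
    head += b"01.01.00"
    head += b"00.00.00"
    head += _ascii(header_bytes, 8)
    head += reserved
    head += _ascii(n_records, 8)
    head += _ascii(1, 8)  # record duration, seconds
    head += _ascii(n_ch, 4)

    bounds = [_phys_bounds(rec.samples[c]) for c in range(n_ch)]
    for name in rec.channel_names:
        head += _ascii(name, 16)
    head += b" " * 80 * n_ch  # transducer
    for _ in range(n_ch):
        head += _ascii("uV", 8)
    for lo, _hi in bounds:
        head += _ascii(f"{lo:.8g}"[:8], 8)
    for _lo, hi in bounds:
        head += _ascii(f"{hi:.8g}"[:8], 8)
    for _ in range(n_ch):
        head += _ascii(dig_min, 8)
    for _ in range(n_ch):
        head += _ascii(dig_max, 8)
    head += b" " * 80 * n_ch  # prefiltering
    for _ in range(n_ch):
        head += _ascii(fs_i, 8)
    head += b" " * 32 * n_ch
    assert len(head) == header_bytes

    # quantise each channel onto its digital range
    digital = np.empty((n_ch, rec.n_samples), dtype=np.int64)
    for c in range(n_ch):
        lo, hi = bounds[c]
        gain = (dig_max - dig_min) / (hi - lo)
        digital[c] = np.clip(
            np.round((rec.samples[c] - lo) * gain) + dig_min, dig_min, dig_max
        )

    with open(path, "wb") as fh:
        fh.write(bytes(head))
        for r in range(n_records):
            block = digital[:, r * fs_i : (r + 1) * fs_i]
            if bytes_per_sample == 2:
                fh.write(block.astype("<i2").tobytes())
            else:
                flat = block.reshape(-1).astype(np.int64)
                raw = np.empty((flat.size, 3), dtype=np.uint8)
                u = flat & 0xFFFFFF
                raw[:, 0] = u & 0xFF
                raw[:, 1] = (u >> 8) & 0xFF
                raw[:, 2] = (u >> 16) & 0xFF
                fh.write(raw.tobytes())
    _write_sidecar(rec, path)


def _read_edf_bdf(path: str, kind: str) -> MultichannelRecording:
    import mne

    reader = mne.io.read_raw_edf if kind == "edf" else mne.io.read_raw_bdf
    try:
        raw = reader(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse as {kind.upper()} ({exc})") from exc
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned channels
    meta = _read_sidecar(path)
    return MultichannelRecording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=meta.get("subject_id", ""),
        label=meta.get("label", "UNKNOWN"),
        condition=meta.get("condition", "UNKNOWN"),
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "bdf", "matrix")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("edf", "bdf"):
        return ext
    return "matrix"


def read_recording(path: str, format: str | None = None) -> MultichannelRecording:
    """Read a recording; ``format`` defaults to the file extension."""
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "matrix":
        return _read_matrix(path)
    return _read_edf_bdf(path, fmt)


def write_recording(rec: MultichannelRecording, path: str, format: str | None = None) -> None:
    """Write a recording so that :func:`read_recording` accepts it back."""
    if not np.isfinite(rec.samples).all():
        raise ValueError("refusing to write recording containing NaN/inf samples")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "matrix":
        _write_matrix(rec, path)
    else:
        _write_edf_bdf(rec, path, fmt)


@dataclass
class DatasetManifest:
    """A tabular index of dataset files with per-row metadata.

    ``entries`` is a DataFrame with at least columns
    ``path, subject_id, label, condition`` (image manifests add ``channel``
    and ``method``); relative paths resolve against ``root``.
    """

    entries: pd.DataFrame
    root: str = "."

    _KEY_COLS = ("subject_id", "condition", "channel", "method")

    def __post_init__(self) -> None:
        required = ["path", "subject_id", "label", "condition"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        key_cols = [c for c in self._KEY_COLS if c in self.entries.columns]
        dup = self.entries.duplicated(subset=key_cols)
        if dup.any():
            rows = self.entries.loc[dup, key_cols].to_dict("records")
            raise ValueError(f"duplicate manifest entries for {rows}")

    def __len__(self) -> int:
        return len(self.entries)

    def resolved_paths(self) -> list[str]:
        return [
            p if os.path.isabs(p) else os.path.join(self.root, p)
            for p in self.entries["path"]
        ]


def save_manifest(manifest: DatasetManifest, path: str) -> None:
    manifest.entries.to_csv(path, index=False)


def load_manifest(path: str, check_files: bool = True) -> DatasetManifest:
    entries = pd.read_csv(path, dtype=str)
    manifest = DatasetManifest(entries=entries, root=os.path.dirname(path) or ".")
    if check_files:
        missing = [p for p in manifest.resolved_paths() if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(
                f"manifest {path} references missing files: {missing}"
            )
    return manifest
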