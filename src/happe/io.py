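"""Reading and writing recordings.

Two formats are supported:

* ``native`` -- a raw little-endian float64 channel-major matrix (``.dat``)
  with a JSON sidecar (same stem, ``.json``) holding the sampling rate,
  channel labels, events, input kind and processing history.  Bit-exact,
  dependency-free intermediates.
* ``edf`` -- European Data Format (continuous, 16-bit).  Reading goes
  through :func:`mne.io.read_raw_edf`; writing uses the minimal EDF writer
  below (no EDF-writing library is bundled with the scientific stack this
  package targets).  EDF is quantized to the configured physical range, so
  round-trips agree only to one least-significant bit.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Recording

__all__ = ["read_recording", "write_recording", "EDF_PHYS_RANGE_UV"]

#: Default symmetric physical range of EDF output, in microvolts.
EDF_PHYS_RANGE_UV = 3276.7


class RecordingIOError(IOError):
    """Unreadable, unwritable or malformed recording file."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path,
                    format: str = "native",
                    phys_range_uv: float = EDF_PHYS_RANGE_UV) -> None:
    """Write ``rec`` to ``path`` in the named format."""
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        if format == "native":
            _write_native(rec, path)
        elif format == "edf":
            _write_edf(rec, path, phys_range_uv)
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise RecordingIOError(f"cannot write {path}: {exc}") from exc


def read_recording(path: str | Path, format: str = "native") -> Recording:
    """Read a recording written by :func:`write_recording` (or any EDF)."""
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such file: {path}")
    if format == "native":
        return _read_native(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------- native

def _write_native(rec: Recording, path: Path) -> None:
    data = np.ascontiguousarray(rec.data, dtype="<f8")
    path.write_bytes(data.tobytes())
    meta = {
        "format": "happe-native-v1",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "sample_rate": rec.sample_rate,
        "channel_ids": rec.channel_ids,
        "events": [[label, int(idx)] for label, idx in rec.events],
        "history": rec.history,
        "input_kind": rec.input_kind,
        "units": "uV",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _read_native(path: Path) -> Recording:
    side = _sidecar(path)
    if not side.exists():
        raise RecordingIOError(f"missing sidecar {side}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise RecordingIOError(f"malformed sidecar {side}: {exc}") from exc
    raw = np.frombuffer(path.read_bytes(), dtype="<f8")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_s:
        raise RecordingIOError(
            f"{path}: expected {n_ch}x{n_s} samples, found {raw.size}"
        )
    return Recording(
        data=raw.reshape(n_ch, n_s).copy(),
        sample_rate=float(meta["sample_rate"]),
        channel_ids=list(meta["channel_ids"]),
        events=[(l, int(i)) for l, i in meta.get("events", [])],
        history=list(meta.get("history", [])) + [f"read_recording({path.name})"],
        input_kind=meta.get("input_kind", "rest"),
    )


# ------------------------------------------------------------------- EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: Recording, path: Path, phys_range_uv: float) -> None:
    """Minimal continuous EDF: one data record spanning the whole file."""
    n_ch, n_s = rec.n_channels, rec.n_samples
    duration = n_s / rec.sample_rate
    phys = float(phys_range_uv)
    clipped = np.clip(rec.data, -phys, phys)
    scale = 32767.0 / phys
    digital = np.round(clipped * scale).astype("<i2")

    header = b"".join([
        _pad("0", 8),                       # version
        _pad("X X X X", 80),                # patient id (anonymous)
        _pad("Startdate X happe", 80),      # recording id
        _pad("01.01.00", 8),                # start date
        _pad("00.00.00", 8),                # start time
        _pad(str(256 * (n_ch + 1)), 8),     # header bytes
        _pad("", 44),                       # reserved (continuous EDF)
        _pad("1", 8),                       # number of data records
        _pad(f"{duration:.6g}", 8),         # record duration, seconds
        _pad(str(n_ch), 4),                 # number of signals
    ])
    fields = [
        ("label", 16, rec.channel_ids),
        ("transducer", 80, [""] * n_ch),
        ("dimension", 8, ["uV"] * n_ch),
        ("phys_min", 8, [f"{-phys:.6g}"] * n_ch),
        ("phys_max", 8, [f"{phys:.6g}"] * n_ch),
        ("dig_min", 8, ["-32767"] * n_ch),
        ("dig_max", 8, ["32767"] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("n_samples", 8, [str(n_s)] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_pad(str(v), width) for v in values)
        for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise RecordingIOError(f"cannot parse EDF {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6      # mne loads Volts
    if not np.isfinite(data_uv).all():
        raise RecordingIOError(f"{path}: non-finite samples after load")
    return Recording(
        data=data_uv,
        sample_rate=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
        history=[f"read_recording({path.name})"],
    )
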