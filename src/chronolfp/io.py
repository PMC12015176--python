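"""Reading and writing recordings and derived tables.

Supported trace formats: a simple ``time_s,mv`` CSV dialect and 16-bit EDF
(European Data Format, one channel per region).  Every writer emits a JSON
sidecar with the full recording metadata next to the data file, and the
readers restore it, so write -> read roundtrips preserve both samples and
metadata.  Band-power series travel as ``zt_hours,delta,...,gamma2`` CSV.
"""
from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BAND_NAMES
from .datatypes import BandPowerSeries, BinnedSeries, RawTrace, RecordingMeta


class FormatError(ValueError):
    """Unknown or unsupported file format."""


class CorruptHeaderError(ValueError):
    """File header could not be parsed."""


class NonUniformSamplingError(ValueError):
    """CSV time stamps are not uniformly spaced."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_sidecar(path: Path, meta: RecordingMeta, extra: dict | None = None) -> None:
    d = meta.to_dict()
    if extra:
        d.update(extra)
    _sidecar_path(path).write_text(json.dumps(d, indent=1))


def _read_sidecar(path: Path) -> RecordingMeta | None:
    sp = _sidecar_path(path)
    if not sp.exists():
        return None
    return RecordingMeta.from_dict(json.loads(sp.read_text()))


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def write_trace_csv(trace: RawTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times_s, "mv": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    _write_sidecar(path, trace.meta)
    return path


def _read_trace_csv(path: Path) -> RawTrace:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "mv"]:
        raise CorruptHeaderError(f"{path}: expected 'time_s,mv' header, got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12) or dt[0] <= 0:
            raise NonUniformSamplingError(f"{path}: non-uniform sample spacing")
        fs = 1.0 / dt[0]
    else:
        fs = 1.0
    meta = _read_sidecar(path) or RecordingMeta(fs=float(fs))
    if abs(meta.fs - fs) / fs > 1e-6:
        meta = RecordingMeta(**{**meta.to_dict(), "fs": float(fs)})
    return RawTrace(meta=meta, samples=df["mv"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# minimal 16-bit EDF
# ---------------------------------------------------------------------------

def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_trace_edf(traces: list[RawTrace] | RawTrace, path: str | Path) -> Path:
    """Write one or more aligned traces as a 16-bit EDF file.

    One channel per trace (labelled by region).  All traces must share the
    sampling rate and length, and the length must be a whole number of
    seconds (one data record per second).
    """
    path = Path(path)
    if isinstance(traces, RawTrace):
        traces = [traces]
    fs = traces[0].fs
    n = traces[0].samples.size
    for tr in traces:
        if tr.fs != fs or tr.samples.size != n:
            raise ValueError("all channels must share fs and length")
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    if n % spr != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_rec = n // spr
    ns = len(traces)

    header = b""
    header += _pad("0", 8)
    header += _pad(traces[0].meta.animal_id, 80)
    header += _pad(f"chronolfp {traces[0].meta.genotype} {traces[0].meta.regimen}", 80)
    header += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)

    phys = []
    digital = []
    for tr in traces:
        amp = float(np.max(np.abs(tr.samples)))
        amp = amp if amp > 0 else 1.0
        phys.append(amp)
        # invert the reader's affine map phys = pmin + (dig - dmin)*gain exactly
        gain = 2.0 * amp / 65535.0
        scaled = np.clip(np.round((tr.samples + amp) / gain) - 32768, -32768, 32767)
        digital.append(scaled.astype("<i2"))

    for getter, width in (
        (lambda i: traces[i].meta.region, 16),
        (lambda i: "LFP electrode", 80),
        (lambda i: "mV", 8),
        (lambda i: f"{-phys[i]:.6g}", 8),
        (lambda i: f"{phys[i]:.6g}", 8),
        (lambda i: "-32768", 8),
        (lambda i: "32767", 8),
        (lambda i: "", 80),
        (lambda i: str(spr), 8),
        (lambda i: "", 32),
    ):
        for i in range(ns):
            header += _pad(getter(i), width)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for i in range(ns):
                fh.write(digital[i][r * spr: (r + 1) * spr].tobytes())
    _write_sidecar(path, traces[0].meta,
                   extra={"channels": [tr.meta.to_dict() for tr in traces]})
    return path


def _read_trace_edf(path: Path, channel: int = 0) -> RawTrace:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise CorruptHeaderError(f"{path}: truncated EDF header")
    try:
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise CorruptHeaderError(f"{path}: unparsable EDF header") from exc
    if len(raw) < 256 * (ns + 1):
        raise CorruptHeaderError(f"{path}: truncated EDF signal headers")
    off = 256

    def field(width: int) -> list[str]:
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)]
        off += ns * width
        return vals

    labels = field(16)
    field(80)  # transducer
    field(8)   # dimension
    pmin = [float(v) for v in field(8)]
    pmax = [float(v) for v in field(8)]
    dmin = [int(v) for v in field(8)]
    dmax = [int(v) for v in field(8)]
    field(80)  # prefiltering
    spr = [int(v) for v in field(8)]
    field(32)

    data_off = 256 * (ns + 1)
    rec_len = sum(spr)
    body = np.frombuffer(raw, dtype="<i2", offset=data_off)
    if body.size < n_rec * rec_len:
        raise CorruptHeaderError(f"{path}: data shorter than header declares")
    body = body[: n_rec * rec_len].reshape(n_rec, rec_len)
    start = sum(spr[:channel])
    dig = body[:, start: start + spr[channel]].reshape(-1).astype(float)
    gain = (pmax[channel] - pmin[channel]) / (dmax[channel] - dmin[channel])
    samples = pmin[channel] + (dig - dmin[channel]) * gain
    fs = spr[channel] / rec_dur
    meta = _read_sidecar(path)
    if meta is None:
        region = labels[channel] if labels[channel] in ("SCN", "NAC") else "SCN"
        meta = RecordingMeta(region=region, fs=fs)
    else:
        sidecar = json.loads(_sidecar_path(path).read_text())
        chans = sidecar.get("channels")
        if chans and channel < len(chans):
            meta = RecordingMeta.from_dict(chans[channel])
    return RawTrace(meta=meta, samples=samples)


def read_trace(path: str | Path, format: str | None = None, channel: int = 0) -> RawTrace:
    """Read a raw trace from CSV or EDF (format inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_trace_csv(path)
    if fmt == "edf":
        return _read_trace_edf(path, channel=channel)
    raise FormatError(f"unsupported trace format {fmt!r} (expected csv or edf)")


# ---------------------------------------------------------------------------
# band-power CSV
# ---------------------------------------------------------------------------

def write_bandpower_csv(series: BandPowerSeries, path: str | Path) -> Path:
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format="%.9g")
    _write_sidecar(path, series.meta, extra={"bin_s": series.bin_s})
    return path


def read_bandpower_csv(path: str | Path) -> BandPowerSeries:
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "zt_hours":
        raise CorruptHeaderError(f"{path}: first column must be zt_hours")
    bands = [c for c in df.columns[1:]]
    unknown = set(bands) - set(BAND_NAMES)
    if unknown:
        raise CorruptHeaderError(f"{path}: unknown band columns {sorted(unknown)}")
    sidecar = json.loads(_sidecar_path(path).read_text()) if _sidecar_path(path).exists() else {}
    meta = RecordingMeta.from_dict(sidecar) if sidecar else RecordingMeta()
    zt = df["zt_hours"].to_numpy(dtype=float)
    bin_s = float(sidecar.get("bin_s", round((zt[1] - zt[0]) * 3600.0, 9) if zt.size > 1 else 4.0))
    return BandPowerSeries(meta=meta, bin_s=bin_s, zt_hours=zt,
                           values=df[bands].to_numpy(dtype=float), band_names=bands)


def write_binned_csv(series: BinnedSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"zt_hours": series.zt_hours, "value": series.values}).to_csv(
        path, index=False, float_format="%.9g")
    _write_sidecar(path, series.meta,
                   extra={"bin_s": series.bin_s, "kind": series.kind, "band": series.band})
    return path


def write_ground_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path
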