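"""Reading and writing recordings, shock annotations and feature tables.

Two on-disk recording formats are supported:

* **CSV** — one header line of comma-separated ``key=value`` pairs (must
  include ``sampling_rate_hz``; optional ``start_time_s``), a column-name
  line (first column ``t`` is optional and ignored on read), then rows of
  samples.  All channels in one CSV share the declared rate; channels at a
  different rate (PetCO2) live in their own file.
* **WFDB** — a minimal subset of the PhysioBank header + format-16 signal
  file: single-segment records, little-endian int16 with per-channel
  gain/baseline.  Sufficient for round-tripping synthetic cohorts.

Shock annotations travel in a sidecar CSV with columns
``patient_id, shock_id, shock_time_s, outcome`` (outcome coded 0/1).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .exceptions import BoundaryError, DataError, FormatError, SchemaError
from .types import Channel, Outcome, SignalSegment

__all__ = [
    "Recording",
    "ShockAnnotation",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "extract_pre_shock",
    "write_features",
    "read_features",
]


@dataclass
class ShockAnnotation:
    patient_id: str
    shock_id: str
    shock_time: float
    outcome: Outcome


@dataclass
class Recording:
    """A set of channels (possibly different rates) plus shock annotations."""

    channels: Dict[Channel, SignalSegment]
    annotations: List[ShockAnnotation] = field(default_factory=list)
    record_id: str = ""

    @property
    def ecg(self) -> SignalSegment:
        return self.channels[Channel.ECG]


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

def _write_csv(rec: Recording, path: Path) -> None:
    rates = {seg.sampling_rate for seg in rec.channels.values()}
    if len(rates) != 1:
        raise FormatError(
            "CSV recordings hold a single rate; write multi-rate channels to "
            "separate files"
        )
    rate = rates.pop()
    segs = {ch.value.lower(): seg for ch, seg in rec.channels.items()}
    start = next(iter(rec.channels.values())).start_time
    n = min(seg.n for seg in rec.channels.values())
    with open(path, "w") as fh:
        fh.write(f"sampling_rate_hz={rate:.10g},start_time_s={start:.10g}\n")
        fh.write("t," + ",".join(segs) + "\n")
        t = start + np.arange(n) / rate
        cols = np.column_stack([t] + [segs[k].samples[:n] for k in segs])
        np.savetxt(fh, cols, delimiter=",", fmt="%.10g")


def _read_csv(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header or "=" not in header:
            raise FormatError(f"{path}: missing key=value header line")
        meta: Dict[str, str] = {}
        for item in header.split(","):
            if "=" not in item:
                raise FormatError(f"{path}: garbled header item {item!r}")
            k, v = item.split("=", 1)
            meta[k.strip()] = v.strip()
        if "sampling_rate_hz" not in meta:
            raise FormatError(f"{path}: header lacks sampling_rate_hz")
        try:
            rate = float(meta["sampling_rate_hz"])
        except ValueError as exc:
            raise FormatError(f"{path}: bad sampling_rate_hz") from exc
        start = float(meta.get("start_time_s", 0.0))
        names = [c.strip() for c in fh.readline().strip().split(",") if c.strip()]
        if not names:
            raise FormatError(f"{path}: missing column-name line")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.size == 0:
        raise FormatError(f"{path}: no sample rows")
    channels: Dict[Channel, SignalSegment] = {}
    for j, name in enumerate(names):
        if name.lower() == "t":
            continue
        try:
            ch = Channel(name.upper())
        except ValueError as exc:
            raise FormatError(f"{path}: unknown channel {name!r}") from exc
        col = data[:, j]
        if not np.all(np.isfinite(col)):
            idx = int(np.flatnonzero(~np.isfinite(col))[0])
            raise DataError(f"{path}: non-finite sample at row {idx} ({name})")
        channels[ch] = SignalSegment(
            col, rate, ch, start_time=start, segment_id=path.stem
        )
    rec = Recording(channels, record_id=path.stem)
    ann = path.with_suffix(".shocks.csv")
    if ann.exists():
        rec.annotations = read_annotations(ann)
    return rec


# --------------------------------------------------------------------------
# Minimal WFDB subset (.hea + format-16 .dat)
# --------------------------------------------------------------------------

_WFDB_GAIN = 1000.0  # ADC units per physical unit; 1 uV / 0.001 mmHg resolution


def _write_wfdb(rec: Recording, path: Path) -> None:
    name = path.stem
    segs = list(rec.channels.items())
    rates = {seg.sampling_rate for _, seg in segs}
    if len(rates) != 1:
        raise FormatError("WFDB subset writer requires a single rate")
    rate = rates.pop()
    n = min(seg.n for _, seg in segs)
    hea_lines = [f"{name} {len(segs)} {rate:.10g} {n}"]
    digital = np.empty((n, len(segs)), dtype="<i2")
    for j, (ch, seg) in enumerate(segs):
        adc = np.rint(seg.samples[:n] * _WFDB_GAIN)
        if np.any(np.abs(adc) > 32767):
            raise DataError(f"{ch.value}: amplitude exceeds int16 WFDB range")
        digital[:, j] = adc.astype("<i2")
        hea_lines.append(
            f"{name}.dat 16 {_WFDB_GAIN:.10g}({0})/{seg.units} 16 0 "
            f"{digital[0, j]} 0 0 {ch.value}"
        )
    path.with_suffix(".hea").write_text("\n".join(hea_lines) + "\n")
    digital.tofile(path.with_suffix(".dat"))


def _read_wfdb(path: Path) -> Recording:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea} not found")
    lines = [ln for ln in hea.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{hea}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: garbled record line")
    try:
        n_sig, rate, n = int(head[1]), float(head[2]), int(head[3])
    except ValueError as exc:
        raise FormatError(f"{hea}: garbled record line") from exc
    if n_sig < 1:
        raise FormatError(f"{hea}: record declares no signals")
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea}: expected {n_sig} signal lines")
    raw = np.fromfile(path.with_suffix(".dat"), dtype="<i2")
    if raw.size < n * n_sig:
        raise FormatError(f"{path}.dat: truncated signal file")
    raw = raw[: n * n_sig].reshape(n, n_sig)
    channels: Dict[Channel, SignalSegment] = {}
    for j in range(n_sig):
        fields = lines[1 + j].split()
        if fields[1] != "16":
            raise FormatError(f"{hea}: only format 16 is supported")
        gain_spec = fields[2]
        baseline = 0.0
        gain_part = gain_spec.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gain, baseline = float(g), float(b.rstrip(")"))
        else:
            gain = float(gain_part)
        ch = Channel(fields[-1].upper())
        channels[ch] = SignalSegment(
            (raw[:, j] - baseline) / gain, rate, ch, segment_id=path.stem
        )
    rec = Recording(channels, record_id=path.stem)
    ann = path.with_suffix(".shocks.csv")
    if ann.exists():
        rec.annotations = read_annotations(ann)
    return rec


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------

def read_recording(path: os.PathLike, format: str = "CSV") -> Recording:
    """Read a recording (channels + shock annotations if present).

    Parameters
    ----------
    path :
        CSV file, or WFDB record path/name (``.hea``/``.dat`` pair).
    format :
        ``"CSV"`` or ``"WFDB"``.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "CSV":
        if not path.exists():
            raise FormatError(f"{path} not found")
        return _read_csv(path)
    if fmt == "WFDB":
        return _read_wfdb(path)
    raise FormatError(f"unknown format {format!r}")


def write_recording(rec: Recording, path: os.PathLike, format: str = "CSV") -> None:
    path = Path(path)
    fmt = format.upper()
    if fmt == "CSV":
        _write_csv(rec, path)
    elif fmt == "WFDB":
        _write_wfdb(rec, path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if rec.annotations:
        write_annotations(rec.annotations, path.with_suffix(".shocks.csv"))


def read_annotations(path: os.PathLike) -> List[ShockAnnotation]:
    df = pd.read_csv(path, dtype={"patient_id": str, "shock_id": str})
    required = {"patient_id", "shock_id", "shock_time_s", "outcome"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation columns must include {sorted(required)}")
    return [
        ShockAnnotation(
            str(r.patient_id), str(r.shock_id), float(r.shock_time_s),
            Outcome(int(r.outcome)),
        )
        for r in df.itertuples()
    ]


def write_annotations(anns: List[ShockAnnotation], path: os.PathLike) -> None:
    pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in anns],
            "shock_id": [a.shock_id for a in anns],
            "shock_time_s": [a.shock_time for a in anns],
            "outcome": [int(a.outcome) for a in anns],
        }
    ).to_csv(path, index=False)


def extract_pre_shock(
    source, shock_time: float, duration: float = 9.0, channel: Channel = Channel.ECG
) -> SignalSegment:
    """Cut the fixed-duration window that ends strictly before the shock.

    The window is half-open ``[shock_time - duration, shock_time)`` so no
    post-shock sample leaks into the features; its length is exactly
    ``round(duration * rate)`` samples.
    """
    seg = source.channels[channel] if isinstance(source, Recording) else source
    rate = seg.sampling_rate
    n = int(round(duration * rate))
    # last sample with time strictly below shock_time
    x = (shock_time - seg.start_time) * rate
    end = int(np.ceil(x - 1e-9))
    start = end - n
    if start < 0 or end > seg.n:
        raise BoundaryError(
            f"window [{shock_time - duration:.3f}, {shock_time:.3f}) s outside "
            f"recording [{seg.start_time:.3f}, {seg.start_time + seg.n / rate:.3f}) s"
        )
    return SignalSegment(
        seg.samples[start:end],
        rate,
        seg.channel,
        start_time=seg.start_time + start / rate,
        segment_id=f"{seg.segment_id}@{shock_time:.3f}",
    )


# --------------------------------------------------------------------------
# Feature tables
# --------------------------------------------------------------------------

def write_features(matrix: pd.DataFrame, path: os.PathLike, metadata: Optional[dict] = None) -> None:
    """Persist a feature table losslessly (17 significant digits).

    The table must have unique column names and exactly one ``outcome``
    column. Optional provenance metadata is stored as a JSON comment line.
    """
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()].tolist()
        raise SchemaError(f"duplicate feature columns: {dup}")
    if list(matrix.columns).count("outcome") != 1:
        raise SchemaError("feature table requires exactly one 'outcome' column")
    meta = dict(matrix.attrs.get("metadata", {}))
    if metadata:
        meta.update(metadata)
    with open(path, "w") as fh:
        fh.write("#meta " + json.dumps(meta) + "\n")
        matrix.to_csv(fh, index=False, float_format="%.17g")


def read_features(path: os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#meta "):
            meta = json.loads(first[len("#meta "):])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, float_precision="round_trip")
    if df.columns.duplicated().any():
        raise SchemaError("duplicate feature columns on read")
    if "outcome" not in df.columns:
        raise SchemaError("feature table lacks an 'outcome' column")
    df.attrs["metadata"] = meta
    return df
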