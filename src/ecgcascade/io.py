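"""Record, annotation and segment-dataset I/O.

Two on-disk dialects are supported:

* a plain-text CSV dialect (the interchange contract): a record file is a
  ``fs=<Hz>,subject=<id>,lead=<name>`` header followed by one sample (mV)
  per line; annotations are ``sample_index,symbol`` CSV; segment datasets
  are ``subject_id,record_id,center_sample,label,s0000..`` CSV;
* a minimal WFDB subset: format-16 ``.hea``/``.dat`` signals and MIT-format
  ``.atr`` beat annotations (single-character beat codes N/V/L/R). Only
  this subset is implemented; the CSV dialect is the primary format.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLASS_SYMBOLS, WFDB_SYMBOL_MAP, BeatAnnotation, EcgRecord, Segment
from .errors import FormatError, ParameterError, ShapeError

logger = logging.getLogger(__name__)

# MIT annotation codes for the beat classes in scope.
_ATR_CODE_OF_SYMBOL = {"N": 1, "LBBB": 2, "RBBB": 3, "PVC": 5}
_SYMBOL_OF_ATR_CODE = {1: "N", 2: "L", 3: "R", 5: "V"}
_ATR_SKIP = 59

_WFDB_GAIN = 200.0  # ADC units per millivolt


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_record_csv(record: EcgRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"fs={record.fs:g},subject={record.subject_id},lead={record.lead}\n")
        fh.writelines(f"{float(v)!r}\n" for v in record.signal)


def _read_record_csv(path: Path) -> EcgRecord:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("fs="):
        raise FormatError(f"{path}: not a CSV-dialect ECG record")
    header = dict(item.split("=", 1) for item in lines[0].split(","))
    try:
        signal = np.array([float(v) for v in lines[1:] if v.strip()])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed sample line") from exc
    if signal.size == 0:
        raise FormatError(f"{path}: record holds no samples")
    return EcgRecord(
        record_id=path.stem,
        subject_id=header.get("subject", path.stem),
        fs=float(header["fs"]),
        signal=signal,
        lead=header.get("lead", "MLII"),
    )


def write_annotations_csv(annotations: list[BeatAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_index,symbol\n")
        fh.writelines(f"{a.sample_index},{a.symbol}\n" for a in annotations)


def _read_annotations_csv(path: Path) -> list[BeatAnnotation]:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "sample_index,symbol":
        raise FormatError(f"{path}: not an annotation CSV")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        try:
            idx, sym = line.split(",")
            out.append(BeatAnnotation(int(idx), sym.strip()))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed annotation line {line!r}") from exc
    return out


# ---------------------------------------------------------------------------
# WFDB subset (format 16 signals, MIT .atr beat annotations)
# ---------------------------------------------------------------------------

def write_record_wfdb(record: EcgRecord, basepath: str | Path) -> None:
    """Write ``<base>.hea`` and a format-16 ``<base>.dat`` (single channel)."""
    basepath = Path(basepath)
    adu = np.clip(np.round(record.signal * _WFDB_GAIN), -32768, 32767).astype("<i2")
    basepath.with_suffix(".dat").write_bytes(adu.tobytes())
    with basepath.with_suffix(".hea").open("w") as fh:
        fh.write(f"{basepath.name} 1 {record.fs:g} {len(record.signal)}\n")
        fh.write(
            f"{basepath.name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 "
            f"{int(adu[0])} 0 0 {record.lead}\n"
        )
        fh.write(f"# subject={record.subject_id}\n")


def _read_record_wfdb(hea_path: Path, lead: str = "MLII") -> EcgRecord:
    lines = [ln for ln in hea_path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{hea_path}: empty header")
    comments = [ln for ln in lines if ln.startswith("#")]
    lines = [ln for ln in lines if not ln.startswith("#")]
    head = lines[0].split()
    try:
        name, n_sig, fs = head[0], int(head[1]), float(head[2].split("/")[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{hea_path}: malformed record line") from exc
    if len(lines) < 1 + n_sig:
        raise FormatError(f"{hea_path}: missing signal specification lines")

    channels = []
    for spec in lines[1 : 1 + n_sig]:
        tok = spec.split()
        fmt = int(tok[1])
        if fmt != 16:
            raise FormatError(f"{hea_path}: only format-16 signals are supported")
        gain_tok = tok[2].split("/")[0]
        baseline = 0
        if "(" in gain_tok:
            gain_tok, base_tok = gain_tok.split("(")
            baseline = int(base_tok.rstrip(")"))
        gain = float(gain_tok) or _WFDB_GAIN
        description = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(channels)}"
        channels.append((tok[0], gain, baseline, description))

    dat_path = hea_path.parent / channels[0][0]
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    if n_sig > 1:
        raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    else:
        raw = raw[:, None]

    names = [c[3] for c in channels]
    if lead in names:
        ch = names.index(lead)
    else:
        ch = 0
        logger.warning("%s: lead %s absent (have %s); using channel 0",
                       hea_path.name, lead, names)
    _, gain, baseline, description = channels[ch]
    signal = (raw[:, ch].astype(float) - baseline) / gain

    subject = name
    for c in comments:
        body = c.lstrip("# ").strip()
        if body.startswith("subject="):
            subject = body.split("=", 1)[1]
    return EcgRecord(name, subject, fs, signal, lead=description)


def write_annotations_wfdb(annotations: list[BeatAnnotation], path: str | Path) -> None:
    """Write an MIT-format .atr: 16-bit words, 6-bit type code + 10-bit interval."""
    words = bytearray()
    prev = 0
    for a in sorted(annotations, key=lambda x: x.sample_index):
        code = _ATR_CODE_OF_SYMBOL.get(a.symbol)
        if code is None:
            raise ParameterError(f"cannot encode symbol {a.symbol!r} as a beat code")
        dt = a.sample_index - prev
        if dt > 1023:
            words += struct.pack("<H", _ATR_SKIP << 10)
            words += struct.pack("<H", (dt >> 16) & 0xFFFF)
            words += struct.pack("<H", dt & 0xFFFF)
            dt = 0
        words += struct.pack("<H", (code << 10) | dt)
        prev = a.sample_index
    words += struct.pack("<H", 0)
    Path(path).write_bytes(bytes(words))


def _read_annotations_wfdb(path: Path) -> list[BeatAnnotation]:
    data = path.read_bytes()
    if len(data) < 2 or len(data) % 2:
        raise FormatError(f"{path}: not an MIT annotation file")
    words = np.frombuffer(data, dtype="<u2")
    out: list[BeatAnnotation] = []
    t, i, pending_skip = 0, 0, 0
    while i < len(words):
        code, dt = int(words[i]) >> 10, int(words[i]) & 0x3FF
        if code == 0 and dt == 0:
            break
        if code == _ATR_SKIP:
            if i + 2 >= len(words):
                raise FormatError(f"{path}: truncated skip interval")
            pending_skip = (int(words[i + 1]) << 16) | int(words[i + 2])
            i += 3
            continue
        t += dt + pending_skip
        pending_skip = 0
        sym = _SYMBOL_OF_ATR_CODE.get(code, "?")
        out.append(BeatAnnotation(t, sym))
        i += 1
    return out


# ---------------------------------------------------------------------------
# Public readers
# ---------------------------------------------------------------------------

def read_record(path: str | Path, lead: str = "MLII") -> EcgRecord:
    """Read a WFDB header or a CSV-dialect record; returns the signal in mV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    if path.suffix == ".hea":
        return _read_record_wfdb(path, lead=lead)
    if path.suffix == ".csv":
        return _read_record_csv(path)
    if path.with_suffix(".hea").exists():
        return _read_record_wfdb(path.with_suffix(".hea"), lead=lead)
    # fall back to sniffing the CSV header
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("fs="):
        return _read_record_csv(path)
    raise FormatError(f"{path}: unrecognized record format")


def read_annotations(
    path: str | Path,
    allowed_symbols: frozenset[str] | set[str] | None = frozenset(CLASS_SYMBOLS),
) -> list[BeatAnnotation]:
    """Read beat annotations (MIT .atr or annotation CSV).

    Single-character MIT beat symbols are mapped to class names
    (N->N, V->PVC, L->LBBB, R->RBBB). Annotations are returned in
    ascending sample order; exact duplicates collapse to one (logged);
    symbols outside ``allowed_symbols`` are dropped (pass ``None`` to
    keep everything, out-of-scope symbols flagged via ``in_scope``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix == ".atr":
        raw = _read_annotations_wfdb(path)
    else:
        raw = _read_annotations_csv(path)

    mapped = [BeatAnnotation(a.sample_index, WFDB_SYMBOL_MAP.get(a.symbol, a.symbol))
              for a in raw]
    mapped.sort(key=lambda a: (a.sample_index, a.symbol))
    out: list[BeatAnnotation] = []
    for a in mapped:
        if out and out[-1] == a:
            logger.warning("%s: duplicate annotation at sample %d dropped",
                           path.name, a.sample_index)
            continue
        out.append(a)
    if allowed_symbols is not None:
        out = [a for a in out if a.symbol in allowed_symbols]
    return out


# ---------------------------------------------------------------------------
# Segment datasets
# ---------------------------------------------------------------------------

def write_segments(segments: list[Segment], path: str | Path) -> None:
    """Write a segment dataset as columnar CSV (lossless round trip)."""
    meta_cols = ["subject_id", "record_id", "center_sample", "label"]
    if not segments:
        pd.DataFrame(columns=meta_cols).to_csv(path, index=False)
        return
    width = len(segments[0].window)
    if any(len(s.window) != width for s in segments):
        raise ShapeError("segments have inconsistent window lengths")
    digits = max(4, len(str(width - 1)))
    cols = [f"s{i:0{digits}d}" for i in range(width)]
    df = pd.DataFrame(np.stack([s.window for s in segments]), columns=cols)
    df.insert(0, "label", [s.label for s in segments])
    df.insert(0, "center_sample", [s.center_sample for s in segments])
    df.insert(0, "record_id", [s.record_id for s in segments])
    df.insert(0, "subject_id", [s.subject_id for s in segments])
    df.to_csv(path, index=False, float_format="%.17g")


def read_segments(path: str | Path) -> list[Segment]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: not a segment CSV") from exc
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    return [
        Segment(
            subject_id=str(row["subject_id"]),
            record_id=str(row["record_id"]),
            center_sample=int(row["center_sample"]),
            label=int(row["label"]),
            window=row[sample_cols].to_numpy(dtype=float),
        )
        for _, row in df.iterrows()
    ]
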