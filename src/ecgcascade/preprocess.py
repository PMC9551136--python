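"""Noise filtering, normalization, resampling and R-peak-centered segmentation.

The preprocessing chain applied to each record is

    50 Hz notch -> baseline-drift rejection -> Z-score -> (resample) ->
    R-peak-centered 6 s segmentation

All filters are zero-phase (forward-backward), so annotated R-peak sample
indices remain valid after filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import CLASS_SYMBOLS, BeatAnnotation, EcgRecord, Segment
from .errors import DegenerateInputError, ParameterError, RateError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``half_window_s * target_fs`` samples are taken on each side of the
    R peak, so the default 3 s half-window at 360 Hz gives 2160-sample
    segments.
    """

    powerline_hz: float = 50.0
    powerline_q: float = 30.0
    baseline_hz: float = 0.05
    target_fs: float = 360.0
    half_window_s: float = 3.0
    allowed_symbols: frozenset[str] = field(default_factory=lambda: frozenset(CLASS_SYMBOLS))

    def __post_init__(self) -> None:
        if not (0 < self.baseline_hz < self.powerline_hz < self.target_fs / 2):
            raise ParameterError(
                "require 0 < baseline_hz < powerline_hz < target_fs/2"
            )
        if self.half_window_s <= 0:
            raise ParameterError("half_window_s must be positive")

    @property
    def window_samples(self) -> int:
        return 2 * int(round(self.half_window_s * self.target_fs))


def notch_filter(signal: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch: suppresses a narrow band around ``f0``."""
    if fs <= 0 or q <= 0:
        raise ParameterError("fs and Q must be positive")
    if not 0 < f0 < fs / 2:
        raise ParameterError(f"notch frequency {f0} outside (0, fs/2) at fs={fs}")
    b, a = sps.iirnotch(f0, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(signal, dtype=float))


def remove_baseline(signal: np.ndarray, fs: float, f_c: float = 0.05) -> np.ndarray:
    """Reject DC and slow baseline wander below ~``f_c``.

    Realized as a zero-phase second-order Butterworth high-pass: a true
    0.05 Hz notch at fs=360 is numerically fragile, and the contract is
    attenuation of the drift band, not the filter topology.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if not 0 < f_c < fs / 2:
        raise ParameterError(f"cut-off {f_c} outside (0, fs/2) at fs={fs}")
    sos = sps.butter(2, f_c, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def zscore(signal: np.ndarray) -> np.ndarray:
    """Standardize to zero mean and unit population standard deviation."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ParameterError("signal must hold at least 2 samples")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant signal cannot be Z-scored")
    return (x - x.mean()) / sd


def resample_linear(
    signal: np.ndarray, fs_in: float, fs_out: float
) -> np.ndarray:
    """Resample by linear interpolation onto a uniform grid at ``fs_out``."""
    if fs_in <= 0 or fs_out <= 0:
        raise ParameterError("sampling rates must be positive")
    x = np.asarray(signal, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    n_out = int(round(len(x) * fs_out / fs_in))
    positions = np.arange(n_out) * (fs_in / fs_out)
    return np.interp(positions, np.arange(len(x)), x)


def rescale_annotation_index(index: int, fs_in: float, fs_out: float) -> int:
    """Map an annotation sample index across a resampling step."""
    return int(round(index * fs_out / fs_in))


def segment_record(
    record: EcgRecord,
    annotations: list[BeatAnnotation],
    config: PreprocessConfig | None = None,
) -> list[Segment]:
    """Cut one half-open window ``[r - H, r + H)`` per in-scope annotation.

    ``H = half_window_s * fs`` (1080 samples at defaults, window 2160).
    The segment label is the central annotation's class, regardless of any
    neighboring beats that fall inside the window. Annotations closer than
    ``H`` to either record boundary are skipped (logged), so every window
    is a genuine contiguous stretch of signal.
    """
    config = config or PreprocessConfig()
    if record.fs != config.target_fs:
        raise RateError(
            f"record at {record.fs} Hz; resample to {config.target_fs} Hz first"
        )
    h = int(round(config.half_window_s * record.fs))
    n = len(record.signal)
    segments: list[Segment] = []
    skipped = 0
    for ann in annotations:
        if ann.symbol not in config.allowed_symbols or not ann.in_scope:
            continue
        r = ann.sample_index
        if r - h < 0 or r + h > n:
            skipped += 1
            continue
        segments.append(
            Segment(
                subject_id=record.subject_id,
                record_id=record.record_id,
                center_sample=r,
                label=ann.label,
                window=record.signal[r - h : r + h],
            )
        )
    if skipped:
        logger.info("%s: skipped %d boundary annotations", record.record_id, skipped)
    return segments


def preprocess_record(
    record: EcgRecord,
    annotations: list[BeatAnnotation],
    config: PreprocessConfig | None = None,
) -> list[Segment]:
    """Full chain: notch -> baseline rejection -> Z-score -> resample -> segment."""
    config = config or PreprocessConfig()
    x = notch_filter(record.signal, record.fs, config.powerline_hz, config.powerline_q)
    x = remove_baseline(x, record.fs, config.baseline_hz)
    x = zscore(x)
    anns = annotations
    fs = record.fs
    if fs != config.target_fs:
        x = resample_linear(x, fs, config.target_fs)
        anns = [
            BeatAnnotation(rescale_annotation_index(a.sample_index, fs, config.target_fs),
                           a.symbol)
            for a in annotations
        ]
        fs = config.target_fs
    clean = EcgRecord(record.record_id, record.subject_id, fs, x, lead=record.lead)
    return segment_record(clean, anns, config)
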