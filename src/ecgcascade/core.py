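"""Core domain containers: ECG records, beat annotations, labeled segments.

Conventions fixed package-wide:

* sample indexing is 0-based; sample ``i`` of a record occurs at time
  ``i / fs`` seconds;
* segment windows are half-open ``[r - H, r + H)`` around the central
  R peak, so a window always holds exactly ``2 * H`` samples;
* beat-class label coding is ``0=N, 1=PVC, 2=LBBB, 3=RBBB``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Beat-class symbols in label order.
CLASS_SYMBOLS: tuple[str, ...] = ("N", "PVC", "LBBB", "RBBB")

#: symbol -> integer label (0=N, 1=PVC, 2=LBBB, 3=RBBB).
LABEL_OF_SYMBOL: dict[str, int] = {s: i for i, s in enumerate(CLASS_SYMBOLS)}

#: Single-character beat symbols used by MIT-format annotation files.
WFDB_SYMBOL_MAP: dict[str, str] = {"N": "N", "V": "PVC", "L": "LBBB", "R": "RBBB"}


@dataclass
class EcgRecord:
    """One subject's single-lead ECG signal.

    Parameters
    ----------
    record_id : str
        Identifier of the recording (one subject may have several).
    subject_id : str
        Identifier of the patient; drives subject-exclusive splitting.
    fs : float
        Sampling rate in Hz.
    signal : numpy.ndarray
        Amplitude samples in millivolt.
    lead : str
        Recording lead name; MLII for the primary channel.
    """

    record_id: str
    subject_id: str
    fs: float
    signal: np.ndarray
    lead: str = "MLII"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size == 0:
            raise ParameterError("signal must be a non-empty 1-D array")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


@dataclass(frozen=True)
class BeatAnnotation:
    """An annotated R-peak position with its beat-class symbol.

    ``symbol`` is one of N/PVC/LBBB/RBBB for in-scope beats; any other
    symbol is preserved on read but marked out of scope.
    """

    sample_index: int
    symbol: str

    @property
    def in_scope(self) -> bool:
        return self.symbol in LABEL_OF_SYMBOL

    @property
    def label(self) -> int:
        if not self.in_scope:
            raise ParameterError(f"symbol {self.symbol!r} has no class label")
        return LABEL_OF_SYMBOL[self.symbol]


@dataclass
class Segment:
    """A fixed-length labeled window centered on one R peak."""

    subject_id: str
    record_id: str
    center_sample: int
    label: int
    window: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.label not in (0, 1, 2, 3):
            raise ParameterError(f"label must be in {{0,1,2,3}}, got {self.label}")
        if self.window.ndim != 1:
            raise ParameterError("window must be 1-D")


def segments_to_arrays(
    segments: list[Segment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack segments into ``(X, y, subjects)`` arrays for model training.

    ``X`` has shape ``(n, W, 1)`` (float32), ``y`` the integer labels and
    ``subjects`` the per-segment subject ids.
    """
    if not segments:
        return (
            np.zeros((0, 0, 1), dtype=np.float32),
            np.zeros(0, dtype=int),
            np.zeros(0, dtype=object),
        )
    X = np.stack([s.window for s in segments]).astype(np.float32)[..., None]
    y = np.array([s.label for s in segments], dtype=int)
    subjects = np.array([s.subject_id for s in segments], dtype=object)
    return X, y, subjects
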