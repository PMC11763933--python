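"""Reading, segmenting, band-filtering and normalizing multichannel EEG.

The preprocessing chain is: read a recording (EDF or delimited text),
cut it into equal non-overlapping segments, band-pass each segment into
the six clinical frequency bands with a second-order Butterworth filter,
and z-score every channel of every band-filtered segment.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import (
    ConfigurationError,
    DegenerateSignalError,
    FormatError,
    InsufficientLengthError,
    UnsupportedInputError,
)

#: Clinical EEG frequency bands (Hz) used throughout the pipeline.
DEFAULT_BANDS: tuple["BandDefinition", ...]

DEFAULT_SEGMENT_LEN = 30_000  # samples; 60 s at 500 Hz
DEFAULT_N_SEGMENTS = 5
DEFAULT_FILTER_ORDER = 2


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open pass edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low_hz < self.high_hz:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
    BandDefinition("smr", 12.0, 15.0),
)


@dataclass
class EEGRecording:
    """A channels x samples recording with sampling rate and labels."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise UnsupportedInputError("data must be a 2-D channels x samples array")
        if self.data.shape[0] < 2:
            raise UnsupportedInputError(
                f"need at least 2 channels for connectivity, got {self.data.shape[0]}"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise UnsupportedInputError("recording contains NaN or Inf samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise UnsupportedInputError("channel_labels length must match n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Segment:
    """One equal-length, zero-anchored slice of a recording."""

    data: np.ndarray
    segment_index: int
    subject_id: str = ""
    class_label: str | None = None


@dataclass
class BandSegment:
    """A segment restricted to one frequency band; optionally z-scored."""

    data: np.ndarray
    band: BandDefinition
    segment_index: int = 0
    subject_id: str = ""
    class_label: str | None = None
    normalized: bool = False


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _edf_header_sanity(path: Path) -> None:
    """Reject EDF files whose signals carry different sampling rates.

    Reads only the fixed header and the per-signal 'samples per record'
    table, so corrupt files fail before any heavy parsing.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: not an EDF file (header shorter than 256 bytes)")
        try:
            n_signals = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF signal count") from exc
        if n_signals < 1:
            raise FormatError(f"{path}: EDF header reports {n_signals} signals")
        fh.seek(256 + n_signals * 216)
        raw = fh.read(n_signals * 8)
        if len(raw) < n_signals * 8:
            raise FormatError(f"{path}: truncated EDF signal header")
        spr = [raw[i * 8 : (i + 1) * 8].decode("ascii", "replace").strip() for i in range(n_signals)]
    try:
        rates = {int(s) for s in spr}
    except ValueError as exc:
        raise FormatError(f"{path}: malformed samples-per-record field") from exc
    if len(rates) > 1:
        raise UnsupportedInputError(
            f"{path}: channels have differing per-record sample counts {sorted(rates)}; "
            "mixed sampling rates are not supported"
        )


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    Sampling rate and channel labels come from the EDF header; channels
    keep header order. Files with per-channel sampling rates raise
    :class:`UnsupportedInputError`.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    _edf_header_sanity(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted concrete types
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    data = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
    )


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a minimal 16-bit EDF file (one data record).

    Enough of the format for round-tripping synthetic cohorts through
    :func:`read_edf`; not a general-purpose clinical EDF exporter.
    """
    path = Path(path)
    n_sig = rec.n_channels
    n_samp = rec.n_samples
    duration = n_samp / rec.fs
    pmin = float(np.min(rec.data))
    pmax = float(np.max(rec.data))
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id or "X", 80),
            pad("synthetic", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + n_sig * 256), 8),
            pad("", 44),
            pad("1", 8),  # one data record
            pad(f"{duration:.6g}", 8),
            pad(str(n_sig), 4),
        ]
    )
    per = b"".join(pad(lbl, 16) for lbl in rec.channel_labels)
    per += b"".join(pad("synthetic EEG", 80) for _ in range(n_sig))
    per += b"".join(pad("uV", 8) for _ in range(n_sig))
    per += b"".join(pad(f"{pmin:.6g}", 8) for _ in range(n_sig))
    per += b"".join(pad(f"{pmax:.6g}", 8) for _ in range(n_sig))
    per += b"".join(pad(str(dmin), 8) for _ in range(n_sig))
    per += b"".join(pad(str(dmax), 8) for _ in range(n_sig))
    per += b"".join(pad("", 80) for _ in range(n_sig))
    per += b"".join(pad(str(n_samp), 8) for _ in range(n_sig))
    per += b"".join(pad("", 32) for _ in range(n_sig))

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((rec.data - pmin) * scale + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per)
        fh.write(digital.tobytes())  # record layout: signal-major


def read_delimited(
    path: str | Path,
    fs: float,
    orientation: str = "channels-by-samples",
    delimiter: str | None = None,
) -> EEGRecording:
    """Read a delimited numeric table (CSV/TSV) as a recording.

    Rows are channels by default; pass ``orientation="samples-by-channels"``
    to transpose. A non-numeric cell raises :class:`FormatError` naming its
    1-based row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, header=None, sep=delimiter, engine="python")
    except Exception as exc:
        raise FormatError(f"{path}: could not parse delimited table ({exc})") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {r + 1}, column {c + 1}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing value at row {r + 1}, column {c + 1}")
    data = numeric.to_numpy(dtype=np.float64)
    if orientation == "samples-by-channels":
        data = data.T
    elif orientation != "channels-by-samples":
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    return EEGRecording(data=data, fs=fs, subject_id=path.stem)


# ---------------------------------------------------------------------------
# segmentation / filtering / normalization
# ---------------------------------------------------------------------------

def segment_recording(
    rec: EEGRecording,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> list[Segment]:
    """Cut the first ``segment_len * n_segments`` samples into equal segments.

    Segments are consecutive and non-overlapping, anchored at sample 0;
    any trailing remainder is discarded.
    """
    needed = segment_len * n_segments
    if rec.n_samples < needed:
        raise InsufficientLengthError(
            f"need {needed} samples for {n_segments} segments of {segment_len}, "
            f"recording has {rec.n_samples}"
        )
    return [
        Segment(
            data=rec.data[:, i * segment_len : (i + 1) * segment_len].copy(),
            segment_index=i,
            subject_id=rec.subject_id,
            class_label=rec.class_label,
        )
        for i in range(n_segments)
    ]


def extract_bands(
    seg: Segment,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    order: int = DEFAULT_FILTER_ORDER,
    zero_phase: bool = True,
) -> list[BandSegment]:
    """Band-pass a segment into each band with a Butterworth filter.

    ``order`` is the design order of the analogue prototype (default 2).
    With ``zero_phase`` the filter is applied forward and backward
    (``sosfiltfilt``), which removes phase distortion at the cost of
    doubling the effective order.
    """
    nyquist = fs / 2.0
    out: list[BandSegment] = []
    for band in bands:
        if band.high_hz >= nyquist:
            raise ConfigurationError(
                f"band {band.name!r} upper edge {band.high_hz} Hz is not below "
                f"Nyquist ({nyquist} Hz)"
            )
        sos = signal.butter(
            order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
        )
        if zero_phase:
            filtered = signal.sosfiltfilt(sos, seg.data, axis=1)
        else:
            filtered = signal.sosfilt(sos, seg.data, axis=1)
        out.append(
            BandSegment(
                data=np.ascontiguousarray(filtered),
                band=band,
                segment_index=seg.segment_index,
                subject_id=seg.subject_id,
                class_label=seg.class_label,
            )
        )
    return out


def zscore_normalize(bs: BandSegment) -> BandSegment:
    """Z-score each channel: subtract its mean, divide by population sd."""
    mu = bs.data.mean(axis=1, keepdims=True)
    sigma = bs.data.std(axis=1, keepdims=True)  # population (divisor n)
    flat = np.nonzero(sigma.ravel() == 0.0)[0]
    if flat.size:
        raise DegenerateSignalError(
            f"channel index {flat[0]} is constant in band {bs.band.name!r}; "
            "z-score undefined"
        )
    return replace(bs, data=(bs.data - mu) / sigma, normalized=True)
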