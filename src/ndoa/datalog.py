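"""Data-log I/O: single-channel EEG plus the per-second annotation stream.

The on-disk form is a two-file CSV dialect:

* ``<prefix>.eeg.csv`` — header ``t_sample,eeg_uV[,eeg_uV_ch2]``, one row per
  sample at 128 Hz, amplitudes in microvolts.
* ``<prefix>.ann.csv`` — header ``t_s,bis,sqi,emg``, one row per second.
  Extra columns (impedance, monitor error codes, ...) are carried through as
  opaque extras.

Second ``t`` covers the half-open sample interval ``[t*fs, (t+1)*fs)``; all
indices are 0-based. A reference-index value of −3276.8 is the monitor's
invalid-BIS sentinel, recorded when signal quality is poor; it is preserved
verbatim by I/O and interpreted only by :func:`valid_bis_mask`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataLogParseError, NdoaError, UnsupportedSamplingRateError

#: Sampling rate (Hz) of the supported monitor recordings.
DEFAULT_FS = 128.0

#: Invalid reference-index sentinel written by the monitor when SQI is poor.
BIS_SENTINEL = -3276.8

#: Absolute tolerance for recognising the sentinel after float round-trips.
SENTINEL_ATOL = 1e-6

#: SQI below this value blanks the reference index on the monitor.
SQI_VALID_MIN = 15.0

ANNOTATION_COLUMNS = ("t_s", "bis", "sqi", "emg")


def is_sentinel(bis) -> np.ndarray | bool:
    """True where ``bis`` equals the −3276.8 invalid marker (atol 1e-6)."""
    return np.isclose(np.asarray(bis, dtype=float), BIS_SENTINEL,
                      rtol=0.0, atol=SENTINEL_ATOL)


@dataclass
class EEGRecording:
    """A single-channel EEG trace in microvolts at a fixed sampling rate."""

    samples: np.ndarray
    fs: float = DEFAULT_FS
    subject_id: str = ""
    channel: str = "CH2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise NdoaError("EEG recording must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise NdoaError("EEG samples must all be finite")
        if not self.fs > 0:
            raise NdoaError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_seconds(self) -> int:
        return int(self.samples.size // self.fs)


@dataclass(frozen=True)
class AnnotatedRecord:
    """One second of monitor annotations: reference index, SQI, EMG index."""

    t: int
    bis: float
    sqi: float
    emg: float


@dataclass
class DataLog:
    """An EEG recording aligned with its per-second annotation stream."""

    recording: EEGRecording
    annotations: list[AnnotatedRecord]
    extras: pd.DataFrame | None = field(default=None, repr=False)

    def validate(self) -> None:
        """Raise :class:`NdoaError` if the alignment invariants do not hold."""
        n_sec = self.recording.n_seconds
        if len(self.annotations) != n_sec:
            raise NdoaError(
                f"annotation count {len(self.annotations)} != "
                f"floor(samples/fs) = {n_sec}"
            )
        ts = [a.t for a in self.annotations]
        if ts != list(range(len(ts))):
            raise NdoaError("annotation seconds must be 0-based and strictly "
                            "increasing by 1")
        for a in self.annotations:
            if not (0.0 <= a.sqi <= 100.0):
                raise NdoaError(f"SQI out of [0,100] at t={a.t}: {a.sqi}")
            if not (0.0 <= a.bis <= 100.0 or is_sentinel(a.bis)):
                raise NdoaError(f"reference index out of range at t={a.t}: "
                                f"{a.bis}")

    def annotation_frame(self) -> pd.DataFrame:
        """Annotations as a DataFrame with columns ``t_s,bis,sqi,emg``."""
        return pd.DataFrame(
            {
                "t_s": [a.t for a in self.annotations],
                "bis": [a.bis for a in self.annotations],
                "sqi": [a.sqi for a in self.annotations],
                "emg": [a.emg for a in self.annotations],
            }
        )

    @property
    def n_seconds(self) -> int:
        return len(self.annotations)


def _resolve_paths(prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    name = prefix.name
    for suffix in (".eeg.csv", ".ann.csv"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    base = prefix.with_name(name)
    return base.with_name(base.name + ".eeg.csv"), base.with_name(base.name + ".ann.csv")


def _parse_rows(path: Path, expected_prefix: tuple[str, ...]):
    """Yield (lineno, list-of-floats) rows; extras beyond the known columns
    are returned as raw strings for pass-through."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataLogParseError(f"{path}: empty file, missing header")
        header = [h.strip() for h in header]
        for want, got in zip(expected_prefix, header):
            if want != got:
                raise DataLogParseError(
                    f"{path}:1: expected column '{want}', found '{got}'"
                )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                values = [float(v) for v in row[: len(header)]]
            except ValueError as exc:
                raise DataLogParseError(f"{path}:{lineno}: {exc}") from None
            if len(values) < len(expected_prefix):
                raise DataLogParseError(
                    f"{path}:{lineno}: expected at least "
                    f"{len(expected_prefix)} columns, found {len(values)}"
                )
            rows.append((lineno, values))
    return header, rows


def read_datalog(prefix, channel: str = "CH2", fs: float = DEFAULT_FS,
                 allow_nonstandard_fs: bool = False,
                 subject_id: str | None = None) -> DataLog:
    """Read a two-file CSV data log.

    Parameters
    ----------
    prefix
        Path prefix; ``<prefix>.eeg.csv`` and ``<prefix>.ann.csv`` are read.
        Passing either file's full path also works.
    channel
        ``"CH1"`` or ``"CH2"``; applied when the EEG file carries two
        channels. The monitor's second channel is the default because its
        feature-to-state correlation is the more consistent of the two.
    fs
        Sampling rate of the file. Only 128 Hz is supported unless
        ``allow_nonstandard_fs`` is set.
    """
    if not math.isclose(fs, DEFAULT_FS) and not allow_nonstandard_fs:
        raise UnsupportedSamplingRateError(
            f"sampling rate {fs} Hz is not supported (expected {DEFAULT_FS}); "
            "pass allow_nonstandard_fs=True to override"
        )
    eeg_path, ann_path = _resolve_paths(prefix)
    if not eeg_path.exists():
        raise FileNotFoundError(eeg_path)
    if not ann_path.exists():
        raise FileNotFoundError(ann_path)

    eeg_header, eeg_rows = _parse_rows(eeg_path, ("t_sample", "eeg_uV"))
    two_channel = len(eeg_header) >= 3 and eeg_header[2] == "eeg_uV_ch2"
    col = 1
    if two_channel and channel.upper() == "CH2":
        col = 2
    elif channel.upper() not in ("CH1", "CH2"):
        raise NdoaError(f"unknown channel {channel!r}; expected CH1 or CH2")
    samples = np.array([v[col] for _, v in eeg_rows], dtype=float)

    ann_header, ann_rows = _parse_rows(ann_path, ANNOTATION_COLUMNS)
    annotations = [
        AnnotatedRecord(t=int(v[0]), bis=v[1], sqi=v[2], emg=v[3])
        for _, v in ann_rows
    ]
    extras = None
    if len(ann_header) > 4:
        extras = pd.DataFrame(
            [v[4:] for _, v in ann_rows], columns=ann_header[4:]
        )

    if subject_id is None:
        subject_id = eeg_path.name[: -len(".eeg.csv")]
    log = DataLog(
        recording=EEGRecording(samples=samples, fs=fs, subject_id=subject_id,
                               channel=channel.upper()),
        annotations=annotations,
        extras=extras,
    )
    log.validate()
    return log


def write_datalog(log: DataLog, prefix) -> None:
    """Write ``log`` as ``<prefix>.eeg.csv`` + ``<prefix>.ann.csv``.

    Amplitudes are printed with 10 significant digits so a write/read
    round-trip reproduces them within 1e-9; the −3276.8 sentinel survives
    verbatim.
    """
    log.validate()
    eeg_path, ann_path = _resolve_paths(prefix)
    eeg_path.parent.mkdir(parents=True, exist_ok=True)
    with open(eeg_path, "w", newline="") as fh:
        fh.write("t_sample,eeg_uV\n")
        for i, x in enumerate(log.recording.samples):
            fh.write(f"{i},{x:.10g}\n")
    extra_cols = list(log.extras.columns) if log.extras is not None else []
    with open(ann_path, "w", newline="") as fh:
        fh.write(",".join(ANNOTATION_COLUMNS + tuple(extra_cols)) + "\n")
        for i, a in enumerate(log.annotations):
            row = f"{a.t},{a.bis:.10g},{a.sqi:.10g},{a.emg:.10g}"
            if extra_cols:
                row += "," + ",".join(
                    f"{v:.10g}" for v in log.extras.iloc[i].tolist()
                )
            fh.write(row + "\n")


def valid_bis_mask(annotations) -> np.ndarray:
    """Element-wise validity of the reference index.

    False exactly where the index carries the −3276.8 sentinel or SQI < 15
    (the monitor blanks its display below that quality); True elsewhere.
    Accepts a sequence of :class:`AnnotatedRecord` or a DataFrame with
    ``bis``/``sqi`` columns.
    """
    if isinstance(annotations, pd.DataFrame):
        bis = annotations["bis"].to_numpy(dtype=float)
        sqi = annotations["sqi"].to_numpy(dtype=float)
    else:
        bis = np.array([a.bis for a in annotations], dtype=float)
        sqi = np.array([a.sqi for a in annotations], dtype=float)
    return ~(is_sentinel(bis) | (sqi < SQI_VALID_MIN))
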