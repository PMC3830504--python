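"""Reading and writing EOG signals and event tables.

The central container is :class:`Recording`: two synchronized EOG channels
(horizontal ``eog_h`` and vertical ``eog_v``, both in microvolts) plus a
sampling rate. The horizontal channel is the bipolar difference between the
electrodes at the outer canthi (right minus left); the vertical channel is the
difference between the electrodes above and below one eye (up minus down), so
that blinks appear as large positive deflections.

Event tables are plain TSV with one row per detected eye event; times are in
seconds, computed from 0-based sample indices as ``index / fs``. Event
intervals are closed ``[onset, offset]`` in samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

#: The five event classes emitted by the classifier.
EVENT_LABELS = (
    "HORIZONTAL_SACCADE",
    "VERTICAL_SACCADE",
    "OBLIQUE_SACCADE",
    "BLINK",
    "SACCADE_WITH_BLINK",
)

#: Saccade-like classes (used by duration filtering and gain calibration).
SACCADE_LABELS = ("HORIZONTAL_SACCADE", "VERTICAL_SACCADE", "OBLIQUE_SACCADE")

_EVENT_COLUMNS = (
    "label",
    "onset_s",
    "offset_s",
    "peak_s",
    "duration_s",
    "peak_velocity_uV_s",
    "direction_sign",
)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Recording:
    """Two-channel EOG time series in microvolts.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, > 0.
    eog_h, eog_v : array-like
        Horizontal and vertical EOG samples in µV; equal length, finite.
    start_time : float
        Offset of the first sample in seconds (default 0).
    meta : dict
        Free-form metadata (subject id, device, ...).
    """

    fs: float
    eog_h: np.ndarray
    eog_v: np.ndarray
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eog_h = _as_float_array(self.eog_h, "eog_h")
        self.eog_v = _as_float_array(self.eog_v, "eog_v")
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if len(self.eog_h) != len(self.eog_v):
            raise InputError(
                f"channel length mismatch: eog_h has {len(self.eog_h)} samples, "
                f"eog_v has {len(self.eog_v)}"
            )
        if len(self.eog_h) == 0:
            raise InputError("recording must contain at least one sample")
        if not (np.isfinite(self.eog_h).all() and np.isfinite(self.eog_v).all()):
            raise InputError("non-finite samples (NaN/inf) in recording")

    @property
    def n_samples(self) -> int:
        return len(self.eog_h)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def scaled(self, k: float) -> "Recording":
        """Return a copy with both channels multiplied by ``k``."""
        return Recording(self.fs, self.eog_h * k, self.eog_v * k,
                         self.start_time, dict(self.meta))


@dataclass
class EventRecord:
    """One classified eye event.

    ``onset``/``peak``/``offset`` are 0-based sample indices with
    ``onset <= peak <= offset``; the interval is closed. ``direction_sign``
    is +1/−1 for saccades (sign of the dominant velocity lobe) and +1 for
    blinks. ``measures`` holds named kinematic measures such as
    ``duration_s``, ``peak_velocity_uV_s``, ``closing_time_s``.
    """

    label: str
    onset: int
    offset: int
    peak: int
    direction_sign: int = 1
    measures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise InputError(f"unknown event label {self.label!r}")
        if not (0 <= self.onset <= self.peak <= self.offset):
            raise InputError(
                f"event indices must satisfy 0 <= onset <= peak <= offset, got "
                f"onset={self.onset}, peak={self.peak}, offset={self.offset}"
            )

    def duration_s(self, fs: float) -> float:
        return (self.offset - self.onset) / fs

    @property
    def is_saccade(self) -> bool:
        return self.label in SACCADE_LABELS


def derive_bipolar(right, left, up, down, fs: float) -> Recording:
    """Combine four monopolar electrode channels into a bipolar recording.

    ``eog_h = right − left`` and ``eog_v = up − down``, elementwise, so that
    rightward gaze and upward gaze (and blinks) give positive deflections.
    """
    right = _as_float_array(right, "right")
    left = _as_float_array(left, "left")
    up = _as_float_array(up, "up")
    down = _as_float_array(down, "down")
    n = len(right)
    if not (len(left) == len(up) == len(down) == n):
        raise InputError(
            "all four monopolar channels must have equal length, got "
            f"{n}/{len(left)}/{len(up)}/{len(down)}"
        )
    if fs <= 0:
        raise InputError(f"sampling rate must be positive, got {fs}")
    return Recording(fs=fs, eog_h=right - left, eog_v=up - down)


_FS_HEADER = "# fs_hz:"


def write_recording(rec: Recording, path) -> None:
    """Write a recording as TSV: a ``# fs_hz: <fs>`` comment line followed by
    a header row ``eog_h\\teog_v`` and one row per sample (µV)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_FS_HEADER} {rec.fs:.10g}\n")
        fh.write("eog_h\teog_v\n")
        for h, v in zip(rec.eog_h, rec.eog_v):
            fh.write(f"{h:.6g}\t{v:.6g}\n")


def read_recording(path, format: str | None = None, fs: float | None = None,
                   channel_map: Mapping[str, str] | None = None) -> Recording:
    """Read a two-channel EOG recording from CSV/TSV or EDF.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"csv", "tsv", "edf"}, optional
        Inferred from the file suffix when omitted.
    fs : float, optional
        Sampling rate in Hz. Mandatory for text input unless the file carries
        a ``# fs_hz:`` header line (as written by :func:`write_recording`).
        Ignored for EDF (the EDF header is authoritative).
    channel_map : mapping, optional
        Maps roles to column/channel names. Either
        ``{"eog_h": ..., "eog_v": ...}`` or the four monopolar roles
        ``{"right": ..., "left": ..., "up": ..., "down": ...}`` (combined via
        :func:`derive_bipolar`). Defaults to ``eog_h``/``eog_v``.

    Text samples are assumed to be in µV; EDF samples are converted using the
    file's physical dimension/scaling.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in ("csv", "tsv", "edf") else "tsv"
    if format == "edf":
        return _read_edf(path, channel_map)
    if format not in ("csv", "tsv"):
        raise InputError(f"unsupported format {format!r}")

    sep = "," if format == "csv" else "\t"
    header_fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(_FS_HEADER):
        header_fs = float(first[len(_FS_HEADER):].strip())
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"could not parse {path}: {exc}") from exc
    fs = fs if fs is not None else header_fs
    if fs is None:
        raise InputError(
            "sampling rate required for text input: pass fs= or include a "
            f"'{_FS_HEADER} <Hz>' header line"
        )
    return _recording_from_columns(df, fs, channel_map, str(path))


def _recording_from_columns(df: pd.DataFrame, fs: float,
                            channel_map: Mapping[str, str] | None,
                            source: str) -> Recording:
    cmap = dict(channel_map or {"eog_h": "eog_h", "eog_v": "eog_v"})

    def col(name):
        if name not in df.columns:
            raise InputError(f"channel {name!r} not found in {source}; "
                             f"available: {list(df.columns)}")
        values = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InputError(f"non-finite samples in channel {name!r} of {source}")
        return values

    if {"right", "left", "up", "down"} <= set(cmap):
        return derive_bipolar(col(cmap["right"]), col(cmap["left"]),
                              col(cmap["up"]), col(cmap["down"]), fs)
    if {"eog_h", "eog_v"} <= set(cmap):
        return Recording(fs=fs, eog_h=col(cmap["eog_h"]), eog_v=col(cmap["eog_v"]))
    raise InputError(
        "channel_map must name either eog_h/eog_v or right/left/up/down; got "
        f"{sorted(cmap)}"
    )


def _read_edf(path: Path, channel_map: Mapping[str, str] | None) -> Recording:
    try:
        from mne.io import read_raw_edf
    except ImportError as exc:  # pragma: no cover
        raise InputError(
            "reading EDF requires the optional dependency 'mne' "
            "(pip install eogkit[edf])"
        ) from exc
    raw = read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    cmap = dict(channel_map or {"eog_h": "eog_h", "eog_v": "eog_v"})

    def chan(name):
        if name not in raw.ch_names:
            raise InputError(f"EDF channel {name!r} not found in {path}; "
                             f"available: {raw.ch_names}")
        data = raw.get_data(picks=[name], units="uV")[0]
        if not np.isfinite(data).all():
            raise InputError(f"non-finite samples in EDF channel {name!r}")
        return data

    if {"right", "left", "up", "down"} <= set(cmap):
        return derive_bipolar(chan(cmap["right"]), chan(cmap["left"]),
                              chan(cmap["up"]), chan(cmap["down"]), fs)
    return Recording(fs=fs, eog_h=chan(cmap["eog_h"]), eog_v=chan(cmap["eog_v"]))


def events_to_frame(events: Sequence[EventRecord], fs: float) -> pd.DataFrame:
    """Convert events to a tidy DataFrame (times in seconds), sorted by onset."""
    events = sorted(events, key=lambda e: (e.onset, e.offset, e.label))
    extra_keys = sorted({k for e in events for k in e.measures
                         if not k.startswith("_")}
                        - {"duration_s", "peak_velocity_uV_s"})
    rows = []
    for e in events:
        row = {
            "label": e.label,
            "onset_s": e.onset / fs,
            "offset_s": e.offset / fs,
            "peak_s": e.peak / fs,
            "duration_s": e.measures.get("duration_s", e.duration_s(fs)),
            "peak_velocity_uV_s": e.measures.get("peak_velocity_uV_s", math.nan),
            "direction_sign": e.direction_sign,
        }
        for k in extra_keys:
            row[k] = e.measures.get(k, math.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(_EVENT_COLUMNS) + extra_keys)


def write_events(events: Sequence[EventRecord], path, fs: float) -> None:
    """Write an event table as TSV, one row per event, sorted by onset.

    Floats are written with 6 significant digits. An empty event list yields a
    header-only file.
    """
    df = events_to_frame(events, fs)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events(path, fs: float) -> list[EventRecord]:
    """Parse an event TSV (as written by :func:`write_events`) back into
    :class:`EventRecord` objects; second-domain times are converted back to
    sample indices by rounding."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"event file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_EVENT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise InputError(f"event table {path} lacks columns {sorted(missing)}")
    events = []
    base = {"label", "onset_s", "offset_s", "peak_s", "direction_sign"}
    for _, row in df.iterrows():
        measures = {k: row[k] for k in df.columns
                    if k not in base and pd.notna(row[k])}
        events.append(EventRecord(
            label=str(row["label"]),
            onset=int(round(row["onset_s"] * fs)),
            offset=int(round(row["offset_s"] * fs)),
            peak=int(round(row["peak_s"] * fs)),
            direction_sign=int(row.get("direction_sign", 1)),
            measures=measures,
        ))
    return events
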