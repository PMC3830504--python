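"""Per-event kinematic measures and recording-level summaries.

For every event the following are computed (times in seconds, velocities in
µV/s unless gain-calibrated):

* ``duration_s`` — (offset − onset)/fs;
* ``peak_velocity_uV_s`` — for saccades, the maximum absolute velocity on
  the event's axis inside [onset, offset]; oblique saccades additionally
  report per-axis maxima and use the Euclidean combination as the headline
  value;
* ``acceleration_uV_s2`` / ``deceleration_uV_s2`` — max/min of the
  differentiated velocity within the event;
* ``closing_time_s`` / ``opening_time_s`` — for blinks, peak − onset and
  offset − peak; their sum equals the duration exactly by construction;
* ``amplitude_uV`` — the positional signal change over the event on the
  dominant axis (value at offset minus value at onset for step-like
  saccades; peak minus onset value for pulse-like blinks).

When a set of reference saccades of known visual angle is available (e.g.
a few 10-degree horizontal saccades), :func:`calibrate_gain` estimates the
µV-per-degree gain and converts peak velocities to deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import ClassifiedEvents
from .exceptions import CalibrationError, InputError
from .io import EVENT_LABELS, SACCADE_LABELS, EventRecord, Recording
from .preprocess import VelocitySignal, differentiate


@dataclass
class CalibrationGain:
    """Voltage-to-visual-angle relationship from reference saccades."""

    uv_per_deg: float
    n_reference: int
    reference_amplitude_deg: float = 10.0


def _events_of(events) -> list[EventRecord]:
    return events.events if isinstance(events, ClassifiedEvents) else list(events)


def compute_measures(events, clean: Recording, vel_h: VelocitySignal,
                     vel_v: VelocitySignal, fs: float | None = None):
    """Fill ``measures`` for every event in place; returns the events.

    Events referencing samples outside the recording raise an input error.
    """
    evs = _events_of(events)
    fs = fs if fs is not None else clean.fs
    n = clean.n_samples
    acc_h = differentiate(vel_h.samples, fs) if n >= 2 else None
    acc_v = differentiate(vel_v.samples, fs) if n >= 2 else None

    for e in evs:
        if e.offset >= n:
            raise InputError(
                f"event [{e.onset}, {e.offset}] exceeds recording length {n}")
        sl = slice(e.onset, e.offset + 1)
        m = e.measures
        m["duration_s"] = (e.offset - e.onset) / fs

        if e.label == "BLINK":
            m["closing_time_s"] = (e.peak - e.onset) / fs
            m["opening_time_s"] = (e.offset - e.peak) / fs
            # duration restated as the sum so the blink identity
            # closing + opening == duration holds exactly in floats
            # (agrees with (offset - onset)/fs to 1 ulp)
            m["duration_s"] = m["closing_time_s"] + m["opening_time_s"]
            m["peak_velocity_uV_s"] = float(np.max(np.abs(vel_v.samples[sl])))
            m["acceleration_uV_s2"] = float(np.max(acc_v[sl]))
            m["deceleration_uV_s2"] = float(np.min(acc_v[sl]))
            m["amplitude_uV"] = float(clean.eog_v[e.peak] - clean.eog_v[e.onset])
            continue

        if e.label == "OBLIQUE_SACCADE":
            pv_h = float(np.max(np.abs(vel_h.samples[sl])))
            pv_v = float(np.max(np.abs(vel_v.samples[sl])))
            m["peak_velocity_h_uV_s"] = pv_h
            m["peak_velocity_v_uV_s"] = pv_v
            m["peak_velocity_uV_s"] = float(np.hypot(pv_h, pv_v))
            amp_h = clean.eog_h[e.offset] - clean.eog_h[e.onset]
            amp_v = clean.eog_v[e.offset] - clean.eog_v[e.onset]
            dominant = amp_h if abs(amp_h) >= abs(amp_v) else amp_v
            m["amplitude_uV"] = float(abs(dominant))
            acc = acc_h if abs(amp_h) >= abs(amp_v) else acc_v
            m["acceleration_uV_s2"] = float(np.max(acc[sl]))
            m["deceleration_uV_s2"] = float(np.min(acc[sl]))
            continue

        # horizontal saccade, vertical saccade, saccade-with-blink
        if e.label == "VERTICAL_SACCADE":
            vel, pos, acc = vel_v.samples, clean.eog_v, acc_v
        else:
            vel, pos, acc = vel_h.samples, clean.eog_h, acc_h
        m["peak_velocity_uV_s"] = float(np.max(np.abs(vel[sl])))
        m["acceleration_uV_s2"] = float(np.max(acc[sl]))
        m["deceleration_uV_s2"] = float(np.min(acc[sl]))
        m["amplitude_uV"] = float(abs(pos[e.offset] - pos[e.onset]))
    return events


def calibrate_gain(events, reference_events: Sequence[EventRecord],
                   reference_amplitude_deg: float = 10.0) -> CalibrationGain:
    """Estimate the µV/deg gain from reference saccades of known amplitude
    and add ``peak_velocity_deg_s`` to every saccade-class event.

    ``uv_per_deg`` is the mean reference ``amplitude_uV`` divided by the
    reference visual angle (default 10 deg).
    """
    refs = [e for e in reference_events if "amplitude_uV" in e.measures]
    if not refs:
        raise CalibrationError(
            "gain calibration needs at least one reference saccade with "
            "amplitude_uV computed")
    gain = float(np.mean([e.measures["amplitude_uV"] for e in refs])
                 / reference_amplitude_deg)
    if gain <= 0:
        raise CalibrationError("non-positive calibration gain")
    for e in _events_of(events):
        if e.is_saccade and "peak_velocity_uV_s" in e.measures:
            e.measures["peak_velocity_deg_s"] = \
                e.measures["peak_velocity_uV_s"] / gain
    return CalibrationGain(uv_per_deg=gain, n_reference=len(refs),
                           reference_amplitude_deg=reference_amplitude_deg)


def summarize(events, duration_s: float | None = None) -> pd.DataFrame:
    """Per-class summary: count, rate per minute, duration and peak-velocity
    statistics. Undefined statistics (no events, single event SD) are NaN.
    Row order is the fixed class order."""
    evs = _events_of(events)
    rows = []
    for lbl in EVENT_LABELS:
        sel = [e for e in evs if e.label == lbl]
        durs = np.array([e.measures.get("duration_s", np.nan) for e in sel])
        pvs = np.array([e.measures.get("peak_velocity_uV_s", np.nan)
                        for e in sel])
        row = {
            "label": lbl,
            "count": len(sel),
            "rate_per_min": (60.0 * len(sel) / duration_s
                             if duration_s else np.nan),
            "duration_mean_s": float(np.mean(durs)) if len(sel) else np.nan,
            "duration_sd_s": (float(np.std(durs, ddof=1))
                              if len(sel) > 1 else np.nan),
            "peak_velocity_mean_uV_s": (float(np.nanmean(pvs))
                                        if np.isfinite(pvs).any() else np.nan),
            "peak_velocity_sd_uV_s": (float(np.nanstd(pvs, ddof=1))
                                      if np.isfinite(pvs).sum() > 1 else np.nan),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")
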