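"""Bounded peak detection and extraction of saccade and blink candidates.

A *bounded peak* is a local extremum whose absolute value exceeds the
channel's threshold, together with a left bound (LB) and right bound (RB):
the nearest samples on either side where the absolute signal falls to the
*bound level*, a fixed fraction (default 10%) of the peak amplitude. The
right-hand search terminates when (1) the bound level is reached, (2) a
larger same-polarity sample is met — in which case the peak is *promoted*
to the larger extremum and the search continues, which is what lets a
double-peaked blink be captured as one event — or (3) the maximum peak
duration is exceeded, in which case the peak is discarded.

Saccade candidates are bounded peaks of the velocity signals. Blinks are
recognized on the vertical channel as an adjacent positive-then-negative
velocity peak pair (lid closing then reopening) within the maximum blink
duration, whose intervening positional EOG_v peak exceeds the blink
amplitude threshold; the constituent vertical velocity candidates are then
consumed by the blink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autocalib import ThresholdSet, collect_peak_amplitudes
from .exceptions import InputError
from .preprocess import VelocitySignal


@dataclass
class BoundedPeak:
    """A detected peak with its 10%-amplitude boundaries (sample indices)."""

    peak_index: int
    lb: int
    rb: int
    polarity: int
    peak_value: float
    bound_level: float
    source: str = ""

    @property
    def span(self) -> int:
        return self.rb - self.lb


@dataclass
class SaccadeCandidate:
    """A bounded velocity peak on one axis, candidate saccade."""

    axis: str  # "h" or "v"
    peak: BoundedPeak
    direction_sign: int


@dataclass
class BlinkCandidate:
    """An up-then-down vertical velocity pair with its positional peak."""

    up_peak: BoundedPeak
    down_peak: BoundedPeak
    v_peak: BoundedPeak  # bounded peak on positional EOG_v
    onset: int
    offset: int

    @property
    def peak_index(self) -> int:
        return self.v_peak.peak_index


def _local_max_indices(absx: np.ndarray) -> np.ndarray:
    """Leftmost-sample indices of (plateau-aware) local maxima of absx."""
    d = np.diff(absx)
    nz = np.flatnonzero(d)
    if len(nz) < 2:
        return np.empty(0, dtype=int)
    signs = np.sign(d[nz])
    starts = nz + 1
    is_max = (signs[:-1] > 0) & (signs[1:] < 0)
    return starts[:-1][is_max]


def find_bounded_peaks(samples, fs: float, threshold: float,
                       bound_frac: float = 0.10,
                       max_peak_duration_s: float = 0.80,
                       source: str = "") -> list[BoundedPeak]:
    """Locate all above-threshold bounded peaks in a signal.

    Peaks whose LB or RB cannot be found within the maximum duration are
    discarded; overlapping accepted peaks of the same polarity are merged
    (larger peak kept, span unioned when it fits the duration cap).
    Output is sorted by peak index.
    """
    x = np.asarray(samples, dtype=float)
    if threshold <= 0:
        raise InputError(f"threshold must be positive, got {threshold}")
    absx = np.abs(x)
    max_span = int(round(max_peak_duration_s * fs))
    n = len(x)
    peaks: list[BoundedPeak] = []
    last_rb = {-1: -1, 1: -1}

    for p0 in _local_max_indices(absx):
        if absx[p0] <= threshold:
            continue
        pol = 1 if x[p0] >= 0 else -1
        if p0 <= last_rb[pol]:
            continue  # already absorbed by a previous accepted peak
        peak_i = int(p0)
        peak_abs = absx[p0]
        bound = bound_frac * peak_abs

        # left bound: first sample at-or-below the bound level; a "crossing"
        # at the very first sample of the recording does not count (the
        # signal may simply run out before reaching the bound level)
        lb = -1
        lo = max(1, peak_i - max_span)
        for j in range(peak_i - 1, lo - 1, -1):
            if absx[j] <= bound:
                lb = j
                break
        if lb < 0:
            continue

        # right bound, with same-polarity peak promotion; terminal sample
        # excluded for the same reason as the left edge
        rb = -1
        j = peak_i + 1
        limit = min(lb + max_span, n - 2)
        while j <= limit:
            if absx[j] > peak_abs and (1 if x[j] >= 0 else -1) == pol:
                peak_i = j
                peak_abs = absx[j]
                bound = bound_frac * peak_abs
            elif absx[j] <= bound:
                rb = j
                break
            j += 1
        if rb < 0:
            continue

        peaks.append(BoundedPeak(peak_index=peak_i, lb=lb, rb=rb, polarity=pol,
                                 peak_value=float(x[peak_i]),
                                 bound_level=float(bound), source=source))
        last_rb[pol] = rb

    return _merge_overlapping(sorted(peaks, key=lambda p: p.peak_index),
                              max_span)


def _merge_overlapping(peaks: list[BoundedPeak],
                       max_span: int) -> list[BoundedPeak]:
    """Merge overlapping same-polarity peaks, keeping the larger one.

    Repeated until a fixpoint: a wide peak can bridge several earlier ones,
    so a single pass is not enough.
    """
    current = sorted(peaks, key=lambda p: p.peak_index)
    while True:
        merged: list[BoundedPeak] = []
        changed = False
        for pk in current:
            hit = next((i for i in range(len(merged) - 1, -1, -1)
                        if merged[i].polarity == pk.polarity
                        and pk.lb < merged[i].rb and merged[i].lb < pk.rb),
                       None)
            if hit is None:
                merged.append(pk)
                continue
            prev = merged[hit]
            big = prev if abs(prev.peak_value) >= abs(pk.peak_value) else pk
            lb, rb = min(prev.lb, pk.lb), max(prev.rb, pk.rb)
            if rb - lb > max_span:
                lb, rb = big.lb, big.rb  # union too long: keep larger alone
            merged[hit] = BoundedPeak(
                peak_index=big.peak_index, lb=lb, rb=rb, polarity=big.polarity,
                peak_value=big.peak_value, bound_level=big.bound_level,
                source=big.source)
            changed = True
        current = sorted(merged, key=lambda p: p.peak_index)
        if not changed:
            return current


def extract_saccade_candidates(vel: VelocitySignal, threshold: float,
                               bound_frac: float = 0.10,
                               max_peak_duration_s: float = 0.80,
                               ) -> list[SaccadeCandidate]:
    """One saccade candidate per bounded peak of the velocity signal."""
    peaks = find_bounded_peaks(vel.samples, vel.fs, threshold,
                               bound_frac=bound_frac,
                               max_peak_duration_s=max_peak_duration_s,
                               source=f"{vel.source}_vel")
    return [SaccadeCandidate(axis=vel.source, peak=p, direction_sign=p.polarity)
            for p in peaks]


def detect_blinks(eog_v, vel_v: VelocitySignal, thresholds: ThresholdSet,
                  fs: float, max_blink_duration_s: float = 1.2,
                  bound_frac: float = 0.10,
                  max_peak_duration_s: float = 0.80,
                  v_candidates: list[SaccadeCandidate] | None = None,
                  ) -> tuple[list[BlinkCandidate], list[SaccadeCandidate]]:
    """Separate blinks from vertical saccade candidates.

    Each negative vertical velocity peak is paired with the nearest preceding
    positive peak with no other positive peak in between (an adjacent
    up-and-down pattern); if the pair lies within the maximum blink duration
    and an EOG_v positional peak above the blink threshold sits between the
    two velocity peaks, a blink is emitted (onset/offset = LB/RB of the
    positional peak) and both velocity candidates are consumed. Anything
    unpaired survives as a vertical saccade candidate.
    """
    if v_candidates is None:
        v_candidates = extract_saccade_candidates(
            vel_v, thresholds.v_saccade, bound_frac=bound_frac,
            max_peak_duration_s=max_peak_duration_s)
    v_candidates = sorted(v_candidates, key=lambda c: c.peak.peak_index)

    pos_peaks = [p for p in find_bounded_peaks(
        eog_v, fs, thresholds.blink, bound_frac=bound_frac,
        max_peak_duration_s=max_blink_duration_s, source="v_pos")
        if p.polarity > 0]

    window = int(round(max_blink_duration_s * fs))
    used = [False] * len(v_candidates)
    pos_used = [False] * len(pos_peaks)
    blinks: list[BlinkCandidate] = []

    for i, cand in enumerate(v_candidates):
        if cand.peak.polarity >= 0 or used[i]:
            continue
        down = cand.peak
        # nearest preceding unused positive peak, adjacent (no +peak between)
        up_idx = None
        for j in range(i - 1, -1, -1):
            if used[j]:
                continue
            if v_candidates[j].peak.polarity > 0:
                up_idx = j
            break
        if up_idx is None:
            continue
        up = v_candidates[up_idx].peak
        if down.peak_index - up.peak_index > window:
            continue
        v_peak = None
        for k, pp in enumerate(pos_peaks):
            if pos_used[k]:
                continue
            if up.peak_index <= pp.peak_index <= down.peak_index:
                v_peak = pp
                pos_used[k] = True
                break
        if v_peak is None:
            continue
        blinks.append(BlinkCandidate(up_peak=up, down_peak=down, v_peak=v_peak,
                                     onset=v_peak.lb, offset=v_peak.rb))
        used[i] = True
        used[up_idx] = True

    surviving = [c for i, c in enumerate(v_candidates) if not used[i]]
    return blinks, surviving


__all__ = [
    "BoundedPeak", "SaccadeCandidate", "BlinkCandidate",
    "find_bounded_peaks", "extract_saccade_candidates", "detect_blinks",
    "collect_peak_amplitudes",
]
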