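"""Event classification and physiological duration filtering.

Every extracted feature is assigned to exactly one of five classes:

* ``HORIZONTAL_SACCADE`` — bounded peak on the horizontal velocity only;
* ``VERTICAL_SACCADE`` — bounded peak on the vertical velocity only;
* ``OBLIQUE_SACCADE`` — simultaneous horizontal and vertical saccade
  (their bounded intervals overlap); the event spans the union;
* ``BLINK`` — an up-and-down vertical velocity pair with a supra-threshold
  positional peak;
* ``SACCADE_WITH_BLINK`` — a horizontal saccade coexisting with a blink.

Blink coexistence takes precedence over obliqueness for a horizontal
candidate overlapping both (the vertical lobe inside a blink has normally
been consumed by blink extraction already).

The optional duration filter keeps only saccades with physiologically
plausible durations (default 30–80 ms, inclusive): genuine saccades up to
~15 deg fall in this window, while shorter detections are mostly noise
spikes and longer ones drifts or fused movements. An optional minimum blink
duration can likewise reject spuriously short blinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import BlinkCandidate, SaccadeCandidate
from .exceptions import ConfigError, EOGError
from .io import EVENT_LABELS, SACCADE_LABELS, EventRecord


@dataclass
class ClassifiedEvents:
    """Events sorted by onset plus per-class counts."""

    events: list[EventRecord]
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset, e.offset))
        self.counts = {lbl: sum(e.label == lbl for e in self.events)
                       for lbl in EVENT_LABELS}

    def __len__(self) -> int:
        return len(self.events)


def _check_no_overlap(cands: list[SaccadeCandidate], axis: str) -> None:
    ordered = sorted(cands, key=lambda c: c.peak.lb)
    for a, b in zip(ordered, ordered[1:]):
        if b.peak.lb < a.peak.rb and a.peak.polarity == b.peak.polarity:
            raise EOGError(
                f"internal error: overlapping same-polarity candidates on the "
                f"{axis} axis (detect should have merged them)")


def _overlap(lo1, hi1, lo2, hi2, min_samples: int) -> bool:
    return min(hi1, hi2) - max(lo1, lo2) + 1 >= min_samples


def classify_events(h: list[SaccadeCandidate], v: list[SaccadeCandidate],
                    blinks: list[BlinkCandidate], fs: float,
                    overlap_min_s: float = 0.0) -> ClassifiedEvents:
    """Assign each candidate to one of the five classes.

    Every input candidate is consumed exactly once; horizontal+vertical pairs
    whose intervals overlap merge into one oblique event spanning the union.
    ``overlap_min_s`` optionally demands more than the default single sample
    of overlap for simultaneity.
    """
    _check_no_overlap(h, "h")
    _check_no_overlap(v, "v")
    min_ov = max(1, int(round(overlap_min_s * fs)))
    events: list[EventRecord] = []

    blink_events = [EventRecord("BLINK", onset=b.onset, offset=b.offset,
                                peak=b.peak_index, direction_sign=1)
                    for b in blinks]
    events.extend(blink_events)

    v_used = [False] * len(v)
    for hc in h:
        hp = hc.peak
        coexists = any(_overlap(hp.lb, hp.rb, b.onset, b.offset, min_ov)
                       for b in blink_events)
        if coexists:
            events.append(EventRecord("SACCADE_WITH_BLINK", onset=hp.lb,
                                      offset=hp.rb, peak=hp.peak_index,
                                      direction_sign=hc.direction_sign))
            continue
        partner = None
        for j, vc in enumerate(v):
            if not v_used[j] and _overlap(hp.lb, hp.rb, vc.peak.lb,
                                          vc.peak.rb, min_ov):
                partner = j
                break
        if partner is not None:
            vp = v[partner].peak
            v_used[partner] = True
            onset, offset = min(hp.lb, vp.lb), max(hp.rb, vp.rb)
            peak = hp.peak_index if abs(hp.peak_value) >= abs(vp.peak_value) \
                else vp.peak_index
            events.append(EventRecord(
                "OBLIQUE_SACCADE", onset=onset, offset=offset, peak=peak,
                direction_sign=hc.direction_sign,
                measures={"_h_peak": hp.peak_index, "_v_peak": vp.peak_index}))
        else:
            events.append(EventRecord("HORIZONTAL_SACCADE", onset=hp.lb,
                                      offset=hp.rb, peak=hp.peak_index,
                                      direction_sign=hc.direction_sign))
    for j, vc in enumerate(v):
        if not v_used[j]:
            vp = vc.peak
            events.append(EventRecord("VERTICAL_SACCADE", onset=vp.lb,
                                      offset=vp.rb, peak=vp.peak_index,
                                      direction_sign=vc.direction_sign))
    return ClassifiedEvents(events=events)


def apply_duration_filters(classified: ClassifiedEvents, fs: float,
                           saccade_min_s: float = 0.030,
                           saccade_max_s: float = 0.080,
                           blink_min_s: float | None = None,
                           ) -> ClassifiedEvents:
    """Remove saccades outside the duration window (bounds inclusive) and,
    when ``blink_min_s`` is given, blinks shorter than it.

    Pure saccades (horizontal/vertical/oblique) are filtered; blink-coupled
    saccade events are exempt since their span is blink-dominated. The
    operation is idempotent.
    """
    if saccade_min_s > saccade_max_s:
        raise ConfigError(
            f"saccade_min_s ({saccade_min_s}) exceeds saccade_max_s "
            f"({saccade_max_s})")
    kept = []
    for e in classified.events:
        dur = e.duration_s(fs)
        if e.label in SACCADE_LABELS and not (
                saccade_min_s <= dur <= saccade_max_s):
            continue
        if (blink_min_s is not None and e.label == "BLINK"
                and dur < blink_min_s):
            continue
        kept.append(e)
    return ClassifiedEvents(events=kept)
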