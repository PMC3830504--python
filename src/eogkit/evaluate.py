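"""Detector-vs-reference event matching and performance scoring.

Detected events are matched one-to-one against reference (ground-truth)
events by nearest peak time within a tolerance (default 100 ms), greedily
from the closest pair outward. Matching is class-agnostic — detection and
classification are scored in two stages: a matched pair is a true positive
regardless of label, and classification quality is then read off the 5×5
confusion matrix of matched pairs.

* sensitivity = tp / (tp + fn) — fraction of reference events found;
* fp_rate = fp / (tp + fp) — fraction of detections that match nothing
  (a false-discovery fraction; the natural reading of a "false positive
  rate" when no true-negative count exists for events in continuous time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import EVENT_LABELS, EventRecord


@dataclass
class MatchResult:
    """One-to-one matching of detected against reference events."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]]  # (detected index, truth index)
    confusion: pd.DataFrame       # truth label (rows) × detected label (cols)

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def fp_rate(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else float("nan")


def match_events(detected: Sequence[EventRecord],
                 truth: Sequence[EventRecord], fs: float,
                 tolerance_s: float = 0.1) -> MatchResult:
    """Greedy nearest-peak one-to-one matching within ``tolerance_s``.

    Pairs are accepted in order of increasing peak-time distance; ties break
    toward the earlier truth event. Every detected and every truth event is
    used at most once.
    """
    if tolerance_s < 0:
        raise InputError(f"tolerance must be non-negative, got {tolerance_s}")
    detected = list(detected)
    truth = list(truth)
    tol = tolerance_s * fs

    cand = []
    for i, d in enumerate(detected):
        for j, t in enumerate(truth):
            dist = abs(d.peak - t.peak)
            if dist <= tol:
                cand.append((dist, t.onset, d.onset, i, j))
    cand.sort()

    d_used = [False] * len(detected)
    t_used = [False] * len(truth)
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in cand:
        if not d_used[i] and not t_used[j]:
            d_used[i] = True
            t_used[j] = True
            pairs.append((i, j))
    pairs.sort(key=lambda p: detected[p[0]].onset)

    confusion = pd.DataFrame(0, index=list(EVENT_LABELS),
                             columns=list(EVENT_LABELS))
    for i, j in pairs:
        confusion.loc[truth[j].label, detected[i].label] += 1

    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp,
                       pairs=pairs, confusion=confusion)


def classification_sensitivity(result: MatchResult,
                               label: str) -> float | None:
    """Among matched pairs whose truth label is ``label``, the fraction
    classified as ``label``; None when no such pair exists."""
    row = result.confusion.loc[label]
    total = int(row.sum())
    if total == 0:
        return None
    return float(row[label]) / total


@dataclass
class DetectionScore:
    """Benchmark-style detection score against ground truth.

    Saccade sensitivity is computed over truth saccades inside the duration
    window (when one is given), mirroring the two-sided windowing used when
    a reference detector's events are duration-filtered as well; the false
    positive fraction counts detections matching *no* truth event at all.
    """

    saccade_sensitivity: float
    blink_sensitivity: float
    fp_rate: float
    match: MatchResult


def score_detection(detected: Sequence[EventRecord],
                    truth: Sequence[EventRecord], fs: float,
                    tolerance_s: float = 0.1,
                    saccade_window_s: tuple[float, float] | None = None,
                    ) -> DetectionScore:
    """Score detections against ground truth, optionally restricting truth
    saccades to a duration window (e.g. (0.030, 0.080))."""
    truth = list(truth)
    result = match_events(detected, truth, fs, tolerance_s=tolerance_s)
    matched_truth = {j for _, j in result.pairs}

    def in_window(e: EventRecord) -> bool:
        if saccade_window_s is None:
            return True
        lo, hi = saccade_window_s
        return lo <= e.measures.get("duration_s", e.duration_s(fs)) <= hi

    sacc_idx = [j for j, t in enumerate(truth)
                if t.label != "BLINK" and in_window(t)]
    blink_idx = [j for j, t in enumerate(truth) if t.label == "BLINK"]
    sacc_sens = (sum(j in matched_truth for j in sacc_idx) / len(sacc_idx)
                 if sacc_idx else float("nan"))
    blink_sens = (sum(j in matched_truth for j in blink_idx) / len(blink_idx)
                  if blink_idx else float("nan"))
    return DetectionScore(saccade_sensitivity=sacc_sens,
                          blink_sensitivity=blink_sens,
                          fp_rate=result.fp_rate, match=result)


def per_class_sensitivity(detected: Sequence[EventRecord],
                          truth: Sequence[EventRecord], fs: float,
                          result: MatchResult,
                          label_group: Sequence[str]) -> float:
    """Detection sensitivity restricted to truth events of the given classes
    (matched by any detection, regardless of the detected label)."""
    truth = list(truth)
    in_group = [j for j, t in enumerate(truth) if t.label in label_group]
    if not in_group:
        return float("nan")
    matched = {j for _, j in result.pairs}
    return sum(j in matched for j in in_group) / len(in_group)
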