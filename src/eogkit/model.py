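"""The model/results surface tying the pipeline together.

:class:`EOGModel` wraps a :class:`~eogkit.io.Recording` and a
:class:`~eogkit.config.PipelineConfig`; ``fit()`` runs preprocessing,
auto-calibration, detection and classification and returns an
:class:`EOGResults` carrying the estimated thresholds, the classified
events with their kinematic measures, per-stage diagnostics and a
``summary()`` table.

    >>> from eogkit import EOGModel, synthetic
    >>> rec, truth = synthetic.generate(synthetic.SimConfig(seed=1))
    >>> res = EOGModel(rec).fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autocalib, classify, detect, io, metrics, preprocess
from .config import PipelineConfig
from .exceptions import InputError


class EOGModel:
    """Auto-calibrating saccade/blink detector for one EOG recording.

    Parameters
    ----------
    recording : Recording
        Two-channel EOG in µV with its sampling rate.
    config : PipelineConfig, optional
        Pipeline tunables; defaults are the standard values (degree-20
        baseline, 100 Hz wavelet cutoff, 0.03 outlier delta, 2% pivot
        margin, 10% bound, 0.80 s max peak, 1.2 s max blink).
    """

    def __init__(self, recording: io.Recording,
                 config: PipelineConfig | None = None):
        if not isinstance(recording, io.Recording):
            raise InputError("EOGModel expects a Recording")
        self.recording = recording
        self.config = config or PipelineConfig()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fs: float,
                       channel_map: dict | None = None,
                       config: PipelineConfig | None = None) -> "EOGModel":
        """Build from a DataFrame with eog_h/eog_v columns (or the four
        monopolar right/left/up/down columns)."""
        rec = io._recording_from_columns(df, fs, channel_map, "dataframe")
        return cls(rec, config=config)

    @classmethod
    def from_monopolar(cls, right, left, up, down, fs: float,
                       config: PipelineConfig | None = None) -> "EOGModel":
        """Build from four monopolar electrode channels (bipolar derivation)."""
        return cls(io.derive_bipolar(right, left, up, down, fs), config=config)

    @classmethod
    def from_file(cls, path, format: str | None = None, fs: float | None = None,
                  channel_map: dict | None = None,
                  config: PipelineConfig | None = None) -> "EOGModel":
        return cls(io.read_recording(path, format=format, fs=fs,
                                     channel_map=channel_map), config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self, filters: bool | None = None) -> "EOGResults":
        """Run the full pipeline and return the results.

        ``filters`` overrides ``config.filters_enabled`` (the physiological
        30–80 ms saccade-duration filter; off by default in the library).
        """
        cfg = self.config
        rec = self.recording
        pre = preprocess.preprocess_recording(
            rec, degree=cfg.baseline_degree, cutoff_hz=cfg.denoise_cutoff_hz)

        calib_details: dict = {}
        thresholds = autocalib.estimate_thresholds(
            pre.clean, pre.vel_h, pre.vel_v,
            outlier_delta=cfg.calib_outlier_delta,
            pivot_margin=cfg.calib_pivot_margin,
            n_min=cfg.calib_n_min, min_peaks=cfg.calib_min_peaks,
            blink_use_abs=cfg.calib_blink_use_abs,
            rescale_after_trim=cfg.calib_rescale_after_trim,
            details=calib_details)

        h_cands = detect.extract_saccade_candidates(
            pre.vel_h, thresholds.h_saccade, bound_frac=cfg.detect_bound_frac,
            max_peak_duration_s=cfg.detect_max_peak_duration_s)
        v_cands = detect.extract_saccade_candidates(
            pre.vel_v, thresholds.v_saccade, bound_frac=cfg.detect_bound_frac,
            max_peak_duration_s=cfg.detect_max_peak_duration_s)
        # the polynomial baseline is least reliable at the recording edges
        # (maximal least-squares variance there); candidates inside the edge
        # margin ride on untrustworthy detrending and are discarded
        margin = int(round(cfg.detect_edge_margin_s * rec.fs))
        lo, hi = margin, rec.n_samples - 1 - margin

        def inside(peak):
            return peak.lb >= lo and peak.rb <= hi
        h_cands = [c for c in h_cands if inside(c.peak)]
        v_cands = [c for c in v_cands if inside(c.peak)]
        blinks, v_cands = detect.detect_blinks(
            pre.clean.eog_v, pre.vel_v, thresholds, rec.fs,
            max_blink_duration_s=cfg.detect_max_blink_duration_s,
            bound_frac=cfg.detect_bound_frac,
            max_peak_duration_s=cfg.detect_max_peak_duration_s,
            v_candidates=v_cands)

        classified = classify.classify_events(
            h_cands, v_cands, blinks, rec.fs,
            overlap_min_s=cfg.detect_overlap_min_s)
        stage_counts = {"h_candidates": len(h_cands),
                        "v_candidates": len(v_cands),
                        "blink_candidates": len(blinks),
                        "classified": len(classified)}

        use_filters = cfg.filters_enabled if filters is None else filters
        if use_filters:
            classified = classify.apply_duration_filters(
                classified, rec.fs,
                saccade_min_s=cfg.filters_saccade_min_s,
                saccade_max_s=cfg.filters_saccade_max_s,
                blink_min_s=cfg.filters_blink_min_s)
        stage_counts["filtered"] = len(classified)

        metrics.compute_measures(classified, pre.clean, pre.vel_h, pre.vel_v)
        return EOGResults(model=self, preprocessed=pre, thresholds=thresholds,
                          calib_details=calib_details, classified=classified,
                          stage_counts=stage_counts,
                          filters_applied=bool(use_filters))


@dataclass
class EOGResults:
    """Fitted detection results for one recording."""

    model: EOGModel
    preprocessed: preprocess.Preprocessed
    thresholds: autocalib.ThresholdSet
    calib_details: dict
    classified: classify.ClassifiedEvents
    stage_counts: dict
    filters_applied: bool
    gain: metrics.CalibrationGain | None = field(default=None)

    @property
    def events(self) -> list[io.EventRecord]:
        return self.classified.events

    @property
    def counts(self) -> dict:
        return self.classified.counts

    @property
    def fs(self) -> float:
        return self.model.recording.fs

    def event_frame(self) -> pd.DataFrame:
        """Events and measures as a tidy DataFrame (times in seconds)."""
        return io.events_to_frame(self.events, self.fs)

    def summary_frame(self) -> pd.DataFrame:
        """Per-class counts/rates/kinematics table."""
        return metrics.summarize(self.classified,
                                 duration_s=self.model.recording.duration_s)

    def calibrate_gain(self, reference_events,
                       reference_amplitude_deg: float = 10.0
                       ) -> metrics.CalibrationGain:
        """Attach deg/s velocities using caller-supplied reference saccades."""
        self.gain = metrics.calibrate_gain(
            self.classified, reference_events,
            reference_amplitude_deg=reference_amplitude_deg)
        return self.gain

    def to_tsv(self, path) -> None:
        io.write_events(self.events, path, self.fs)

    def summary(self) -> str:
        """Human-readable report: thresholds, stage counts, per-class table."""
        rec = self.model.recording
        lines = [
            "            Auto-calibrating EOG event detection",
            "=" * 64,
            f"Samples: {rec.n_samples}   fs: {rec.fs:g} Hz   "
            f"duration: {rec.duration_s:.1f} s",
            f"Baseline R² (h/v): {self.preprocessed.baseline_h.r_squared:.3f}"
            f" / {self.preprocessed.baseline_v.r_squared:.3f}",
            "",
            "Estimated amplitude thresholds",
            f"  horizontal saccade : {self.thresholds.h_saccade:10.1f} µV/s",
            f"  vertical saccade   : {self.thresholds.v_saccade:10.1f} µV/s",
            f"  blink              : {self.thresholds.blink:10.1f} µV",
            "",
            f"Duration filters applied: {self.filters_applied}",
            f"Stage counts: {self.stage_counts}",
            "",
            self.summary_frame().to_string(),
        ]
        if self.gain is not None:
            lines.insert(-1, f"Gain: {self.gain.uv_per_deg:.2f} µV/deg "
                             f"(n={self.gain.n_reference} references)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot both channels with detected events shaded (diagnostics)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 4))
        rec = self.preprocessed.clean
        t = np.arange(rec.n_samples) / rec.fs
        ax.plot(t, rec.eog_h, lw=0.6, label="EOG_h (clean)", color="tab:blue")
        ax.plot(t, rec.eog_v, lw=0.6, label="EOG_v (clean)", color="tab:red")
        for e in self.events:
            ax.axvspan(e.onset / rec.fs, e.offset / rec.fs, alpha=0.2,
                       color="gray")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("amplitude (µV)")
        ax.legend(loc="upper right", fontsize=8)
        return ax
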