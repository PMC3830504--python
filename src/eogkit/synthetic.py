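"""Ground-truth-annotated synthetic EOG recordings.

The generator emulates a 500 Hz DC-coupled two-channel EOG recording of a
subject performing a center-out saccade task: each *trial* is an outward
saccade to one of eight directions (0°–315°) at one of four amplitudes
(2.5–10 deg of visual angle), a fixation dwell on the target, and a return
saccade to center; voluntary blinks occur in the center-gaze gaps between
trials, as instructed blink pauses do in laboratory recordings. On top of
the eye movements the recording carries slow baseline drift (a few
sinusoids below ~0.05 Hz), broadband white noise, powerline interference,
and optionally sparse 1–3-sample high-amplitude artifacts.

Saccade position profiles are logistic (sigmoid) steps: the logistic has a
closed-form velocity pulse ``v(t) = A·k·σ(kt)(1−σ(kt))`` whose width at 10%
of its maximum — the same bound level the detector uses — can be set
exactly, so ground-truth durations follow the empirical main sequence
(37 ms at 2.5 deg up to 55 ms at 10 deg, linearly interpolated in between,
with optional Gaussian jitter mimicking natural variability). The analytic
peak velocity is ``A·k/4`` and grows monotonically with amplitude, matching
the main-sequence trend. Blinks are asymmetric raised-cosine pulses on the
vertical channel (closing faster than reopening).

Every injected event is recorded in a :class:`GroundTruth` table with its
class, sample indices, amplitude, direction and analytic kinematics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, InputError
from .io import EventRecord, Recording

#: logit of the upper 10%-crossing of the logistic velocity pulse:
#: 4·σ(1−σ) = 0.1  ⇒  σ = (1+√0.9)/2,  kt = ln(σ/(1−σ))
_LOGIT_10 = math.log((1 + math.sqrt(0.9)) / (1 - math.sqrt(0.9)))  # ≈ 3.6369

#: empirical main-sequence durations (ms) and their spreads per amplitude (deg)
MAIN_SEQUENCE_AMP_DEG = (2.5, 5.0, 7.5, 10.0)
MAIN_SEQUENCE_DURATION_MS = (37.0, 45.0, 51.0, 55.0)
MAIN_SEQUENCE_DURATION_SD_MS = (13.0, 10.0, 7.0, 12.0)


@dataclass
class SimConfig:
    """Conditions of a simulated recording.

    Defaults mirror a ~1-minute laboratory saccade-task recording: 500 Hz
    sampling, 40 saccades (20 out-and-return trials) drawn from the task's
    amplitude/direction grid, 15 blinks of ~300 µV, ~200 µV slow drift,
    0.5 µV broadband noise, 0.5 µV of 50 Hz powerline pickup and a couple of
    large movement artifacts. A 13 µV/deg electro-oculographic gain sits in
    the middle of the commonly cited 10–20 µV/deg range.
    """

    fs: float = 500.0
    duration_s: float = 60.0
    n_saccades: int = 40
    saccade_amplitudes_deg: tuple = MAIN_SEQUENCE_AMP_DEG
    directions_deg: tuple = (0, 45, 90, 135, 180, 225, 270, 315)
    n_blinks: int = 15
    gain_uv_per_deg: float = 13.0
    #: relative sensitivity of the vertical channel to eye rotation; real
    #: vertical EOG is often weaker than horizontal (1.0 = symmetric)
    v_gain_factor: float = 1.0
    drift_amplitude_uV: float = 200.0
    drift_max_freq_hz: float = 0.05
    noise_white_sd_uV: float = 0.5
    powerline_amp_uV: float = 0.5
    powerline_hz: float = 50.0
    n_artifacts: int = 2
    blink_amplitude_uV: float = 300.0
    blink_amplitude_jitter_uV: float = 50.0
    blink_duration_range_s: tuple = (0.20, 0.30)
    blink_asymmetry: float = 0.4
    duration_jitter: bool = True
    dwell_range_s: tuple = (1.25, 1.35)
    gap_range_s: tuple = (0.30, 0.50)
    blink_gap_range_s: tuple = (1.25, 1.45)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if self.n_saccades < 0 or self.n_blinks < 0 or self.n_artifacts < 0:
            raise ConfigError("event counts must be non-negative")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")


@dataclass
class GroundTruth:
    """The injected events, with true class, indices and kinematics."""

    events: list[EventRecord] = field(default_factory=list)

    def saccades(self) -> list[EventRecord]:
        return [e for e in self.events if e.label != "BLINK"]

    def blinks(self) -> list[EventRecord]:
        return [e for e in self.events if e.label == "BLINK"]


def main_sequence_duration_s(amplitude_deg: float) -> float:
    """Main-sequence saccade duration (s), linearly interpolated."""
    return float(np.interp(amplitude_deg, MAIN_SEQUENCE_AMP_DEG,
                           MAIN_SEQUENCE_DURATION_MS)) / 1000.0


def saccade_waveform(amplitude_deg: float, direction_deg: float, fs: float,
                     gain: float = 13.0, duration_s: float | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Logistic-step saccade position profiles for both channels.

    Returns ``(h_pulse, v_pulse, duration_s)`` where the pulses rise from
    exactly 0 to the full step (``amplitude·gain·cosθ`` horizontally,
    ``·sinθ`` vertically) over a window of four durations, and
    ``duration_s`` is the width of the velocity pulse at 10% of its maximum.
    """
    if amplitude_deg <= 0:
        raise InputError(f"amplitude must be positive, got {amplitude_deg}")
    if duration_s is None:
        duration_s = main_sequence_duration_s(amplitude_deg)
    k = 2.0 * _LOGIT_10 / duration_s
    half = 2.0 * duration_s
    t = np.arange(-half, half, 1.0 / fs)
    sig = 1.0 / (1.0 + np.exp(-k * t))
    lo, hi = sig[0], sig[-1]
    profile = (sig - lo) / (hi - lo)  # exact 0 → 1, no splice discontinuity
    theta = math.radians(direction_deg)
    amp_uv = amplitude_deg * gain
    return (amp_uv * math.cos(theta) * profile,
            amp_uv * math.sin(theta) * profile, duration_s)


def saccade_peak_velocity_uv_s(amplitude_deg: float, gain: float,
                               duration_s: float) -> float:
    """Analytic maximum of the logistic velocity pulse, in µV/s (vector
    magnitude across both channels)."""
    k = 2.0 * _LOGIT_10 / duration_s
    return amplitude_deg * gain * k / 4.0


def blink_waveform(amplitude_uV: float, duration_s: float,
                   asymmetry: float = 0.4, fs: float = 500.0) -> np.ndarray:
    """Asymmetric raised-cosine blink pulse (positive, vertical channel).

    ``asymmetry`` is the closing fraction of the total duration: the rising
    (lid closing) half-cosine lasts ``asymmetry·duration`` and the falling
    (reopening) one the rest, so closing is faster than opening for
    asymmetry < 0.5.
    """
    if not (0.1 <= duration_s <= 1.0):
        raise InputError(
            f"blink duration must lie in [0.1, 1.0] s, got {duration_s}")
    if not (0.0 < asymmetry < 1.0):
        raise InputError(f"asymmetry must lie in (0, 1), got {asymmetry}")
    n = max(3, int(round(duration_s * fs)))
    n_rise = max(1, int(round(asymmetry * n)))
    t_rise = np.arange(n_rise) / n_rise
    t_fall = np.arange(n - n_rise) / max(1, n - n_rise - 1)
    rise = 0.5 * (1 - np.cos(np.pi * t_rise))
    fall = 0.5 * (1 + np.cos(np.pi * np.clip(t_fall, 0, 1)))
    pulse = np.concatenate([rise, fall])
    return amplitude_uV * pulse


def _truth_saccade(label, center, duration_s, fs, amplitude_deg,
                   direction_deg, gain, sign_h, sign_v,
                   v_factor: float = 1.0) -> EventRecord:
    half_w = duration_s * fs / 2.0
    onset = int(round(center - half_w))
    offset = int(round(center + half_w))
    vmax = saccade_peak_velocity_uv_s(amplitude_deg, gain, duration_s)
    theta = math.radians(direction_deg)
    sign = sign_h if label != "VERTICAL_SACCADE" else sign_v
    return EventRecord(
        label=label, onset=onset, offset=offset, peak=int(center),
        direction_sign=sign if sign != 0 else 1,
        measures={
            "amplitude_deg": amplitude_deg,
            "direction_deg": direction_deg,
            "duration_s": duration_s,
            "peak_velocity_uV_s": vmax,
            "peak_velocity_h_uV_s": abs(vmax * math.cos(theta)),
            "peak_velocity_v_uV_s": abs(vmax * math.sin(theta)) * v_factor,
            "amplitude_uV": amplitude_deg * gain,
        })


def _classify_direction(direction_deg: float) -> str:
    d = direction_deg % 360
    if d in (0.0, 180.0):
        return "HORIZONTAL_SACCADE"
    if d in (90.0, 270.0):
        return "VERTICAL_SACCADE"
    return "OBLIQUE_SACCADE"


def generate(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate a recording plus ground truth; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    h = np.zeros(n)
    v = np.zeros(n)
    truth = GroundTruth()

    n_trials = (config.n_saccades + 1) // 2
    blink_slots: dict[int, int] = {}
    if config.n_blinks and config.n_saccades:
        replace = config.n_blinks > n_trials
        chosen = rng.choice(n_trials, size=config.n_blinks, replace=replace)
        for s in chosen:
            blink_slots[int(s)] = blink_slots.get(int(s), 0) + 1

    def add_step(center_idx, amplitude_deg, direction_deg, duration_s):
        ph, pv, dur = saccade_waveform(amplitude_deg, direction_deg, fs,
                                       gain=config.gain_uv_per_deg,
                                       duration_s=duration_s)
        pv = pv * config.v_gain_factor
        w = len(ph)
        start = center_idx - w // 2
        if start < 0 or start + w > n:
            raise ConfigError("event placement exceeds recording bounds")
        h[start:start + w] += ph
        v[start:start + w] += pv
        h[start + w:] += ph[-1]
        v[start + w:] += pv[-1]

    def draw_duration(amp):
        base = main_sequence_duration_s(amp)
        if not config.duration_jitter:
            return base
        sd = float(np.interp(amp, MAIN_SEQUENCE_AMP_DEG,
                             MAIN_SEQUENCE_DURATION_SD_MS)) / 1000.0
        return float(np.clip(rng.normal(base, sd), 0.015, 0.095))

    # --- schedule trials sequentially -----------------------------------
    t = 0.8 + 0.2 * rng.random()  # settle-in before the first trial
    placed_saccades = 0
    for trial in range(n_trials):
        amp = float(rng.choice(config.saccade_amplitudes_deg))
        direction = float(rng.choice(config.directions_deg))
        theta = math.radians(direction)

        # outward saccade
        dur_out = draw_duration(amp)
        center = int(round((t + 2 * dur_out) * fs))
        add_step(center, amp, direction, dur_out)
        truth.events.append(_truth_saccade(
            _classify_direction(direction), center, dur_out, fs, amp,
            direction, config.gain_uv_per_deg,
            int(np.sign(round(math.cos(theta), 12))),
            int(np.sign(round(math.sin(theta), 12))),
            v_factor=config.v_gain_factor))
        placed_saccades += 1
        t += 4 * dur_out

        # fixation dwell on target, then return saccade
        if placed_saccades < config.n_saccades:
            t += rng.uniform(*config.dwell_range_s)
            back = (direction + 180.0) % 360
            theta_b = math.radians(back)
            dur_back = draw_duration(amp)
            center = int(round((t + 2 * dur_back) * fs))
            add_step(center, amp, back, dur_back)
            truth.events.append(_truth_saccade(
                _classify_direction(back), center, dur_back, fs, amp, back,
                config.gain_uv_per_deg,
                int(np.sign(round(math.cos(theta_b), 12))),
                int(np.sign(round(math.sin(theta_b), 12))),
                v_factor=config.v_gain_factor))
            placed_saccades += 1
            t += 4 * dur_back

        # inter-trial center gaze; blinks happen here
        n_blinks_here = blink_slots.get(trial, 0)
        if n_blinks_here:
            for _ in range(n_blinks_here):
                gap = rng.uniform(*config.blink_gap_range_s)
                bdur = rng.uniform(*config.blink_duration_range_s)
                bamp = config.blink_amplitude_uV + rng.uniform(
                    -1, 1) * config.blink_amplitude_jitter_uV
                pulse = blink_waveform(bamp, bdur, config.blink_asymmetry, fs)
                start = int(round((t + (gap - bdur) / 2.0) * fs))
                if start < 0 or start + len(pulse) > n:
                    raise ConfigError(
                        "too many events for the recording duration")
                v[start:start + len(pulse)] += pulse
                peak = start + int(np.argmax(pulse))
                truth.events.append(EventRecord(
                    "BLINK", onset=start, offset=start + len(pulse) - 1,
                    peak=peak, direction_sign=1,
                    measures={"duration_s": bdur, "amplitude_uV": bamp}))
                t += gap
        else:
            t += rng.uniform(*config.gap_range_s)

    # blinks without any saccades: spread them over the recording
    if config.n_blinks and not config.n_saccades:
        gap = config.duration_s / (config.n_blinks + 1)
        for i in range(config.n_blinks):
            bdur = rng.uniform(*config.blink_duration_range_s)
            bamp = config.blink_amplitude_uV + rng.uniform(
                -1, 1) * config.blink_amplitude_jitter_uV
            pulse = blink_waveform(bamp, bdur, config.blink_asymmetry, fs)
            start = int(round(((i + 1) * gap - bdur / 2) * fs))
            if start < 0 or start + len(pulse) > n:
                raise ConfigError("too many blinks for the recording duration")
            v[start:start + len(pulse)] += pulse
            truth.events.append(EventRecord(
                "BLINK", onset=start, offset=start + len(pulse) - 1,
                peak=start + int(np.argmax(pulse)), direction_sign=1,
                measures={"duration_s": bdur, "amplitude_uV": bamp}))

    if t > config.duration_s - 0.2:
        raise ConfigError(
            f"event schedule ({t:.1f} s) does not fit into the "
            f"{config.duration_s} s recording; reduce event counts")

    # --- drift, noise, powerline, artifacts -----------------------------
    tt = np.arange(n) / fs
    for chan in (h, v):
        n_sin = rng.integers(3, 6)
        for _ in range(n_sin):
            amp = config.drift_amplitude_uV / n_sin * rng.uniform(0.5, 1.5)
            freq = rng.uniform(0.005, config.drift_max_freq_hz)
            phase = rng.uniform(0, 2 * np.pi)
            chan += amp * np.sin(2 * np.pi * freq * tt + phase)
        if config.noise_white_sd_uV > 0:
            chan += rng.normal(0.0, config.noise_white_sd_uV, size=n)
        if config.powerline_amp_uV > 0:
            phase = rng.uniform(0, 2 * np.pi)
            chan += config.powerline_amp_uV * np.sin(
                2 * np.pi * config.powerline_hz * tt + phase)

    # movement/electrode-pop artifacts: an abrupt jump with an exponential
    # return to baseline (time constant ~tens of ms), hitting both channels
    # with independent magnitudes — the fast edge dwarfs the decay in the
    # velocity domain, as real pops do
    for _ in range(config.n_artifacts):
        pos = int(rng.integers(int(0.05 * n), int(0.95 * n)))
        tau = rng.uniform(0.02, 0.06)  # s
        length = min(n - pos, int(round(5 * tau * fs)))
        decay = np.exp(-np.arange(length) / (tau * fs))
        amp = rng.uniform(5, 10) * config.blink_amplitude_uV
        h[pos:pos + length] += rng.choice([-1.0, 1.0]) * amp * decay
        v[pos:pos + length] += rng.uniform(0.3, 1.0) * amp * decay

    rec = Recording(fs=fs, eog_h=h, eog_v=v,
                    meta={"synthetic": True, "seed": config.seed})
    truth.events.sort(key=lambda e: e.onset)
    return rec, truth
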