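"""Auto-calibration: estimating amplitude thresholds from the signal itself.

The detector needs three amplitude thresholds — horizontal saccade velocity,
vertical saccade velocity (both µV/s), and blink amplitude (µV) — but in
routine EOG there is no gaze calibration to set them from. The thresholds
are instead read off the distribution of the signal's own peaks:

1. Collect all local maxima of the absolute signal.
2. Sort the peak amplitudes ascending and scale them to [0, 1].
3. Trim large isolated artifact peaks from the top: scanning downward from
   the largest value, discard peaks while the gap to the next lower peak is
   at least 0.03 (on the [0, 1] scale); stop at the first adjacent pair
   closer than that.
4. Find the *pivot point* splitting the curve into a noise segment and an
   event segment: for every candidate split fit one straight line to each
   side (x = rank) and take the split minimizing the summed least-squares
   error. The final threshold sits 2% above the amplitude at the optimal
   split, mapped back to signal units.

Noise peaks are dense and small, so they form a long, nearly flat left
segment; saccade/blink peaks are sparse and large, forming a steep right
tail — the two-line fit finds the knee between the regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import CalibrationError, InputError
from .io import Recording
from .preprocess import VelocitySignal


@dataclass
class PeakCurve:
    """Sorted, scaled peak-amplitude curve.

    ``values`` are nondecreasing in [0, 1]; ``scale_max`` is the amplitude
    (in original signal units) mapped to 1.0, so ``values * scale_max``
    recovers original units. ``n_raw`` counts peaks before artifact
    trimming, ``n`` after.
    """

    values: np.ndarray
    scale_max: float
    n_raw: int

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class PivotResult:
    """Optimal two-line split of a peak curve.

    ``n_star`` is the size of the noise-side segment (1-based rank of the
    candidate pivot), ``d_n_amplitude`` the scaled amplitude there,
    ``d_p_amplitude`` the final pivot amplitude (margin above the candidate,
    default 2%) and ``threshold`` that amplitude in original signal units.
    """

    n_star: int
    d_n_amplitude: float
    d_p_amplitude: float
    threshold: float
    lse_total: float


@dataclass
class ThresholdSet:
    """The three auto-calibrated thresholds (all > 0)."""

    h_saccade: float  # µV/s, on |d(EOG_h)/dt|
    v_saccade: float  # µV/s, on |d(EOG_v)/dt|
    blink: float      # µV, on EOG_v


def collect_peak_amplitudes(samples) -> np.ndarray:
    """Amplitudes of all local maxima of ``|samples|``.

    A sample is a local maximum when it strictly exceeds both neighbours;
    for a flat (plateau) maximum the leftmost plateau sample counts once.
    """
    x = np.abs(np.asarray(samples, dtype=float))
    if len(x) < 3:
        raise InputError("need at least 3 samples to find local maxima")
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if len(nz) < 2:
        return np.empty(0)
    signs = np.sign(d[nz])
    starts = nz + 1  # first sample after each strict change
    is_max = (signs[:-1] > 0) & (signs[1:] < 0)
    return x[starts[:-1][is_max]]


def build_peak_curve(amplitudes, min_peaks: int = 30) -> PeakCurve:
    """Sort amplitudes ascending and scale so the maximum maps to 1.0."""
    amps = np.asarray(amplitudes, dtype=float)
    if len(amps) < min_peaks:
        raise CalibrationError(
            f"only {len(amps)} signal peaks found but {min_peaks} are needed "
            "for auto-calibration; provide a longer recording"
        )
    values = np.sort(amps)
    scale_max = float(values[-1])
    if scale_max <= 0:
        raise CalibrationError("all signal peaks are zero; cannot calibrate")
    return PeakCurve(values=values / scale_max, scale_max=scale_max,
                     n_raw=len(values))


def trim_artifacts(curve: PeakCurve, delta: float = 0.03,
                   rescale: bool = True) -> PeakCurve:
    """Drop isolated large artifact peaks from the top of the curve.

    Scanning from the largest value downward, a peak is discarded while the
    difference to the next lower peak is ≥ ``delta`` (on the scaled curve);
    the scan stops at the first adjacent pair closer than ``delta``, which is
    retained together with everything below it. With ``rescale`` (default)
    the trimmed curve is re-scaled to [0, 1] and ``scale_max`` updated so
    thresholds remain interpretable after huge artifacts are removed.
    """
    v = curve.values
    cut = len(v)
    while cut >= 2 and v[cut - 1] - v[cut - 2] >= delta:
        cut -= 1
    if cut == len(v):
        return replace(curve)
    kept = v[:cut]
    if len(kept) == 0:
        return replace(curve)  # degenerate: refuse to trim everything
    if rescale and kept[-1] > 0:
        new_max = float(kept[-1])
        return PeakCurve(values=kept / new_max,
                         scale_max=curve.scale_max * new_max,
                         n_raw=curve.n_raw)
    return PeakCurve(values=kept.copy(), scale_max=curve.scale_max,
                     n_raw=curve.n_raw)


def _segment_sse(cx, cy, cxx, cxy, cyy, i, j):
    """Vectorized SSE of per-segment straight-line fits.

    Given prefix sums (index k holds the sum over the first k points) and
    arrays ``i`` (exclusive-left) and ``j`` (inclusive-right counts), return
    the least-squares line-fit SSE over points i+1..j (1-based ranks).
    """
    n = j - i
    sx = cx[j] - cx[i]
    sy = cy[j] - cy[i]
    sxx = cxx[j] - cxx[i]
    sxy = cxy[j] - cxy[i]
    syy = cyy[j] - cyy[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        vxx = sxx - sx * sx / n
        vxy = sxy - sx * sy / n
        vyy = syy - sy * sy / n
        sse = vyy - np.where(vxx > 0, vxy * vxy / np.where(vxx > 0, vxx, 1.0), 0.0)
    return np.where(n >= 2, np.maximum(sse, 0.0), 0.0)


def find_pivot(curve: PeakCurve, n_min: int = 10,
               margin: float = 1.02) -> PivotResult:
    """Exhaustive two-line least-squares scan for the noise/event knee.

    For every split size n ∈ [n_min, N − n_min] a straight line is fit to
    ranks 1..n and another to ranks n+1..N; the split minimizing the summed
    SSE wins (ties break toward smaller n, the more conservative threshold).
    The pivot amplitude is ``margin`` (default 2% higher) times the amplitude
    at the winning split; the threshold is that amplitude in signal units.
    """
    y = curve.values
    N = len(y)
    if N < 2 * n_min:
        raise CalibrationError(
            f"peak curve has {N} points but the pivot scan needs at least "
            f"{2 * n_min}; provide a longer recording"
        )
    x = np.arange(1, N + 1, dtype=float)
    zero = np.zeros(1)
    cx = np.concatenate([zero, np.cumsum(x)])
    cy = np.concatenate([zero, np.cumsum(y)])
    cxx = np.concatenate([zero, np.cumsum(x * x)])
    cxy = np.concatenate([zero, np.cumsum(x * y)])
    cyy = np.concatenate([zero, np.cumsum(y * y)])

    ks = np.arange(n_min, N - n_min + 1)
    sse_left = _segment_sse(cx, cy, cxx, cxy, cyy, np.zeros_like(ks), ks)
    sse_right = _segment_sse(cx, cy, cxx, cxy, cyy, ks, np.full_like(ks, N))
    total = sse_left + sse_right
    # ties break toward smaller n; a tiny tolerance keeps degenerate
    # (e.g. perfectly collinear) curves from being decided by float noise
    tie_tol = 1e-12 * (1.0 + float(total.max()))
    best = int(np.argmax(total <= total.min() + tie_tol))
    n_star = int(ks[best])
    d_n = float(y[n_star - 1])
    d_p = margin * d_n
    threshold = d_p * curve.scale_max
    if threshold <= 0:
        raise CalibrationError(
            "pivot amplitude is zero (signal peaks indistinguishable); "
            "cannot derive a positive threshold"
        )
    return PivotResult(n_star=n_star, d_n_amplitude=d_n, d_p_amplitude=d_p,
                       threshold=threshold, lse_total=float(total[best]))


def calibrate_channel(samples, *, outlier_delta: float = 0.03,
                      pivot_margin: float = 1.02, n_min: int = 10,
                      min_peaks: int = 30, rescale_after_trim: bool = True,
                      ) -> tuple[PivotResult, PeakCurve]:
    """Full calibration chain for one channel: collect → build → trim → pivot."""
    amps = collect_peak_amplitudes(samples)
    curve = build_peak_curve(amps, min_peaks=min_peaks)
    curve = trim_artifacts(curve, delta=outlier_delta, rescale=rescale_after_trim)
    pivot = find_pivot(curve, n_min=n_min, margin=pivot_margin)
    return pivot, curve


def estimate_thresholds(clean: Recording, vel_h: VelocitySignal,
                        vel_v: VelocitySignal, *, outlier_delta: float = 0.03,
                        pivot_margin: float = 1.02, n_min: int = 10,
                        min_peaks: int = 30, blink_use_abs: bool = False,
                        rescale_after_trim: bool = True,
                        details: dict | None = None) -> ThresholdSet:
    """Estimate all three thresholds from a preprocessed recording.

    Saccade thresholds come from the absolute velocity signals; the blink
    threshold from the positional vertical channel. Blinks are upward
    deflections in the up-minus-down derivation, so by default only the
    positive part of EOG_v feeds the blink calibration (``blink_use_abs``
    switches to the absolute signal).

    If ``details`` is a dict it is filled with per-channel
    ``(PivotResult, PeakCurve)`` pairs under keys ``h_vel``/``v_vel``/``v_pos``
    for diagnostics.
    """
    kwargs = dict(outlier_delta=outlier_delta, pivot_margin=pivot_margin,
                  n_min=n_min, min_peaks=min_peaks,
                  rescale_after_trim=rescale_after_trim)
    blink_src = (np.abs(clean.eog_v) if blink_use_abs
                 else np.clip(clean.eog_v, 0.0, None))
    out = {}
    for key, samples in (("h_vel", vel_h.samples), ("v_vel", vel_v.samples),
                         ("v_pos", blink_src)):
        try:
            out[key] = calibrate_channel(samples, **kwargs)
        except CalibrationError as exc:
            raise CalibrationError(f"channel {key}: {exc}") from exc
    if details is not None:
        details.update(out)
    return ThresholdSet(h_saccade=out["h_vel"][0].threshold,
                        v_saccade=out["v_vel"][0].threshold,
                        blink=out["v_pos"][0].threshold)
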