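"""Pipeline configuration: validated tunables with their field defaults.

Config files are plain text with one dotted key per line::

    baseline.degree = 20
    denoise.cutoff_hz = 100
    calib.outlier_delta = 0.03
    filters.saccade_min_s = 0.030

Dotted keys map to attribute names by replacing ``.`` with ``_``. Lines
starting with ``#`` and blank lines are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .exceptions import ConfigError

_RANGES = {
    "baseline_degree": (1, 100),
    "denoise_cutoff_hz": (1.0, None),
    "calib_outlier_delta": (0.0, 1.0),
    "calib_pivot_margin": (1.0, 2.0),
    "calib_n_min": (2, None),
    "calib_min_peaks": (4, None),
    "detect_bound_frac": (0.0, 1.0),
    "detect_max_peak_duration_s": (0.0, None),
    "detect_max_blink_duration_s": (0.0, None),
    "detect_overlap_min_s": (0.0, None),
    "detect_edge_margin_s": (0.0, None),
    "filters_saccade_min_s": (0.0, None),
    "filters_saccade_max_s": (0.0, None),
    "filters_blink_min_s": (0.0, None),
}


@dataclass
class PipelineConfig:
    """All tunables of the detection pipeline, with standard defaults."""

    baseline_degree: int = 20
    denoise_cutoff_hz: float = 100.0
    denoise_wavelet: str = "haar"
    calib_outlier_delta: float = 0.03
    calib_pivot_margin: float = 1.02
    calib_n_min: int = 10
    calib_min_peaks: int = 30
    calib_blink_use_abs: bool = False
    calib_rescale_after_trim: bool = True
    detect_bound_frac: float = 0.10
    detect_max_peak_duration_s: float = 0.80
    detect_max_blink_duration_s: float = 1.2
    detect_overlap_min_s: float = 0.0
    detect_edge_margin_s: float = 0.75
    filters_enabled: bool = False
    filters_saccade_min_s: float = 0.030
    filters_saccade_max_s: float = 0.080
    filters_blink_min_s: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.denoise_wavelet != "haar":
            raise ConfigError(
                f"only the 'haar' wavelet is supported, got "
                f"{self.denoise_wavelet!r}")
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if lo is not None and value < lo:
                raise ConfigError(f"{name} = {value} below minimum {lo}")
            if hi is not None and value > hi:
                raise ConfigError(f"{name} = {value} above maximum {hi}")
        if self.filters_saccade_min_s > self.filters_saccade_max_s:
            raise ConfigError("filters.saccade_min_s exceeds saccade_max_s")

    # -- dotted-key plumbing ------------------------------------------------

    @staticmethod
    def _attr(dotted: str) -> str:
        return dotted.strip().replace(".", "_")

    def to_dict(self) -> dict:
        """Effective configuration as dotted keys (echoed in output headers)."""
        out = {}
        for f in fields(self):
            dotted = f.name.replace("_", ".", 1)
            out[dotted] = getattr(self, f.name)
        return out

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        """Load from a key-value file, then apply overrides (flags win)."""
        values: dict = {}
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            values[cls._attr(key)] = _parse_value(raw.strip())
        if overrides:
            values.update({cls._attr(k): v for k, v in overrides.items()
                           if v is not None})
        return cls.from_dict(values)

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, value in values.items():
            name = cls._attr(key)
            if name not in known:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[name] = _coerce(value, known[name].type)
        return cls(**kwargs)


def _parse_value(raw: str):
    low = raw.lower()
    if low in ("true", "on", "yes"):
        return True
    if low in ("false", "off", "no"):
        return False
    if low in ("none", "null", ""):
        return None
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def _coerce(value, ftype):
    if value is None or isinstance(value, (bool, str)):
        return value
    if "int" in str(ftype):
        return int(value)
    if "float" in str(ftype):
        return float(value)
    return value
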