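"""Minimal EDF (European Data Format) writer.

Writes a two-channel continuous EDF file with 16-bit samples and µV physical
dimension, sufficient for interchange with standard biosignal readers. Only
writing is implemented here — reading goes through mne (see
:func:`eogkit.io.read_recording`).
"""

from __future__ import annotations

import math
from datetime import datetime

import numpy as np

from .exceptions import InputError
from .io import Recording


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path, labels: tuple[str, str] = ("EOGh", "EOGv"),
              patient: str = "X", recording_id: str = "eogkit") -> None:
    """Write a :class:`Recording` as a 2-signal EDF file.

    The sampling rate must yield an integral number of samples per 1-second
    data record (true for ordinary rates like 250/500/1000 Hz).
    """
    fs = rec.fs
    spr = fs  # samples per 1 s record
    if abs(spr - round(spr)) > 1e-9:
        raise InputError(
            f"EDF export needs an integer number of samples per second, "
            f"got fs={fs}")
    spr = int(round(spr))
    channels = [np.asarray(rec.eog_h, dtype=float),
                np.asarray(rec.eog_v, dtype=float)]
    n = len(channels[0])
    n_records = math.ceil(n / spr)
    pad = n_records * spr - n

    phys_min, phys_max = [], []
    digital = []
    for x in channels:
        lo = float(np.floor(x.min())) - 1.0
        hi = float(np.ceil(x.max())) + 1.0
        scale = (hi - lo) / (32767 - (-32768))
        dig = np.round((x - lo) / scale + (-32768)).astype("<i2")
        if pad:
            dig = np.concatenate([dig, np.full(pad, dig[-1], dtype="<i2")])
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(dig)

    ns = len(channels)
    header_bytes = 256 * (ns + 1)
    now = datetime(2000, 1, 1)
    head = b"".join([
        _fixed("0", 8),
        _fixed(patient, 80),
        _fixed(recording_id, 80),
        _fixed(now.strftime("%d.%m.%y"), 8),
        _fixed(now.strftime("%H.%M.%S"), 8),
        _fixed(str(header_bytes), 8),
        _fixed("", 44),
        _fixed(str(n_records), 8),
        _fixed("1", 8),            # record duration, seconds
        _fixed(str(ns), 4),
    ])
    sig = b"".join([
        b"".join(_fixed(lab, 16) for lab in labels),
        b"".join(_fixed("EOG", 80) for _ in channels),          # transducer
        b"".join(_fixed("uV", 8) for _ in channels),
        b"".join(_fixed(f"{v:.6g}", 8) for v in phys_min),
        b"".join(_fixed(f"{v:.6g}", 8) for v in phys_max),
        b"".join(_fixed("-32768", 8) for _ in channels),
        b"".join(_fixed("32767", 8) for _ in channels),
        b"".join(_fixed("", 80) for _ in channels),             # prefiltering
        b"".join(_fixed(str(spr), 8) for _ in channels),
        b"".join(_fixed("", 32) for _ in channels),
    ])
    with open(path, "wb") as fh:
        fh.write(head + sig)
        for r in range(n_records):
            for dig in digital:
                fh.write(dig[r * spr:(r + 1) * spr].tobytes())
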