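"""Overall Dynamic Body Acceleration (ODBA) from tri-axial bursts.

Static acceleration on each axis is the arithmetic mean over the whole
burst; dynamic acceleration is the per-sample deviation from that mean.
ODBA is the sum over the burst, and then over the three axes, of the
absolute dynamic accelerations — a summed (not per-sample-averaged) index
of energy expenditure in raw acceleration units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NOMINAL_SAMPLES = 60  # 6 s burst at 10 Hz
MIN_SAMPLES = 10


def _as_burst(samples) -> np.ndarray:
    arr = [np.asarray(a, dtype=float).ravel() for a in samples]
    if len(arr) != 3:
        raise ValueError("burst must have exactly 3 axes")
    n = len(arr[0])
    if any(len(a) != n for a in arr):
        raise ValueError("burst axes differ in length")
    if n == 0:
        raise ValueError("burst axes are empty")
    return np.vstack(arr)


def static_acceleration(samples) -> np.ndarray:
    """Per-axis whole-burst mean (the static/gravitational component)."""
    return _as_burst(samples).mean(axis=1)


def compute_odba(samples) -> float:
    """ODBA = sum over axes of summed |sample - axis mean|."""
    burst = _as_burst(samples)
    static = burst.mean(axis=1, keepdims=True)
    return float(np.abs(burst - static).sum())


def process_bursts(bursts: pd.DataFrame) -> pd.DataFrame:
    """Per-burst ODBA records from a frame of bursts (ax/ay/az arrays).

    Bursts shorter than the nominal 60 samples are processed but flagged
    ``short``; bursts with fewer than 10 samples are rejected (``rejected``
    flag set, odba NaN).
    """
    odba = np.full(len(bursts), np.nan)
    short = np.zeros(len(bursts), dtype=bool)
    rejected = np.zeros(len(bursts), dtype=bool)
    for i, row in enumerate(bursts.itertuples()):
        n = len(row.ax)
        if n < MIN_SAMPLES:
            rejected[i] = True
            continue
        short[i] = n < NOMINAL_SAMPLES
        odba[i] = compute_odba((row.ax, row.ay, row.az))
    return pd.DataFrame({
        "bird_id": bursts["bird_id"].to_numpy(),
        "timestamp": bursts["timestamp"].to_numpy(),
        "odba": odba,
        "short": short,
        "rejected": rejected,
    })
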