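"""Respiratory time-series processing.

Mixing-chamber ergospirometry exports native 10-s averages. For the all-out
time trial these are expanded to a 1-s grid (piecewise constant) and smoothed
with a 9-s counterbalanced moving average (+/- 4 s) applied twice, with the
window shrinking symmetrically toward segment edges so the first and last
seconds stay unsmoothed. Window means, moving-window peaks and fractional
utilization are defined here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeakSet",
    "expand_to_1s",
    "counterbalanced_smooth",
    "window_mean",
    "moving_peak",
    "fractional_utilization",
]


@dataclass(frozen=True)
class PeakSet:
    """Peak values over the TT, each with its defining moving-window length.

    vo2peak: highest 20-s moving average of the smoothed VO2 (L min^-1);
    rer_peak: RER over the same 20-s window; hr_peak: highest 10-s average;
    po_peak / cadence_peak: highest 5-s moving averages of the 1-s power data.
    """

    vo2peak: float
    vo2peak_window_start: int
    rer_peak: float
    po_peak: float
    cadence_peak: float | None = None
    hr_peak: float | None = None


def expand_to_1s(values, spacing_s: int = 10) -> np.ndarray:
    """Replicate each native sample across the seconds it covers.

    ``values`` are the native (e.g. 10-s) averages in time order; the result
    has ``len(values) * spacing_s`` one-second samples, so block-averaging
    back to the native grid is the identity.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("expand_to_1s expects a non-empty 1-D array")
    if spacing_s < 1:
        raise ValueError("spacing must be >= 1 s")
    return np.repeat(v, spacing_s)


def counterbalanced_smooth(values, half_width: int = 4, passes: int = 2) -> np.ndarray:
    """Counterbalanced (centred) moving average with edge-shrinking windows.

    Interior second ``t`` is replaced by the mean over ``[t-h, t+h]`` with
    ``h = half_width`` (9 samples for the default +/- 4 s). Near a segment
    edge the half-width shrinks symmetrically to the distance from the edge,
    so the window grows from 1 sample at the first second to the full 9
    samples at the fifth, and mirrors this over the last seconds. The whole
    operator is applied ``passes`` times (twice by default).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    full = 2 * half_width + 1
    if x.size < full:
        raise ValueError(
            f"series of length {x.size} shorter than smoothing window {full}"
        )
    n = x.size
    idx = np.arange(n)
    h = np.minimum(half_width, np.minimum(idx, n - 1 - idx))
    out = x
    edge = h == 0
    for _ in range(passes):
        c = np.concatenate(([0.0], np.cumsum(out)))
        lo = idx - h
        hi = idx + h + 1
        prev = out
        out = (c[hi] - c[lo]) / (hi - lo)
        out[edge] = prev[edge]  # width-1 windows are exactly the input
    return out


def window_mean(t, values, window) -> float:
    """Arithmetic mean of the samples whose timestamps fall in [start, end).

    Works for the 1-s grid and for native 10-s samples alike (timestamps are
    the sample centres for native data).
    """
    start, end = window
    tt = np.asarray(t, dtype=float)
    mask = (tt >= start) & (tt < end)
    if not mask.any():
        raise ValueError(f"no samples in window [{start}, {end})")
    return float(np.mean(np.asarray(values, dtype=float)[mask]))


def moving_peak(values, window_s: int) -> tuple[float, int]:
    """Highest ``window_s``-second moving average and its start index.

    Ties are broken by the earliest window (argmax convention), which makes
    the peak deterministic on plateaus.
    """
    x = np.asarray(values, dtype=float)
    if window_s < 1:
        raise ValueError("window must be >= 1 s")
    if x.size < window_s:
        raise ValueError(f"series of length {x.size} shorter than window {window_s}")
    c = np.concatenate(([0.0], np.cumsum(x)))
    means = (c[window_s:] - c[:-window_s]) / window_s
    start = int(np.argmax(means))
    return float(means[start]), start


def fractional_utilization(tt_mean_vo2: float, vo2peak: float) -> float:
    """Mean TT VO2 as a percentage of VO2peak."""
    if vo2peak <= 0:
        raise ValueError("vo2peak must be positive")
    return 100.0 * tt_mean_vo2 / vo2peak
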