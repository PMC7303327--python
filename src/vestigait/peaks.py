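"""Shared local-extremum detection for sway and yaw series.

Detection runs on a 0.25 s moving-average smoothed copy of the signal (so
sample-level sensor noise does not spawn spurious peaks), then each extremum
index is refined to the raw signal's extreme within half a smoothing window,
so reported amplitudes are not attenuated by the filter.  A plateau yields
its center sample.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = ["smooth", "local_extrema", "alternating_extrema", "DEFAULT_SMOOTH_S"]

DEFAULT_SMOOTH_S = 0.25


def smooth(x: np.ndarray, rate: float, window_s: float = DEFAULT_SMOOTH_S) -> np.ndarray:
    """Odd-length moving average; window clamped to the series length."""
    x = np.asarray(x, dtype=float)
    n = int(round(window_s * rate))
    if n % 2 == 0:
        n += 1
    if n <= 1 or x.size < 3:
        return x.copy()
    n = min(n, x.size if x.size % 2 else x.size - 1)
    return uniform_filter1d(x, size=n, mode="nearest")


def _refine(x: np.ndarray, idx: np.ndarray, half: int, mode: str) -> np.ndarray:
    """Move each smoothed-signal extremum to the raw extreme nearby."""
    pick = np.argmax if mode == "max" else np.argmin
    refined = []
    for i in idx:
        lo = max(0, int(i) - half)
        hi = min(x.size, int(i) + half + 1)
        refined.append(lo + int(pick(x[lo:hi])))
    return np.unique(np.asarray(refined, dtype=int))


def local_extrema(
    x: np.ndarray,
    rate: float,
    window_s: float = DEFAULT_SMOOTH_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima of ``x``.

    Returns ``(maxima, minima)`` as sorted integer index arrays.  Endpoints
    are never extrema; ties on a plateau resolve to its center.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    xs = smooth(x, rate, window_s)
    maxima, _ = find_peaks(xs)
    minima, _ = find_peaks(-xs)
    half = max(1, int(round(window_s * rate)) // 2)
    return _refine(x, maxima, half, "max"), _refine(x, minima, half, "min")


def alternating_extrema(
    x: np.ndarray,
    rate: float,
    window_s: float = DEFAULT_SMOOTH_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Merged, strictly alternating extrema sequence.

    Returns ``(indices, kinds)`` where ``kinds`` is +1 for a maximum and -1
    for a minimum.  When two extrema of the same kind are adjacent (possible
    after refinement on noisy data) only the more extreme one is kept.
    """
    maxima, minima = local_extrema(x, rate, window_s)
    idx = np.concatenate([maxima, minima])
    kind = np.concatenate([np.ones(maxima.size, dtype=int), -np.ones(minima.size, dtype=int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]

    kept_idx: list[int] = []
    kept_kind: list[int] = []
    for i, k in zip(idx, kind):
        if kept_kind and kept_kind[-1] == k:
            # same-kind run: keep the more extreme sample
            if k * x[i] > k * x[kept_idx[-1]]:
                kept_idx[-1] = int(i)
        else:
            kept_idx.append(int(i))
            kept_kind.append(int(k))
    return np.asarray(kept_idx, dtype=int), np.asarray(kept_kind, dtype=int)
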