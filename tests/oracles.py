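"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


def cox_de_boor_basis(x, knots, degree=3):
    """Textbook Cox–de Boor recursion, independent of scipy.

    Evaluates all ``len(knots) - degree - 1`` B-spline basis functions
    at the points ``x``.  Intervals are half-open except that the right
    boundary is attached to the last non-empty interval (clamped
    convention), matching evaluation on ``[knots[0], knots[-1]]``.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    n = len(t) - degree - 1
    out = np.zeros((len(x), n))
    for pi, xp in enumerate(x):
        # degree 0
        b = np.zeros((len(t) - 1,))
        for i in range(len(t) - 1):
            if t[i] <= xp < t[i + 1]:
                b[i] = 1.0
        if xp == t[-1]:  # clamp right boundary into the last real interval
            for i in range(len(t) - 2, -1, -1):
                if t[i] < t[i + 1]:
                    b[i] = 1.0
                    break
        # recursion
        for d in range(1, degree + 1):
            nb = np.zeros(len(t) - 1 - d)
            for i in range(len(nb)):
                left = 0.0
                if t[i + d] != t[i]:
                    left = (xp - t[i]) / (t[i + d] - t[i]) * b[i]
                right = 0.0
                if t[i + d + 1] != t[i + 1]:
                    right = (t[i + d + 1] - xp) / (t[i + d + 1] - t[i + 1]) * b[i + 1]
                nb[i] = left + right
            b = nb
        out[pi] = b[:n]
    return out


def brute_force_peak2peak(data, threshold, wlen, wstep):
    """All window positions (in samples) whose peak-to-peak exceeds the
    threshold on any channel; returns a per-sample boolean mask."""
    data = np.atleast_2d(data)
    n = data.shape[1]
    mask = np.zeros(n, dtype=bool)
    starts = list(range(0, max(n - wlen + 1, 1), wstep))
    if starts and starts[-1] != n - wlen and n - wlen > 0:
        starts.append(n - wlen)
    for s in starts:
        seg = data[:, s : s + wlen]
        if np.any(seg.max(axis=1) - seg.min(axis=1) > threshold):
            mask[s : s + wlen] = True
    return mask


def convolve_trains(trains, kernels, n_samples):
    """Discrete convolution of per-event-type indicator/weight trains
    with their kernels, truncated to the recording — the signal a stick
    expansion must reproduce."""
    y = np.zeros(n_samples)
    for train, kernel in zip(trains, kernels):
        full = np.convolve(train, kernel)
        y += full[:n_samples]
    return y
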