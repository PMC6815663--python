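"""Artifact handling for continuous recordings: detect, then blank.

Deconvolution operates on the continuous (not epoched) signal, so
contaminated stretches cannot simply be cut out — removing samples would
also remove the overlap structure.  Instead, artifact intervals are
detected (moving-window peak-to-peak threshold) and the corresponding
rows of the time-expanded design matrix are blanked (set to zero).
Zeroed rows carry no leverage, so the contaminated samples do not
influence the fit while the clean parts of every trial still do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .timeexpand import ExpandedDesign

__all__ = ["IntervalSet", "detect_peak2peak", "blank_rows"]

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Sorted, merged, pairwise-disjoint half-open sample intervals."""

    intervals: np.ndarray  # (n, 2) int, [start, stop)

    def __init__(self, intervals=()):
        arr = np.asarray(list(intervals), dtype=int).reshape(-1, 2)
        if arr.size and np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("intervals must satisfy stop > start")
        self.intervals = _merge(arr)

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    def __eq__(self, other):
        return isinstance(other, IntervalSet) and np.array_equal(
            self.intervals, other.intervals
        )

    @property
    def n_samples(self) -> int:
        if not len(self.intervals):
            return 0
        return int(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def mask(self, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask, True inside an interval."""
        m = np.zeros(n_samples, dtype=bool)
        for start, stop in self.intervals:
            m[max(start, 0) : min(stop, n_samples)] = True
        return m

    # -- TSV round trip --------------------------------------------------
    def save(self, path, srate=None):
        """Write as 2-column TSV of sample indices (or seconds if srate)."""
        arr = self.intervals.astype(float)
        if srate is not None:
            arr = arr / srate
        np.savetxt(path, arr, delimiter="\t", header="start\tstop", comments="")

    @classmethod
    def load(cls, path, srate=None):
        arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        if srate is not None:
            arr = np.rint(arr * srate)
        return cls(arr.astype(int))


def _merge(arr: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0])]
    merged = [list(arr[0])]
    for start, stop in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append([start, stop])
    return np.asarray(merged, dtype=int)


def detect_peak2peak(
    data,
    threshold: float,
    winlen: float,
    srate: float,
    step: float = None,
) -> IntervalSet:
    """Moving-window peak-to-peak amplitude threshold on any channel.

    A window of ``winlen`` seconds steps through the recording in
    increments of ``step`` seconds (default ``winlen / 2``).  Whenever
    ``max - min`` within the window exceeds ``threshold`` on any
    channel, the full window is flagged; flagged windows are merged.
    """
    if threshold <= 0 or winlen <= 0:
        raise ValueError("threshold and winlen must be positive")
    if step is None:
        step = winlen / 2
    if step <= 0:
        raise ValueError("step must be positive")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[1]
    wlen = max(int(np.rint(winlen * srate)), 1)
    wstep = max(int(np.rint(step * srate)), 1)
    if wlen >= n:
        ptp = data.max(axis=1) - data.min(axis=1)
        return IntervalSet([(0, n)] if np.any(ptp > threshold) else [])
    flagged = []
    starts = list(range(0, n - wlen + 1, wstep))
    if starts[-1] != n - wlen:  # cover the tail
        starts.append(n - wlen)
    for start in starts:
        seg = data[:, start : start + wlen]
        if np.any(seg.max(axis=1) - seg.min(axis=1) > threshold):
            flagged.append((start, start + wlen))
    return IntervalSet(flagged)


def blank_rows(
    expanded: ExpandedDesign, intervals: IntervalSet
) -> tuple[ExpandedDesign, int]:
    """Zero all design rows covered by the intervals.

    Column structure is unchanged; returns the blanked design and the
    number of blanked rows.  The response should be zeroed on the same
    rows before fitting (the solver does this) so the residual variance
    stays interpretable.
    """
    n = expanded.n_samples
    if len(intervals) and (
        intervals.intervals[0, 0] < 0 or intervals.intervals[-1, 1] > n
    ):
        raise ValueError("intervals extend outside the recording")
    mask = intervals.mask(n)
    n_blanked = int(mask.sum())
    keep = sp.diags((~mask).astype(float), format="csr")
    X = (keep @ expanded.X).tocsr()
    X.eliminate_zeros()
    logger.info("blanked %d of %d design rows", n_blanked, n)
    out = ExpandedDesign(
        X=X,
        colmap=list(expanded.colmap),
        srate=expanded.srate,
        blocks=dict(expanded.blocks),
    )
    out.blanked_mask = mask  # attribute used by the solver for y and sigma
    return out, n_blanked
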