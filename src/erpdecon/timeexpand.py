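"""Time expansion: the sparse continuous-time design matrix.

The instance-level design matrix X (one row per event) is expanded into
a sparse matrix spanning every sample of the continuous recording.  Each
predictor column is replicated across the samples of a local time window
around each event onset, under one of three temporal bases:

stick
    one column per local sample (FIR / dummy coding) — the default.
spline
    cubic B-splines over local time; fewer columns, smooth estimates.
fourier
    truncated Fourier set (constant + K cosine/sine harmonics); acts as
    a low-pass on the estimated time-courses.

Windows of overlapping events land on the same rows and their
contributions are summed — solving the resulting least-squares problem
is the deconvolution.  Local sample indices are 0-based and the window
includes both rounded endpoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .design import SPLINE_DEGREE, DesignMatrix
from .formula import Term

__all__ = [
    "TemporalBasis",
    "ColRef",
    "ExpandedDesign",
    "onsets_to_samples",
    "local_window",
    "basis_transform",
    "time_expand",
    "assemble",
    "add_continuous_covariate",
]


@dataclass(frozen=True)
class TemporalBasis:
    """Descriptor of the local-time basis used in the expansion."""

    kind: str = "stick"  # {"stick", "spline", "fourier"}
    n_basis: Optional[int] = None  # spline only
    n_harmonics: Optional[int] = None  # fourier only (K)

    def __post_init__(self):
        if self.kind not in ("stick", "spline", "fourier"):
            raise ValueError(f"unknown temporal basis {self.kind!r}")
        if self.kind == "spline" and (self.n_basis is None or self.n_basis < 4):
            raise ValueError("spline temporal basis needs n_basis >= 4")
        if self.kind == "fourier" and (
            self.n_harmonics is None or self.n_harmonics < 1
        ):
            raise ValueError("fourier temporal basis needs n_harmonics >= 1")

    def n_cols(self, n_local: int) -> int:
        if self.kind == "stick":
            return n_local
        if self.kind == "spline":
            return self.n_basis
        return 2 * self.n_harmonics + 1


def onsets_to_samples(onsets, srate: float, n_samples: Optional[int] = None):
    """Event onsets in seconds → 0-based sample indices (half-to-even).

    If ``n_samples`` is given, out-of-range events are excluded with a
    warning; returns ``(samples, keep_mask)``, otherwise just samples.
    """
    if srate <= 0:
        raise ValueError("sampling rate must be positive")
    samples = np.rint(np.asarray(onsets, dtype=float) * srate).astype(int)
    if n_samples is None:
        return samples
    keep = (samples >= 0) & (samples < n_samples)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} event(s) outside the recording",
            stacklevel=2,
        )
    return samples[keep], keep


def local_window(tau_min: float, tau_max: float, srate: float) -> np.ndarray:
    """Local sample grid ``round(tau_min*srate) .. round(tau_max*srate)``.

    Inclusive of both rounded endpoints; local time of sample ``k`` is
    ``k / srate``.
    """
    if not tau_min < tau_max:
        raise ValueError("window must satisfy tau_min < tau_max")
    k0 = int(np.rint(tau_min * srate))
    k1 = int(np.rint(tau_max * srate))
    grid = np.arange(k0, k1 + 1)
    if grid.size < 2:
        raise ValueError("window shorter than 2 samples")
    return grid


def basis_transform(basis: TemporalBasis, n_local: int) -> np.ndarray:
    """Matrix T (n_local × n_cols) mapping basis coefficients to local time.

    stick → identity; spline → clamped cubic B-splines on equally spaced
    knots across the window (no column dropped: local time has no
    intercept); fourier → constant column ``1/sqrt(n_local)`` followed by
    cos/sin at integer frequencies ``k = 1..K`` cycles per window, all
    columns l2-normalized (pairwise orthogonal).
    """
    n_cols = basis.n_cols(n_local)
    if n_cols > n_local:
        raise ValueError(
            f"temporal basis with {n_cols} columns exceeds window "
            f"length {n_local}"
        )
    if basis.kind == "stick":
        return np.eye(n_local)
    if basis.kind == "spline":
        n = basis.n_basis
        # uniform analogue of the quantile construction: n-2 equally
        # spaced breakpoints spanning the window, boundaries repeated
        q = np.linspace(0.0, n_local - 1.0, n - 2)
        knots = np.concatenate([[q[0]] * 3, q, [q[-1]] * 3])
        grid = np.arange(n_local, dtype=float)
        T = BSpline.design_matrix(grid, knots, SPLINE_DEGREE, extrapolate=False)
        return np.asarray(T.todense())
    # fourier
    K = basis.n_harmonics
    j = np.arange(n_local)
    cols = [np.full(n_local, 1.0 / np.sqrt(n_local))]
    for k in range(1, K + 1):
        c = np.cos(2 * np.pi * k * j / n_local)
        s = np.sin(2 * np.pi * k * j / n_local)
        cols.append(c / np.linalg.norm(c))
        cols.append(s / np.linalg.norm(s))
    return np.column_stack(cols)


@dataclass(frozen=True)
class ColRef:
    """Metadata for one column of the expanded design."""

    event_type: str
    term: Optional[Term]  # None for continuous whole-recording covariates
    column_label: str  # label of the instance-level design column
    basis_index: int  # local-time sample (stick) or basis column index
    kind: str = "expanded"  # {"expanded", "continuous_covariate"}


@dataclass
class ExpandedDesign:
    """Sparse time-expanded design matrix with its column map."""

    X: sp.csr_matrix  # (n_samples, n_columns)
    colmap: list[ColRef]
    srate: float
    # per event type: (window grid, TemporalBasis, transform T, design)
    blocks: dict[str, dict] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def columns_for(self, event_type: str, column_label=None):
        return [
            i
            for i, c in enumerate(self.colmap)
            if c.event_type == event_type
            and (column_label is None or c.column_label == column_label)
        ]

    # -- serialization (Matrix Market + JSON sidecar) --------------------
    def save(self, mtx_path, colmap_path):
        from scipy.io import mmwrite

        mmwrite(str(mtx_path), self.X.tocoo())
        meta = {
            "srate": self.srate,
            "columns": [
                {
                    "event_type": c.event_type,
                    "term": c.term.label if c.term is not None else None,
                    "column_label": c.column_label,
                    "basis_index": c.basis_index,
                    "kind": c.kind,
                }
                for c in self.colmap
            ],
        }
        with open(colmap_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def time_expand(
    design: DesignMatrix,
    onset_samples,
    window: np.ndarray,
    basis: TemporalBasis,
    n_samples_total: int,
    event_type: str = "event",
    srate: float = 0.0,
) -> ExpandedDesign:
    """Expand an instance-level design across the continuous recording.

    For each instance ``i``, predictor column ``c`` and local sample
    ``k``, row ``onset_i + k`` receives ``x[i, c] * T[k, b]`` in column
    ``(c, b)``; collisions between overlapping windows are summed.  Rows
    falling outside the recording are truncated (partial windows at the
    edges).
    """
    X = np.asarray(design.values, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    if np.isnan(X).any():
        raise ValueError("design matrix contains NaN")
    onset_samples = np.asarray(onset_samples, dtype=int)
    n_inst, n_pred = X.shape
    n_local = len(window)
    T = basis_transform(basis, n_local)
    n_b = T.shape[1]
    n_cols = n_pred * n_b
    if n_cols > n_samples_total:
        warnings.warn(
            "expanded design has more columns than rows (underdetermined)",
            stacklevel=2,
        )

    # rows: (instance, local sample) pairs inside the recording
    rows_full = onset_samples[:, None] + window[None, :]  # (n_inst, n_local)
    inside = (rows_full >= 0) & (rows_full < n_samples_total)
    inst_idx, loc_idx = np.nonzero(inside)
    rows = rows_full[inst_idx, loc_idx]

    # data for all (row, col) contributions: x[i, c] * T[k, b]
    # build per predictor column to keep memory bounded
    row_parts, col_parts, dat_parts = [], [], []
    for c in range(n_pred):
        xc = X[inst_idx, c]  # per surviving (i, k) pair
        Tk = T[loc_idx, :]  # (pairs, n_b)
        dat = xc[:, None] * Tk
        nz = dat != 0
        pair_rows = np.broadcast_to(rows[:, None], dat.shape)[nz]
        pair_cols = (
            c * n_b + np.broadcast_to(np.arange(n_b)[None, :], dat.shape)[nz]
        )
        row_parts.append(pair_rows)
        col_parts.append(pair_cols)
        dat_parts.append(dat[nz])

    coo = sp.coo_matrix(
        (
            np.concatenate(dat_parts) if dat_parts else np.empty(0),
            (
                np.concatenate(row_parts) if row_parts else np.empty(0, int),
                np.concatenate(col_parts) if col_parts else np.empty(0, int),
            ),
        ),
        shape=(n_samples_total, n_cols),
    )
    Xdc = coo.tocsr()  # duplicate (row, col) entries are summed here

    colmap = [
        ColRef(
            event_type=event_type,
            term=design.columns[c].term,
            column_label=design.columns[c].label,
            basis_index=b,
        )
        for c in range(n_pred)
        for b in range(n_b)
    ]
    blocks = {
        event_type: {
            "window": window,
            "basis": basis,
            "transform": T,
            "design": design,
            "onset_samples": onset_samples,
        }
    }
    return ExpandedDesign(X=Xdc, colmap=colmap, srate=srate, blocks=blocks)


def assemble(event_blocks: list[ExpandedDesign], srate: float) -> ExpandedDesign:
    """Concatenate per-event-type expansions along columns."""
    if not event_blocks:
        raise ValueError("no expanded designs to assemble")
    n_rows = {b.X.shape[0] for b in event_blocks}
    if len(n_rows) != 1:
        raise ValueError(f"mismatched row counts: {sorted(n_rows)}")
    X = sp.hstack([b.X for b in event_blocks], format="csr")
    colmap = [c for b in event_blocks for c in b.colmap]
    blocks = {}
    for b in event_blocks:
        overlap = blocks.keys() & b.blocks.keys()
        if overlap:
            raise ValueError(f"duplicate event type(s): {sorted(overlap)}")
        blocks.update(b.blocks)
    return ExpandedDesign(X=X, colmap=colmap, srate=srate, blocks=blocks)


def add_continuous_covariate(
    expanded: ExpandedDesign, signal, name: str
) -> ExpandedDesign:
    """Append a whole-recording covariate as a single dense column.

    No time expansion is applied; the fitted coefficient is the
    instantaneous (zero-lag) response to the signal.
    """
    sig = np.asarray(signal, dtype=float).ravel()
    if sig.shape[0] != expanded.n_samples:
        raise ValueError(
            f"signal length {sig.shape[0]} != row count {expanded.n_samples}"
        )
    if np.isnan(sig).any():
        raise ValueError("continuous covariate contains NaN; clean or blank first")
    X = sp.hstack([expanded.X, sp.csr_matrix(sig[:, None])], format="csr")
    colmap = expanded.colmap + [
        ColRef(
            event_type="",
            term=None,
            column_label=name,
            basis_index=0,
            kind="continuous_covariate",
        )
    ]
    return ExpandedDesign(
        X=X, colmap=colmap, srate=expanded.srate, blocks=dict(expanded.blocks)
    )
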