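"""From coefficients to interpretable event-related time-courses.

Fitted coefficients live on the expanded-design columns (per basis
function, per predictor).  This module regroups them into per-term
regression-ERP waveforms on the model's local-time grid, evaluates
spline effects at chosen predictor values, applies baseline correction
to the betas, and exports everything as long-format CSV.

With treatment coding the intercept course is the reference-condition
waveform and every other course is a partial effect (a difference wave
relative to the reference), never a cell mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formula import Term
from .solve import FitResult

__all__ = [
    "ErpSet",
    "unfold_betas",
    "evaluate_spline_effect",
    "baseline_correct",
    "export_long",
    "import_long",
]

CSV_COLUMNS = ["channel", "event_type", "term", "effect_column", "time_s", "beta"]


@dataclass
class ErpSet:
    """rERP time-courses grouped by (event type, term).

    ``courses[(event_type, term_label)]`` has shape
    (n_channels, n_local, n_effect_columns); ``time[event_type]`` is the
    local-time axis in seconds.  Reference levels and spline bases are
    carried so downstream evaluation is unambiguous.
    """

    courses: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    effect_labels: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    terms: dict[tuple[str, str], Term | None] = field(default_factory=dict)
    time: dict[str, np.ndarray] = field(default_factory=dict)
    channels: list[str] = field(default_factory=list)
    reference: dict[str, dict[str, str]] = field(default_factory=dict)
    spline_bases: dict[str, dict] = field(default_factory=dict)
    srate: float = 0.0

    def keys(self):
        return list(self.courses)

    def get(self, event_type: str, term_label: str) -> np.ndarray:
        return self.courses[(event_type, term_label)]

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def unfold_betas(fit: FitResult, channels=None) -> ErpSet:
    """Regroup fitted coefficients into per-term time-courses.

    For the stick basis this is a pure reshape; for spline/Fourier
    temporal bases the basis coefficients are mapped through the
    transform T so every course lives on the local-time sample grid.
    """
    n_ch = fit.n_channels
    if channels is None:
        channels = [f"ch{c}" for c in range(n_ch)]
    out = ErpSet(channels=list(channels), srate=fit.srate)

    # offsets of each event block in the flat coefficient vector
    offset = 0
    block_offsets = {}
    seen = set()
    for i, ref in enumerate(fit.colmap):
        key = ref.event_type if ref.kind == "expanded" else None
        if key is not None and key not in seen:
            block_offsets[key] = i
            seen.add(key)
    for etype, block in fit.blocks.items():
        T = np.asarray(block["transform"])
        n_local, n_b = T.shape
        design = block["design"]
        window = np.asarray(block["window"])
        out.time[etype] = (
            window / fit.srate if fit.srate else window.astype(float)
        )
        out.reference[etype] = dict(design.reference)
        out.spline_bases[etype] = dict(design.spline_bases)
        base = block_offsets[etype]
        n_cols = design.n_columns
        expected = [
            (design.columns[c].label, b)
            for c in range(n_cols)
            for b in range(n_b)
        ]
        actual = [
            (r.column_label, r.basis_index)
            for r in fit.colmap[base : base + n_cols * n_b]
        ]
        if expected != actual:
            raise ValueError(
                f"column map of event type {etype!r} does not match its design"
            )
        coeffs = fit.coefficients[:, base : base + n_cols * n_b]
        coeffs = coeffs.reshape(n_ch, n_cols, n_b)
        # (ch, c, b) @ T.T -> (ch, c, n_local) -> (ch, n_local, c)
        full = np.transpose(coeffs @ T.T, (0, 2, 1))
        # split per term, preserving term order
        by_term: dict[str, list[int]] = {}
        for c, col in enumerate(design.columns):
            by_term.setdefault(col.term.label, []).append(c)
        for term_label, cols in by_term.items():
            key = (etype, term_label)
            out.courses[key] = full[:, :, cols]
            out.effect_labels[key] = [design.columns[c].label for c in cols]
            out.terms[key] = design.columns[cols[0]].term

    # whole-recording continuous covariates: one zero-lag coefficient
    for i, ref in enumerate(fit.colmap):
        if ref.kind == "continuous_covariate":
            key = ("", ref.column_label)
            out.courses[key] = fit.coefficients[:, i][:, None, None]
            out.effect_labels[key] = [ref.column_label]
            out.terms[key] = None
            out.time.setdefault("", np.zeros(1))
    return out


def evaluate_spline_effect(
    erps: ErpSet, predictor: str, values, event_type: str | None = None
) -> np.ndarray:
    """Evaluate a fitted spline effect at chosen predictor values.

    Uses the same basis (same knots, same dropped column) as the fit,
    clamping out-of-range values to the boundary knots.  The returned
    effect (n_channels × n_local × n_values) is relative to the model's
    reference: at the dropped column's peak location the effect is zero
    by construction.
    """
    candidates = [
        (etype, label)
        for (etype, label), term in erps.terms.items()
        if term is not None
        and term.kind in ("spline", "circspline")
        and term.variables == (predictor,)
        and (event_type is None or etype == event_type)
    ]
    if not candidates:
        raise KeyError(f"no spline term for predictor {predictor!r}")
    etype, label = candidates[0]
    bset = erps.spline_bases[etype][label]
    basis = bset.evaluate(np.asarray(values, dtype=float), drop=True)
    courses = erps.courses[(etype, label)]  # (ch, n_local, n_kept)
    return np.einsum("ntj,vj->ntv", courses, basis)


def baseline_correct(erps: ErpSet, window: tuple[float, float]) -> ErpSet:
    """Subtract each course's mean over the baseline window (seconds).

    Applied to the betas after conversion to time-courses; idempotent.
    """
    b0, b1 = window
    if not b0 <= b1:
        raise ValueError("baseline window must satisfy b0 <= b1")
    out = ErpSet(
        effect_labels=dict(erps.effect_labels),
        terms=dict(erps.terms),
        time={k: v.copy() for k, v in erps.time.items()},
        channels=list(erps.channels),
        reference=dict(erps.reference),
        spline_bases=dict(erps.spline_bases),
        srate=erps.srate,
    )
    for (etype, label), course in erps.courses.items():
        t = erps.time[etype]
        mask = (t >= b0) & (t <= b1)
        if len(t) > 1 and not mask.any():
            raise ValueError(
                f"baseline window [{b0}, {b1}] contains no samples of the "
                f"model window for event type {etype!r}"
            )
        if mask.any():
            course = course - course[:, mask, :].mean(axis=1, keepdims=True)
        out.courses[(etype, label)] = course
    return out


def export_long(erps: ErpSet, path) -> pd.DataFrame:
    """Write the rERP set as long-format CSV (12 significant digits).

    One row per (channel, event_type, term, effect_column, time_s,
    beta); reading the file back with :func:`import_long` reproduces the
    set to float precision.
    """
    records = []
    for (etype, term_label), course in erps.courses.items():
        t = erps.time[etype]
        labels = erps.effect_labels[(etype, term_label)]
        for ci, ch in enumerate(erps.channels):
            for j, lab in enumerate(labels):
                for ti, ts in enumerate(t):
                    records.append((ch, etype, term_label, lab, ts, course[ci, ti, j]))
    frame = pd.DataFrame(records, columns=CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.12g")
    return frame


def import_long(path) -> ErpSet:
    """Read a long-format CSV written by :func:`export_long`."""
    frame = pd.read_csv(path, keep_default_na=False, na_values=[], dtype=str)
    frame["time_s"] = frame["time_s"].astype(float)
    frame["beta"] = frame["beta"].astype(float)
    out = ErpSet()
    if frame.empty:
        return out
    out.channels = list(dict.fromkeys(frame["channel"]))
    ch_index = {c: i for i, c in enumerate(out.channels)}
    for (etype, term_label), grp in frame.groupby(
        ["event_type", "term"], sort=False
    ):
        time = np.asarray(sorted(grp["time_s"].unique()))
        labels = list(dict.fromkeys(grp["effect_column"]))
        course = np.zeros((len(out.channels), len(time), len(labels)))
        t_index = {t: i for i, t in enumerate(time)}
        l_index = {l: i for i, l in enumerate(labels)}
        for row in grp.itertuples(index=False):
            course[
                ch_index[row.channel], t_index[row.time_s], l_index[row.effect_column]
            ] = row.beta
        key = (etype, term_label)
        out.courses[key] = course
        out.effect_labels[key] = labels
        out.terms[key] = None
        out.time[etype] = time
    return out
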