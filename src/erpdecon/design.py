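"""Instance-level design matrices: coding, spline bases, imputation.

Builds the per-event-type design matrix ``X`` (rows = event instances,
columns = coded predictors) from an event table and a parsed model.
Non-linear covariate effects are expanded into cubic B-spline bases
(clamped, knots on predictor quantiles), cyclic B-splines for circular
predictors, and tensor-product bases for 2D spline interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .formula import ModelSpec, Term, render_term

__all__ = [
    "SplineBasisSet",
    "DesignMatrix",
    "ColumnInfo",
    "load_events",
    "quantile_knots",
    "bspline_basis",
    "cyclic_spline_basis",
    "tensor_spline_basis",
    "build_design",
    "impute_missing",
]

SPLINE_DEGREE = 3  # cubic


class DegeneratePredictorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def load_events(path, duration: Optional[float] = None) -> pd.DataFrame:
    """Load a BIDS-style event table (TSV/CSV with ``onset``, ``type``).

    Rows are sorted by onset; the original file order is kept in the
    ``orig_index`` column.  ``duration`` (seconds), when given, bounds
    the onsets.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    events = pd.read_csv(path, sep=sep, na_values=["", "NaN", "n/a"])
    return normalize_events(events, duration=duration)


def normalize_events(events: pd.DataFrame, duration=None) -> pd.DataFrame:
    if "onset" not in events.columns:
        raise ValueError("event table must contain an 'onset' column")
    if "type" not in events.columns:
        events = events.copy()
        events["type"] = "event"
    if (events["onset"] < 0).any():
        raise ValueError("event onsets must be non-negative")
    if duration is not None and (events["onset"] >= duration).any():
        raise ValueError("event onset beyond recording duration")
    events = events.copy()
    if "orig_index" not in events.columns:
        events["orig_index"] = np.arange(len(events))
    return events.sort_values("onset", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# spline bases
# ---------------------------------------------------------------------------


def quantile_knots(values, n_basis: int) -> np.ndarray:
    """Quantile-based knot vector for a clamped cubic B-spline basis.

    The knot sequence places ``n_basis - 2`` quantile points of the
    observed predictor values (levels ``linspace(0, 1, n_basis - 2)``,
    so the first and last coincide with the observed min and max) and
    repeats each boundary three more times.  The resulting vector has
    ``n_basis + 4`` entries, hence ``n_basis`` cubic basis functions
    (basis count = knot count − 4).
    """
    if n_basis < 4:
        raise ValueError(
            "cubic B-spline terms need n_basis >= 4 "
            "(a clamped cubic basis has at least 4 functions)"
        )
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if np.unique(vals).size < n_basis:
        raise DegeneratePredictorError(
            f"need at least {n_basis} distinct finite values, "
            f"got {np.unique(vals).size}"
        )
    levels = np.linspace(0.0, 1.0, n_basis - 2)
    q = np.quantile(vals, levels)  # linear-interpolation quantiles
    knots = np.concatenate([[q[0]] * 3, q, [q[-1]] * 3])
    if np.any(np.diff(knots) < 0):
        raise AssertionError("knots must be nondecreasing")
    return knots


def bspline_basis(values, knots) -> np.ndarray:
    """Evaluate the clamped cubic B-spline basis at ``values``.

    Values outside the boundary knots are clamped to the nearest
    boundary (no extrapolation).  Returns a dense (points × n_basis)
    matrix; rows sum to 1 and each row has at most 4 nonzeros.
    """
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) < 0):
        raise ValueError("knot vector must be nondecreasing")
    x = np.clip(np.asarray(values, dtype=float), knots[0], knots[-1])
    mat = BSpline.design_matrix(x, knots, SPLINE_DEGREE, extrapolate=False)
    return np.asarray(mat.todense())


def cyclic_spline_basis(values, n_basis: int, lo: float, hi: float) -> np.ndarray:
    """Periodic (cyclic) cubic B-spline basis on uniform knots.

    Values are wrapped into ``[lo, hi)``; the basis is built from
    uniformly spaced knots extended past both bounds, with columns
    folded modulo ``n_basis`` so that ``basis(lo) == basis(hi)``
    row-wise.  Partition of unity holds everywhere.
    """
    if not lo < hi:
        raise ValueError("cyclic bounds must satisfy lo < hi")
    if n_basis < 3:
        raise ValueError("cyclic cubic splines need n_basis >= 3")
    period = hi - lo
    x = lo + np.mod(np.asarray(values, dtype=float) - lo, period)
    h = period / n_basis
    ext_knots = lo + h * np.arange(-3, n_basis + 4)
    full = BSpline.design_matrix(x, ext_knots, SPLINE_DEGREE, extrapolate=False)
    full = np.asarray(full.todense())  # points × (n_basis + 3)
    out = np.zeros((len(x), n_basis))
    for i in range(full.shape[1]):
        out[:, i % n_basis] += full[:, i]
    return out


def tensor_spline_basis(values_a, values_b, basis_a, basis_b) -> np.ndarray:
    """Tensor-product basis: pairwise products of two 1D spline bases.

    ``basis_a``/``basis_b`` are (points × n) matrices evaluated at the
    same points; column ``(j, k)`` of the result (index ``j*n_b + k``)
    is the elementwise product of column ``j`` of A and ``k`` of B.
    """
    a = np.asarray(basis_a, dtype=float)
    b = np.asarray(basis_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("margins must be evaluated at the same points")
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


@dataclass
class SplineBasisSet:
    """A fitted 1D spline basis: knots, kind, and identifiability bookkeeping.

    ``dropped`` is the index of the basis column removed when the model
    contains an intercept (the basis sums to one, so the full set is
    collinear with it).
    """

    kind: str  # {"bspline", "cyclic"}
    n_basis: int
    knots: Optional[np.ndarray] = None
    cycle_bounds: Optional[tuple[float, float]] = None
    dropped: Optional[int] = None

    def evaluate(self, values, drop: bool = True) -> np.ndarray:
        if self.kind == "bspline":
            mat = bspline_basis(values, self.knots)
        elif self.kind == "cyclic":
            lo, hi = self.cycle_bounds
            mat = cyclic_spline_basis(values, self.n_basis, lo, hi)
        else:
            raise ValueError(f"unknown spline kind {self.kind!r}")
        if drop and self.dropped is not None:
            mat = np.delete(mat, self.dropped, axis=1)
        return mat

    def domain(self) -> tuple[float, float]:
        if self.kind == "bspline":
            return float(self.knots[0]), float(self.knots[-1])
        return self.cycle_bounds

    def peak_locations(self, n_grid: int = 2001) -> np.ndarray:
        """Argmax location of each basis function on a fine grid."""
        lo, hi = self.domain()
        grid = np.linspace(lo, hi, n_grid)
        mat = self.evaluate(grid, drop=False)
        return grid[np.argmax(mat, axis=0)]


def _pick_drop_index(basis_set: SplineBasisSet, values) -> int:
    """Basis column to drop for identifiability: peak nearest the median."""
    med = np.nanmedian(np.asarray(values, dtype=float))
    peaks = basis_set.peak_locations()
    return int(np.argmin(np.abs(peaks - med)))


# ---------------------------------------------------------------------------
# design matrix assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnInfo:
    term: Term
    label: str  # human-readable column label
    index_in_term: int  # position within the term's column block


@dataclass
class DesignMatrix:
    """Dense instance-level design matrix with column metadata."""

    values: np.ndarray  # (n_instances, n_columns)
    columns: list[ColumnInfo]
    spline_bases: dict[str, object] = field(default_factory=dict)
    levels: dict[str, list[str]] = field(default_factory=dict)
    reference: dict[str, str] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def column_labels(self) -> list[str]:
        return [c.label for c in self.columns]

    def term_slice(self, term: Term) -> slice:
        idx = [i for i, c in enumerate(self.columns) if c.term == term]
        if not idx:
            raise KeyError(f"term {render_term(term)} not in design")
        return slice(idx[0], idx[-1] + 1)


def _categorical_columns(col: pd.Series, var: str, coding: str, reference):
    levels = sorted(map(str, col.dropna().unique()))
    if len(levels) < 2:
        raise DegeneratePredictorError(
            f"categorical predictor {var!r} has fewer than 2 levels"
        )
    vals = col.astype(str).to_numpy()
    if coding == "treatment":
        ref = str(reference) if reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among levels of {var!r}")
        others = [lv for lv in levels if lv != ref]
        mat = np.column_stack([(vals == lv).astype(float) for lv in others])
        labels = [f"{var}[{lv}]" for lv in others]
        return mat, labels, levels, ref
    # effects (sum-to-zero) coding: alphabetically last level is the -1 row
    base = levels[-1]
    others = levels[:-1]
    mat = np.zeros((len(vals), len(others)))
    for j, lv in enumerate(others):
        mat[vals == lv, j] = 1.0
    mat[vals == base, :] = -1.0
    labels = [f"{var}[{lv}]" for lv in others]
    return mat, labels, levels, base


def _atom_columns(term: Term, events: pd.DataFrame, spec: ModelSpec):
    """Coded columns for an atomic (non-spline) term, used by interactions."""
    var = term.variables[0]
    if term.kind == "continuous":
        return events[var].to_numpy(dtype=float)[:, None], [var]
    coding = term.coding or "treatment"
    mat, labels, _, _ = _categorical_columns(
        events[var], var, coding, spec.reference_levels.get(var)
    )
    return mat, labels


def build_design(events: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Assemble the instance-level design matrix for one event type.

    Treatment coding uses L−1 indicators against the (alphabetical or
    user-set) reference level; effects coding uses sum-to-zero
    contrasts.  Continuous predictors pass through uncentered.  Spline
    terms are expanded through their basis, with one basis column
    removed when an intercept is present (the column whose peak lies
    closest to the predictor's median).  Interaction columns are
    elementwise products of the parents' coded columns.
    """
    n = len(events)
    has_intercept = any(t.kind == "intercept" for t in spec.terms)
    blocks: list[np.ndarray] = []
    columns: list[ColumnInfo] = []
    spline_bases: dict[str, object] = {}
    levels: dict[str, list[str]] = {}
    reference: dict[str, str] = {}

    for term in spec.terms:
        if term.kind == "intercept":
            block, labels = np.ones((n, 1)), ["intercept"]
        elif term.kind == "continuous":
            block = events[term.variables[0]].to_numpy(dtype=float)[:, None]
            labels = [term.variables[0]]
        elif term.kind == "categorical":
            var = term.variables[0]
            block, labels, lvls, ref = _categorical_columns(
                events[var],
                var,
                term.coding or "treatment",
                spec.reference_levels.get(var),
            )
            levels[var] = lvls
            reference[var] = ref
        elif term.kind == "spline":
            var = term.variables[0]
            vals = events[var].to_numpy(dtype=float)
            bset = SplineBasisSet(
                "bspline", term.n_basis, knots=quantile_knots(vals, term.n_basis)
            )
            if has_intercept:
                bset.dropped = _pick_drop_index(bset, vals)
            block = bset.evaluate(vals)
            kept = [j for j in range(term.n_basis) if j != bset.dropped]
            labels = [f"spl({var})[{j}]" for j in kept]
            spline_bases[render_term(term)] = bset
        elif term.kind == "circspline":
            var = term.variables[0]
            lo, hi = term.cycle_bounds
            vals = events[var].to_numpy(dtype=float)
            bset = SplineBasisSet(
                "cyclic", term.n_basis, cycle_bounds=(float(lo), float(hi))
            )
            if has_intercept:
                period = hi - lo
                wrapped = lo + np.mod(vals - lo, period)
                bset.dropped = _pick_drop_index(bset, wrapped)
            block = bset.evaluate(vals)
            kept = [j for j in range(term.n_basis) if j != bset.dropped]
            labels = [f"circspl({var})[{j}]" for j in kept]
            spline_bases[render_term(term)] = bset
        elif term.kind == "spline2d":
            va, vb = term.variables
            xa = events[va].to_numpy(dtype=float)
            xb = events[vb].to_numpy(dtype=float)
            set_a = SplineBasisSet(
                "bspline", term.n_basis, knots=quantile_knots(xa, term.n_basis)
            )
            set_b = SplineBasisSet(
                "bspline", term.n_basis, knots=quantile_knots(xb, term.n_basis)
            )
            block = tensor_spline_basis(
                xa, xb, set_a.evaluate(xa, drop=False), set_b.evaluate(xb, drop=False)
            )
            dropped = None
            if has_intercept:
                ja = _pick_drop_index(set_a, xa)
                jb = _pick_drop_index(set_b, xb)
                dropped = ja * term.n_basis + jb
                block = np.delete(block, dropped, axis=1)
            kept = [j for j in range(term.n_basis**2) if j != dropped]
            labels = [
                f"2dspl({va},{vb})[{j // term.n_basis},{j % term.n_basis}]"
                for j in kept
            ]
            spline_bases[render_term(term)] = (set_a, set_b, dropped)
        elif term.kind == "interaction":
            pk = term.parent_kinds or ("continuous", "continuous")
            pa = Term(pk[0], (term.variables[0],), coding=spec.coding
                      if pk[0] == "categorical" else None)
            pb = Term(pk[1], (term.variables[1],), coding=spec.coding
                      if pk[1] == "categorical" else None)
            mat_a, lab_a = _atom_columns(pa, events, spec)
            mat_b, lab_b = _atom_columns(pb, events, spec)
            block = (mat_a[:, :, None] * mat_b[:, None, :]).reshape(n, -1)
            labels = [f"{la}:{lb}" for la in lab_a for lb in lab_b]
        else:
            raise AssertionError(term.kind)

        if np.isnan(block).any():
            raise ValueError(
                f"NaN in design columns for term {render_term(term)}; "
                "run impute_missing first"
            )
        for j in range(block.shape[1]):
            if not np.any(block[:, j]):
                warnings.warn(
                    f"design column {labels[j]!r} is all zeros", stacklevel=2
                )
        blocks.append(block)
        columns.extend(
            ColumnInfo(term, lab, j) for j, lab in enumerate(labels)
        )

    if not blocks:
        raise ValueError("model has no terms")
    return DesignMatrix(
        values=np.hstack(blocks),
        columns=columns,
        spline_bases=spline_bases,
        levels=levels,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# missing values
# ---------------------------------------------------------------------------


def impute_missing(
    events: pd.DataFrame,
    method: str = "mean",
    seed: Optional[int] = None,
    columns: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Treat missing predictor values before design assembly.

    ``drop`` removes the whole event instance (warning: its overlap
    contribution to neighbouring events is then unmodelled); ``mean``
    and ``median`` replace NaN with the column statistic over
    non-missing rows of the same event type; ``marginal`` draws a
    uniform random replacement from the observed values of that column
    (seeded).
    """
    if method not in ("drop", "mean", "median", "marginal"):
        raise ValueError(f"unknown imputation method {method!r}")
    if method == "marginal" and seed is None:
        raise ValueError("marginal imputation requires a seed")
    out = events.copy()
    predictors = columns or [
        c for c in out.columns if c not in ("onset", "type", "orig_index")
    ]
    if method == "drop":
        mask = out[predictors].isna().any(axis=1)
        if mask.any():
            warnings.warn(
                f"dropping {int(mask.sum())} event(s) with missing predictors; "
                "their overlap contribution is no longer modelled",
                stacklevel=2,
            )
        return out[~mask].reset_index(drop=True)

    rng = np.random.default_rng(seed)
    for etype, idx in out.groupby("type").groups.items():
        for col in predictors:
            series = out.loc[idx, col]
            missing = series.isna()
            if not missing.any():
                continue
            observed = series.dropna()
            if observed.empty:
                raise ValueError(
                    f"column {col!r} of event type {etype!r} is entirely "
                    "missing and cannot be imputed"
                )
            if method == "marginal":
                fill = rng.choice(observed.to_numpy(), size=int(missing.sum()))
                out.loc[series.index[missing], col] = fill
            else:
                if not pd.api.types.is_numeric_dtype(series):
                    raise ValueError(
                        f"{method} imputation needs a numeric column, "
                        f"{col!r} is {series.dtype}"
                    )
                stat = observed.mean() if method == "mean" else observed.median()
                out.loc[series.index[missing], col] = stat
    return out
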