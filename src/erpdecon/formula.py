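"""Wilkinson-notation model formulas for event-related regression.

A model is written as ``y ~ 1 + cat(condition) + luminance + spl(size, 5)``.
The left-hand side is accepted and ignored (the response is always the
recorded data).  Term functions:

``cat(name)``
    categorical predictor (treatment coding by default).
``spl(name, n)``
    non-linear effect via ``n`` cubic B-spline basis functions.
``2dspl(a, b, n)``
    tensor-product spline interaction between two continuous predictors
    (``n`` basis functions per margin, ``n**2`` columns).
``circspl(name, n, lo, hi)``
    cyclic (periodic) spline for circular predictors such as angles;
    ``lo``/``hi`` are the wrapping bounds.

``a*b`` expands to ``a + b + a:b``; ``a:b`` is the interaction alone.
A leading ``1`` is the intercept (implied when neither ``1`` nor ``0``
is written); ``0 +`` suppresses it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Term",
    "ModelSpec",
    "FormulaError",
    "parse_formula",
    "render_terms",
    "validate_spec",
]

TERM_KINDS = {
    "intercept",
    "categorical",
    "continuous",
    "spline",
    "spline2d",
    "circspline",
    "interaction",
}


class FormulaError(ValueError):
    """Raised for malformed formulas; carries the offending position."""

    def __init__(self, message: str, position: Optional[int] = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Term:
    """One additive term of a model formula."""

    kind: str
    variables: tuple[str, ...] = ()
    n_basis: Optional[int] = None
    cycle_bounds: Optional[tuple[float, float]] = None
    coding: Optional[str] = None
    # for interactions: kinds of the two parents, in variable order
    parent_kinds: Optional[tuple[str, str]] = None

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise FormulaError(f"unknown term kind {self.kind!r}")
        if self.kind in ("spline", "spline2d", "circspline"):
            if self.n_basis is None or self.n_basis < 2:
                raise FormulaError("spline terms need n_basis >= 2")
        elif self.n_basis is not None:
            raise FormulaError(f"{self.kind} term cannot carry n_basis")
        if self.kind == "circspline":
            lo, hi = self.cycle_bounds
            if not lo < hi:
                raise FormulaError("circspl bounds must satisfy lo < hi")
        elif self.cycle_bounds is not None:
            raise FormulaError("cycle_bounds only valid for circspl terms")
        if self.kind == "interaction" and len(set(self.variables)) != len(
            self.variables
        ):
            raise FormulaError("interaction variables must be distinct")

    @property
    def label(self) -> str:
        return render_term(self)


@dataclass
class ModelSpec:
    """Model definition for one event type."""

    formula: str
    window: tuple[float, float]
    basis: "object" = None  # TemporalBasis; default stick, resolved downstream
    reference_levels: dict[str, str] = field(default_factory=dict)
    coding: str = "treatment"
    terms: list[Term] = field(default_factory=list)

    def __post_init__(self):
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy tau_min < tau_max")
        if self.coding not in ("treatment", "effects"):
            raise ValueError("coding must be 'treatment' or 'effects'")
        if not self.terms:
            self.terms = parse_formula(self.formula)
        if self.coding != "treatment":
            self.terms = [
                replace(t, coding=self.coding) if t.kind == "categorical" else t
                for t in self.terms
            ]


# ---------------------------------------------------------------------------
# tokenizer / parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>[0-9]+(?:\.[0-9]+)?)|(?P<name>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op>[~+*:(),-]))"
)

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*$")


def _tokenize(text: str):
    tokens = []  # (kind, value, position)
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        # "2dspl" starts with a digit; special-case it before number matching
        if text.startswith("2dspl", pos):
            tokens.append(("name", "2dspl", pos))
            pos += 5
            continue
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FormulaError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num"), m.start("num")))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name"), m.start("name")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


def _split_top(tokens, seps):
    """Split a token list on top-level (outside parentheses) operators."""
    parts, current, depth = [], [], 0
    for tok in tokens:
        kind, val, _ = tok
        if kind == "op" and val == "(":
            depth += 1
        elif kind == "op" and val == ")":
            depth -= 1
        if depth == 0 and kind == "op" and val in seps:
            parts.append((current, val))
            current = []
        else:
            current.append(tok)
    parts.append((current, None))
    return parts


def _parse_number(tok, what):
    kind, val, pos = tok
    if kind != "num" and not (kind == "op" and val == "-"):
        raise FormulaError(f"expected {what}", pos)
    return val


def _parse_atom(tokens) -> Optional[Term]:
    """Parse one atomic term (no + * :). Returns None for '0'."""
    if not tokens:
        raise FormulaError("empty term")
    kind, val, pos = tokens[0]
    if kind == "num":
        if len(tokens) > 1:
            raise FormulaError("unexpected tokens after numeric term", tokens[1][2])
        if val == "1":
            return Term("intercept")
        if val == "0":
            return None
        raise FormulaError(f"numeric term must be 0 or 1, got {val}", pos)
    if kind != "name":
        raise FormulaError("expected predictor name or term function", pos)
    if len(tokens) == 1:
        return Term("continuous", (val,))
    # function call form
    if not (tokens[1][0] == "op" and tokens[1][1] == "("):
        raise FormulaError("malformed term", tokens[1][2])
    if not (tokens[-1][0] == "op" and tokens[-1][1] == ")"):
        raise FormulaError("unbalanced parentheses", tokens[-1][2])
    inner = tokens[2:-1]
    args = [part for part, _ in _split_top(inner, {","})]
    fn = val

    def arg_name(i):
        a = args[i]
        if len(a) != 1 or a[0][0] != "name":
            raise FormulaError(
                f"argument {i + 1} of {fn}() must be a predictor name",
                a[0][2] if a else pos,
            )
        return a[0][1]

    def arg_num(i, integer=False):
        a = args[i]
        text = "".join(t[1] for t in a)
        try:
            return int(text) if integer else float(text)
        except ValueError:
            raise FormulaError(
                f"argument {i + 1} of {fn}() must be a number", a[0][2] if a else pos
            ) from None

    if fn == "cat":
        if len(args) != 1:
            raise FormulaError("cat() takes one argument", pos)
        return Term("categorical", (arg_name(0),), coding="treatment")
    if fn == "spl":
        if len(args) != 2:
            raise FormulaError("spl() takes (name, n_basis)", pos)
        return Term("spline", (arg_name(0),), n_basis=arg_num(1, integer=True))
    if fn == "2dspl":
        if len(args) != 3:
            raise FormulaError("2dspl() takes (a, b, n_basis)", pos)
        return Term(
            "spline2d", (arg_name(0), arg_name(1)), n_basis=arg_num(2, integer=True)
        )
    if fn == "circspl":
        if len(args) != 4:
            raise FormulaError("circspl() takes (name, n_basis, lo, hi)", pos)
        return Term(
            "circspline",
            (arg_name(0),),
            n_basis=arg_num(1, integer=True),
            cycle_bounds=(arg_num(2), arg_num(3)),
        )
    raise FormulaError(f"unknown term function {fn}()", pos)


_SPLINE_KINDS = ("spline", "spline2d", "circspline")


def _make_interaction(a: Term, b: Term) -> Term:
    for t in (a, b):
        if t.kind in _SPLINE_KINDS:
            raise FormulaError(
                "spline terms may not appear in * or : interactions; "
                "use 2dspl() for non-linear interactions"
            )
        if t.kind in ("intercept", "interaction"):
            raise FormulaError(f"cannot interact with {t.kind} term")
    return Term(
        "interaction",
        (a.variables[0], b.variables[0]),
        parent_kinds=(a.kind, b.kind),
    )


def parse_formula(text: str) -> list[Term]:
    """Parse a Wilkinson formula into a list of :class:`Term`.

    Terms come back in left-to-right order; ``a*b`` expands to
    ``a + b + a:b``.  Duplicate terms raise :class:`FormulaError`.
    """
    tokens = _tokenize(text)
    sides = _split_top(tokens, {"~"})
    if len(sides) != 2:
        raise FormulaError("formula must contain exactly one '~'")
    rhs = sides[1][0]
    if not rhs:
        raise FormulaError("empty right-hand side")

    terms: list[Term] = []
    explicit_zero = False
    saw_explicit_intercept = False
    chunks = _split_top(rhs, {"+"})
    for idx, (chunk, _) in enumerate(chunks):
        if not chunk:
            raise FormulaError("empty term between '+' operators")
        if len(chunk) == 1 and chunk[0][0] == "num" and chunk[0][1] == "0":
            if idx != 0:
                raise FormulaError("'0' (no intercept) must come first", chunk[0][2])
            explicit_zero = True
            continue
        factors = _split_top(chunk, {"*", ":"})
        if len(factors) == 1:
            atom = _parse_atom(chunk)
            if atom is None:
                raise FormulaError("'0' must stand alone as the first term")
            if atom.kind == "intercept":
                saw_explicit_intercept = True
            terms.append(atom)
        elif len(factors) == 2:
            (ta, op), (tb, _) = factors
            a, b = _parse_atom(ta), _parse_atom(tb)
            if a is None or b is None:
                raise FormulaError("'0' cannot appear in an interaction")
            if op == "*":
                terms.extend([a, b, _make_interaction(a, b)])
            else:
                terms.append(_make_interaction(a, b))
        else:
            raise FormulaError(
                "only pairwise interactions are supported", chunk[0][2]
            )

    if explicit_zero and saw_explicit_intercept:
        raise FormulaError("formula contains both '0' and '1'")
    if not explicit_zero and not saw_explicit_intercept:
        terms.insert(0, Term("intercept"))

    # duplicates (interactions compared orderless)
    seen = set()
    for t in terms:
        key = (t.kind, frozenset(t.variables), t.n_basis, t.cycle_bounds)
        if key in seen:
            raise FormulaError(f"duplicate term: {render_term(t)}")
        seen.add(key)

    # cat() and spl() wrapping the same predictor is a conflict, not a model
    by_var: dict[str, set[str]] = {}
    for t in terms:
        for v in t.variables:
            by_var.setdefault(v, set()).add(t.kind)
    for v, kinds in by_var.items():
        nonlin = kinds & set(_SPLINE_KINDS)
        if nonlin and (kinds - set(_SPLINE_KINDS) - {"interaction"}):
            raise FormulaError(
                f"predictor {v!r} appears both as a spline and a "
                "linear/categorical term"
            )
    return terms


def render_term(term: Term) -> str:
    if term.kind == "intercept":
        return "1"
    if term.kind == "continuous":
        return term.variables[0]
    if term.kind == "categorical":
        return f"cat({term.variables[0]})"
    if term.kind == "spline":
        return f"spl({term.variables[0]},{term.n_basis})"
    if term.kind == "spline2d":
        return f"2dspl({term.variables[0]},{term.variables[1]},{term.n_basis})"
    if term.kind == "circspline":
        lo, hi = term.cycle_bounds
        return f"circspl({term.variables[0]},{term.n_basis},{lo:g},{hi:g})"
    if term.kind == "interaction":
        parts = []
        for v, k in zip(term.variables, term.parent_kinds or ("continuous",) * 2):
            parts.append(f"cat({v})" if k == "categorical" else v)
        return ":".join(parts)
    raise AssertionError(term.kind)


def render_terms(terms: list[Term]) -> str:
    """Render a term list back to canonical formula text (round-trips)."""
    has_intercept = any(t.kind == "intercept" for t in terms)
    rest = [render_term(t) for t in terms if t.kind != "intercept"]
    head = "1" if has_intercept else "0"
    return "y ~ " + " + ".join([head] + rest)


# ---------------------------------------------------------------------------
# validation against an event table
# ---------------------------------------------------------------------------


def validate_spec(spec: ModelSpec, events) -> list[str]:
    """Check a parsed model against an event table; returns diagnostics.

    An empty list means the model can be built.  The event table is a
    pandas DataFrame restricted to one event type.  Inputs are never
    mutated.
    """
    import pandas as pd

    diagnostics: list[str] = []
    for term in spec.terms:
        for var in term.variables:
            if var not in events.columns:
                diagnostics.append(
                    f"term {render_term(term)}: predictor {var!r} not found "
                    "in the event table"
                )
                continue
            col = events[var]
            if term.kind == "categorical":
                if col.dropna().nunique() < 2:
                    diagnostics.append(
                        f"term {render_term(term)}: categorical predictor "
                        f"{var!r} has fewer than 2 levels"
                    )
            elif term.kind in ("continuous",) + _SPLINE_KINDS:
                if not pd.api.types.is_numeric_dtype(col):
                    diagnostics.append(
                        f"term {render_term(term)}: predictor {var!r} must be "
                        f"numeric, got dtype {col.dtype}"
                    )
                elif term.kind in _SPLINE_KINDS:
                    nuniq = col.dropna().nunique()
                    if term.n_basis is not None and nuniq < term.n_basis:
                        diagnostics.append(
                            f"term {render_term(term)}: only {nuniq} distinct "
                            f"values for {var!r}, fewer than n_basis="
                            f"{term.n_basis}"
                        )
    return diagnostics
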