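"""Model terms and design-matrix construction.

A model's systematic part is an ordered list of :class:`Term` descriptors:

* ``linear("x")``              -- numeric predictor, one column
* ``factor("f")``              -- categorical predictor, treatment coding
* ``interaction("a", "b")``    -- product of the parametric codings
* ``smooth("x", k=10)``        -- penalized cubic B-spline (P-spline)
* ``smooth_interaction("x", "f")`` -- difference smoother (numeric by factor)
  or tensor-product interaction smooth (numeric by numeric)

Smooth blocks carry sum-to-zero constraints so they are identifiable next to
the intercept and main effects, and each block owns one or two quadratic
penalty matrices (second-order coefficient differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space

TERM_KINDS = ("linear", "factor", "interaction", "smooth", "smooth_interaction")

# domain padding for spline bases: forward-difference steps taken at the top
# of the observed range must stay evaluable
_PAD = 0.02


@dataclass(frozen=True)
class Term:
    kind: str
    columns: tuple[str, ...]
    k: int = 10

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind in ("linear", "factor", "smooth") and len(self.columns) != 1:
            raise ValueError(f"{self.kind} term takes exactly one column")
        if self.kind == "smooth_interaction" and len(self.columns) != 2:
            raise ValueError("smooth_interaction takes exactly two columns")

    @property
    def label(self) -> str:
        inner = ",".join(self.columns)
        return {"linear": inner, "factor": inner,
                "interaction": ":".join(self.columns),
                "smooth": f"s({inner})",
                "smooth_interaction": f"s({inner})"}[self.kind]


def linear(column: str) -> Term:
    return Term("linear", (column,))


def factor(column: str) -> Term:
    return Term("factor", (column,))


def interaction(*columns: str) -> Term:
    if len(columns) < 2:
        raise ValueError("interaction needs at least two columns")
    return Term("interaction", tuple(columns))


def smooth(column: str, k: int = 10) -> Term:
    return Term("smooth", (column,), k)


def smooth_interaction(col_a: str, col_b: str, k: int = 5) -> Term:
    return Term("smooth_interaction", (col_a, col_b), k)


class UnseenLevelError(ValueError):
    """A factor level at prediction time that was absent from the training data."""


def _bspline_knots(x: np.ndarray, k: int) -> np.ndarray:
    """Clamped cubic knot vector giving exactly k basis functions."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo if hi > lo else 1.0
    lo -= _PAD * span
    hi += _PAD * span
    if k < 4:
        raise ValueError("spline basis needs k >= 4")
    inner = np.linspace(lo, hi, k - 2)
    return np.concatenate([[lo] * 3, inner, [hi] * 3])


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[0], knots[-1]
    xc = np.clip(np.asarray(x, float), lo, hi)
    return BSpline.design_matrix(xc, knots, 3).toarray()


def _difference_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


@dataclass
class _Block:
    """One fitted term: columns of the design plus optional penalties."""
    term: Term
    names: list[str]
    # encoding state
    levels: dict[str, list] = field(default_factory=dict)
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    constraint: np.ndarray | None = None   # k x (k-1) null-space basis
    penalties: list[np.ndarray] = field(default_factory=list)  # on final coords
    by_level: object = None                # difference-smooth level


class DesignBuilder:
    """Encodes rows into a fixed-width design matrix.

    Factor levels, spline knots and identifiability constraints are frozen
    against the training table so that predictions at new rows are exact
    linear functionals of the fitted coefficients.
    """

    def __init__(self, terms: Sequence[Term], data: pd.DataFrame):
        self.terms = list(terms)
        self._blocks: list[_Block] = []
        self.column_names: list[str] = ["(Intercept)"]
        self._slices: list[slice] = []
        start = 1
        for term in self.terms:
            for block in self._fit_term(term, data):
                width = len(block.names)
                self._blocks.append(block)
                self._slices.append(slice(start, start + width))
                self.column_names.extend(block.names)
                start += width
        self.n_coef = start

    # -- fitting the encodings -------------------------------------------

    def _levels(self, data: pd.DataFrame, col: str) -> list:
        return sorted(pd.unique(data[col]).tolist())

    def _fit_term(self, term: Term, data: pd.DataFrame) -> list[_Block]:
        for col in term.columns:
            if col not in data.columns:
                raise ValueError(f"column {col!r} missing from data")
        if term.kind == "linear":
            return [_Block(term, [term.columns[0]])]
        if term.kind == "factor":
            col = term.columns[0]
            levels = self._levels(data, col)
            names = [f"{col}[{lv}]" for lv in levels[1:]]
            return [_Block(term, names, levels={col: levels})]
        if term.kind == "interaction":
            levels = {c: self._levels(data, c)
                      for c in term.columns if not _is_numeric(data[c])}
            names = self._interaction_names(term, levels)
            return [_Block(term, names, levels=levels)]
        if term.kind == "smooth":
            return [self._fit_smooth(term, data)]
        return self._fit_smooth_interaction(term, data)

    def _interaction_names(self, term: Term, levels: dict) -> list[str]:
        parts: list[list[str]] = []
        for c in term.columns:
            if c in levels:
                parts.append([f"{c}[{lv}]" for lv in levels[c][1:]])
            else:
                parts.append([c])
        names = [""]
        for p in parts:
            names = [f"{a}:{b}" if a else b for a in names for b in p]
        return names

    def _fit_smooth(self, term: Term, data: pd.DataFrame) -> _Block:
        col = term.columns[0]
        x = data[col].to_numpy(float)
        knots = _bspline_knots(x, term.k)
        B = _bspline_design(x, knots)
        constraint = null_space(B.sum(axis=0)[None, :])
        S = constraint.T @ _difference_penalty(term.k) @ constraint
        names = [f"s({col}).{i}" for i in range(constraint.shape[1])]
        return _Block(term, names, knots={col: knots},
                      constraint=constraint, penalties=[S])

    def _fit_smooth_interaction(self, term: Term, data: pd.DataFrame) -> list[_Block]:
        a, b = term.columns
        num_a, num_b = _is_numeric(data[a]), _is_numeric(data[b])
        if num_a and num_b:
            return [self._fit_tensor(term, data)]
        if num_a == num_b:
            raise ValueError("smooth_interaction of two factors is not defined; "
                             "use interaction()")
        xcol, fcol = (a, b) if num_a else (b, a)
        levels = self._levels(data, fcol)
        x = data[xcol].to_numpy(float)
        knots = _bspline_knots(x, term.k)
        blocks = []
        # one difference smoother per non-reference level: the deviation of
        # that level's curve from the reference curve
        for lv in levels[1:]:
            mask = (data[fcol] == lv).to_numpy()
            B = _bspline_design(x[mask], knots)
            constraint = null_space(B.sum(axis=0)[None, :])
            S = constraint.T @ _difference_penalty(term.k) @ constraint
            names = [f"s({xcol}):{fcol}[{lv}].{i}"
                     for i in range(constraint.shape[1])]
            blocks.append(_Block(term, names, levels={fcol: levels},
                                 knots={xcol: knots}, constraint=constraint,
                                 penalties=[S], by_level=lv))
        return blocks

    def _fit_tensor(self, term: Term, data: pd.DataFrame) -> _Block:
        a, b = term.columns
        ka = kb = term.k
        knots_a = _bspline_knots(data[a].to_numpy(float), ka)
        knots_b = _bspline_knots(data[b].to_numpy(float), kb)
        Ba = _bspline_design(data[a].to_numpy(float), knots_a)
        Bb = _bspline_design(data[b].to_numpy(float), knots_b)
        Qa = null_space(Ba.sum(axis=0)[None, :])
        Qb = null_space(Bb.sum(axis=0)[None, :])
        Sa = Qa.T @ _difference_penalty(ka) @ Qa
        Sb = Qb.T @ _difference_penalty(kb) @ Qb
        pa, pb = Qa.shape[1], Qb.shape[1]
        # marginal roughness penalties on the tensor coefficients
        P1 = np.kron(Sa, np.eye(pb))
        P2 = np.kron(np.eye(pa), Sb)
        names = [f"s({a},{b}).{i}" for i in range(pa * pb)]
        block = _Block(term, names, knots={a: knots_a, b: knots_b},
                       penalties=[P1, P2])
        block.constraint = None
        block._tensor = (Qa, Qb)  # type: ignore[attr-defined]
        return block

    # -- building --------------------------------------------------------

    def build(self, rows: pd.DataFrame) -> np.ndarray:
        rows = pd.DataFrame(rows)
        n = len(rows)
        X = np.zeros((n, self.n_coef))
        X[:, 0] = 1.0
        for block, sl in zip(self._blocks, self._slices):
            X[:, sl] = self._build_block(block, rows)
        return X

    def _codings(self, block: _Block, rows: pd.DataFrame, col: str) -> np.ndarray:
        if col in block.levels:
            levels = block.levels[col]
            vals = rows[col]
            unseen = set(pd.unique(vals)) - set(levels)
            if unseen:
                raise UnseenLevelError(
                    f"factor {col!r} has unseen level(s) {sorted(unseen)!r}")
            return np.column_stack([(vals == lv).to_numpy(float)
                                    for lv in levels[1:]])
        return rows[col].to_numpy(float)[:, None]

    def _build_block(self, block: _Block, rows: pd.DataFrame) -> np.ndarray:
        term = block.term
        for col in term.columns:
            if col not in rows.columns:
                raise ValueError(f"column {col!r} missing from prediction rows")
        if term.kind in ("linear", "factor"):
            return self._codings(block, rows, term.columns[0])
        if term.kind == "interaction":
            out = np.ones((len(rows), 1))
            for c in term.columns:
                cc = self._codings(block, rows, c)
                out = (out[:, :, None] * cc[:, None, :]).reshape(len(rows), -1)
            return out
        if term.kind == "smooth":
            col = term.columns[0]
            B = _bspline_design(rows[col].to_numpy(float), block.knots[col])
            return B @ block.constraint
        # smooth_interaction
        if block.by_level is not None:
            (xcol,) = block.knots.keys()
            fcol = [c for c in term.columns if c != xcol][0]
            vals = rows[fcol]
            unseen = set(pd.unique(vals)) - set(block.levels[fcol])
            if unseen:
                raise UnseenLevelError(
                    f"factor {fcol!r} has unseen level(s) {sorted(unseen)!r}")
            ind = (vals == block.by_level).to_numpy(float)
            B = _bspline_design(rows[xcol].to_numpy(float), block.knots[xcol])
            return ind[:, None] * (B @ block.constraint)
        Qa, Qb = block._tensor  # type: ignore[attr-defined]
        a, b = term.columns
        Za = _bspline_design(rows[a].to_numpy(float), block.knots[a]) @ Qa
        Zb = _bspline_design(rows[b].to_numpy(float), block.knots[b]) @ Qb
        return (Za[:, :, None] * Zb[:, None, :]).reshape(len(rows), -1)

    # -- penalties -------------------------------------------------------

    def penalty_matrices(self) -> list[tuple[slice, np.ndarray, str]]:
        """(coefficient slice, penalty on that slice, label) per smoothing parameter."""
        out = []
        for block, sl in zip(self._blocks, self._slices):
            for i, S in enumerate(block.penalties):
                suffix = f".pen{i}" if len(block.penalties) > 1 else ""
                lbl = block.names[0].rsplit(".", 1)[0] + suffix
                out.append((sl, S, lbl))
        return out

    @property
    def has_smooths(self) -> bool:
        return any(b.penalties for b in self._blocks)

    def term_slices(self) -> dict[str, list[slice]]:
        out: dict[str, list[slice]] = {}
        for block, sl in zip(self._blocks, self._slices):
            out.setdefault(block.term.label, []).append(sl)
        return out


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s)
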