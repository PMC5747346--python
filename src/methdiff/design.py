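"""Observation-level design matrices and test contrasts.

For an experiment with *n* DNA samples and a sample-level design with *k*
columns, every sample contributes two observations (its Me and its Un
count), and the observation-level design has 2n rows and n + k columns.
The first n columns are per-sample indicators that absorb the read
coverage of each sample; the remaining k columns apply the sample-level
design to the Me rows only, so those coefficients measure base-2 logit
methylation levels (log ratios of methylated to unmethylated reads) per
condition.  Because inference on the condition block conditions on total
coverage, the model is an over-dispersed analogue of logistic binomial
regression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ObservationDesign", "expand_design", "design_from_groups", "make_contrast", "make_contrasts"]


@dataclass
class ObservationDesign:
    """2n x (n + k) design matrix with named columns.

    ``matrix`` rows are ordered sample1-Me, sample1-Un, sample2-Me, ...
    matching the column layout of a :class:`~methdiff.experiment.MethylationExperiment`.
    The first ``n`` columns are sample-coverage indicators; the last
    ``k`` are condition/methylation coefficients.
    """

    matrix: np.ndarray
    colnames: list[str]
    n: int
    k: int

    @property
    def sample_columns(self) -> slice:
        return slice(0, self.n)

    @property
    def condition_columns(self) -> slice:
        return slice(self.n, self.n + self.k)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.matrix, dtype=dtype)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.colnames)


def expand_design(sample_design, colnames: Sequence[str] | None = None, sample_names: Sequence[str] | None = None) -> ObservationDesign:
    """Expand an n x k sample-level design to the 2n x (n+k) observation level.

    Accepts a pandas DataFrame (column names taken from it) or an ndarray
    plus ``colnames``.  Works for any full-rank sample-level
    parametrization: group means, intercept + treatment, or designs with
    additive covariates.
    """
    if isinstance(sample_design, pd.DataFrame):
        if colnames is None:
            colnames = list(sample_design.columns)
        sample_design = sample_design.to_numpy(dtype=float)
    sample_design = np.atleast_2d(np.asarray(sample_design, dtype=float))
    n, k = sample_design.shape
    if n < 1:
        raise ValueError("sample_design must have at least one row")
    if np.linalg.matrix_rank(sample_design) < k:
        raise ValueError("sample_design is rank deficient")
    if colnames is None:
        colnames = [f"Condition{j+1}" for j in range(k)]
    if sample_names is None:
        sample_names = [f"Sample{i+1}" for i in range(n)]

    matrix = np.zeros((2 * n, n + k))
    for i in range(n):
        matrix[2 * i, i] = 1.0        # Me row
        matrix[2 * i + 1, i] = 1.0    # Un row
        matrix[2 * i, n:] = sample_design[i]
    return ObservationDesign(matrix, list(sample_names) + list(colnames), n, k)


def design_from_groups(groups: Sequence[str], intercept: bool = False) -> ObservationDesign:
    """Observation-level design for a one-way layout given per-sample group labels.

    With ``intercept=False`` (the default) the condition block has one
    group-means column per group level (levels in order of first
    appearance).  With ``intercept=True`` the first level is the baseline
    and the remaining columns estimate log2 fold-changes directly.
    """
    groups = list(groups)
    levels = list(dict.fromkeys(groups))
    n = len(groups)
    idx = np.array([levels.index(g) for g in groups])
    if intercept:
        sample_design = np.ones((n, len(levels)))
        sample_design[:, 1:] = (idx[:, None] == np.arange(1, len(levels))[None, :]).astype(float)
        colnames = ["(Intercept)"] + [f"Condition{lv}" for lv in levels[1:]]
    else:
        sample_design = (idx[:, None] == np.arange(len(levels))[None, :]).astype(float)
        colnames = [f"Condition{lv}" for lv in levels]
    return expand_design(sample_design, colnames=colnames)


# -- contrast expressions ---------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(\d+\.?\d*(?:[eE][+-]?\d+)?)|([A-Za-z_.][\w.]*)|([()+*-]))")


def _tokenize(spec: str) -> list[str]:
    tokens, i = [], 0
    while i < len(spec):
        m = _TOKEN.match(spec, i)
        if not m or m.end() == i:
            raise ValueError(f"cannot parse contrast expression at: {spec[i:]!r}")
        tokens.append(m.group(m.lastindex))
        i = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for linear combinations of column names.

    Grammar: expr := term (('+'|'-') term)*;
    term := factor ('*' factor)*; factor := number | name | '(' expr ')'
    with unary +/-.  The result must be linear in the column names.
    """

    def __init__(self, tokens: list[str], columns: dict[str, int]):
        self.tokens = tokens
        self.pos = 0
        self.columns = columns

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        coef, vec = self.expr()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r} in contrast expression")
        if coef != 0:
            raise ValueError("contrast expression has a constant term")
        return vec

    def expr(self):
        sign = 1.0
        while self.peek() in ("+", "-"):
            if self.next() == "-":
                sign = -sign
        coef, vec = self.term()
        coef, vec = sign * coef, sign * vec
        while self.peek() in ("+", "-"):
            op = self.next()
            s = 1.0 if op == "+" else -1.0
            c2, v2 = self.term()
            coef, vec = coef + s * c2, vec + s * v2
        return coef, vec

    def term(self):
        coef, vec = self.factor()
        while self.peek() == "*":
            self.next()
            c2, v2 = self.factor()
            if np.any(vec) and np.any(v2):
                raise ValueError("contrast expressions must be linear in column names")
            if np.any(v2):
                coef, vec = c2, coef * v2
            else:
                coef, vec = coef * c2, vec * c2
        return coef, vec

    def factor(self):
        tok = self.peek()
        if tok == "(":
            self.next()
            coef, vec = self.expr()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in contrast expression")
            return coef, vec
        if tok in ("+", "-"):
            self.next()
            c, v = self.factor()
            return (-c, -v) if tok == "-" else (c, v)
        tok = self.next()
        if tok is None:
            raise ValueError("unexpected end of contrast expression")
        try:
            return float(tok), np.zeros(len(self.columns))
        except ValueError:
            pass
        if tok not in self.columns:
            raise ValueError(f"unknown design column {tok!r} in contrast expression")
        vec = np.zeros(len(self.columns))
        vec[self.columns[tok]] = 1.0
        return 0.0, vec


def make_contrast(design_colnames: Sequence[str] | ObservationDesign, spec: str) -> np.ndarray:
    """Build a contrast vector from a linear-combination expression.

    ``spec`` supports column names, +, -, scalar multiplication and
    parentheses, e.g. ``"P6 - 0.5*(P7 + P8)"``.
    """
    if isinstance(design_colnames, ObservationDesign):
        design_colnames = design_colnames.colnames
    columns = {name: i for i, name in enumerate(design_colnames)}
    return _Parser(_tokenize(spec), columns).parse()


def make_contrasts(design_colnames: Sequence[str] | ObservationDesign, specs: dict[str, str]) -> pd.DataFrame:
    """Build several named contrasts; returns a columns-per-contrast frame."""
    if isinstance(design_colnames, ObservationDesign):
        design_colnames = design_colnames.colnames
    return pd.DataFrame(
        {name: make_contrast(design_colnames, spec) for name, spec in specs.items()},
        index=list(design_colnames),
    )
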