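"""Pairwise-comparison matrices and AHP weight/consistency computation.

The analytic hierarchy process (AHP) derives priority weights for a set of
factors from a square positive reciprocal matrix of pairwise judgments on
the Saaty 1-9 ratio scale.  This module implements the *sum-product*
(arithmetic-mean) approximation: each column is normalized to sum 1, and
the weight of a factor is the mean of its normalized row.  The principal
right eigenvector is the classical alternative; here it serves only as an
independent cross-check in the test suite, because the sum-product method
is the one whose intermediate quantities (column sums, AW, lambda_max) the
reporting layer exposes.

Consistency is diagnosed with lambda_max = mean_i (A w)_i / w_i, the
consistency index CI = (lambda_max - n)/(n - 1), and the consistency ratio
CR = CI/RI where RI is the average random index for matrices of order n.
A matrix passes when CR < 0.1 (strictly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAATY_VALUES",
    "RANDOM_INDEX",
    "ComparisonMatrix",
    "AhpResult",
    "MatrixValidationError",
    "Violation",
    "validate_matrix",
    "compute_weights",
    "compute_aw",
    "consistency",
    "principal_eigenvector",
    "parse_judgment",
]

#: Admissible judgment values on the Saaty scale: the integers 1..9 and
#: their reciprocals.  Intermediate even values 2,4,6,8 are included.
SAATY_VALUES: tuple[float, ...] = tuple(
    sorted({float(k) for k in range(1, 10)} | {1.0 / k for k in range(2, 10)})
)

#: Average random consistency index by matrix order n (1..9).  CR is
#: defined as 0 whenever RI is 0 (orders 1 and 2 are always consistent).
RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.52,
    4: 0.89,
    5: 1.12,
    6: 1.26,
    7: 1.36,
    8: 1.41,
    9: 1.46,
}

#: Largest matrix order for which the random index is tabulated.
MAX_ORDER = 9

_RECIPROCITY_RTOL = 1e-9
_SAATY_RTOL = 1e-6


def parse_judgment(cell: str | float | int) -> float:
    """Parse one matrix cell: a decimal or an exact fraction string like ``1/7``.

    Fractions are parsed exactly (rational arithmetic) before conversion to
    float, so ``"1/3"`` and ``1/3`` agree to the last bit.
    """
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        return float(cell)
    text = str(cell).strip()
    try:
        return float(Fraction(text))
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"cannot parse judgment value {cell!r}") from exc


@dataclass(frozen=True)
class Violation:
    """One broken matrix invariant: a rule code and the offending cell."""

    code: str          # e.g. "reciprocity", "diagonal", "nonpositive", "off_scale"
    row: int | None
    col: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


class MatrixValidationError(ValueError):
    """Raised when a comparison matrix is structurally unusable."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class ComparisonMatrix:
    """A square positive reciprocal matrix of pairwise Saaty judgments.

    Parameters
    ----------
    group_id:
        Label of the factor group being compared (conventionally one of
        ``S``, ``W``, ``O``, ``T``, but any label is accepted).
    factor_ids:
        Ordered identifiers of the n compared factors.
    values:
        The n x n judgment matrix, row i / column j meaning "importance of
        factor i relative to factor j".
    """

    group_id: str
    factor_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise MatrixValidationError(
                "not_square", f"judgment matrix must be square, got shape {arr.shape}"
            )
        if arr.shape[0] != len(self.factor_ids):
            raise MatrixValidationError(
                "label_mismatch",
                f"{len(self.factor_ids)} factor ids for a {arr.shape[0]}x{arr.shape[0]} matrix",
            )
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "factor_ids", tuple(self.factor_ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_rows(
        cls, rows: Sequence[Sequence[str | float]], factor_ids: Sequence[str], group_id: str = ""
    ) -> "ComparisonMatrix":
        """Build from full rows whose cells may be fraction strings."""
        arr = np.array([[parse_judgment(c) for c in row] for row in rows], dtype=float)
        return cls(group_id=group_id, factor_ids=tuple(factor_ids), values=arr)

    @classmethod
    def from_upper_triangle(
        cls,
        upper: dict[tuple[str, str], float | str],
        factor_ids: Sequence[str],
        group_id: str = "",
    ) -> "ComparisonMatrix":
        """Build from upper-triangle judgments; the lower triangle is filled
        with reciprocals and the diagonal with 1 (reciprocity by construction)."""
        ids = tuple(factor_ids)
        index = {f: i for i, f in enumerate(ids)}
        n = len(ids)
        arr = np.eye(n)
        seen: set[tuple[int, int]] = set()
        for (fi, fj), raw in upper.items():
            i, j = index[fi], index[fj]
            if i == j:
                continue
            if i > j:
                i, j, raw = j, i, 1.0 / parse_judgment(raw)
            v = parse_judgment(raw)
            if v <= 0:
                raise MatrixValidationError("nonpositive", f"judgment ({fi},{fj}) = {v} <= 0")
            arr[i, j] = v
            arr[j, i] = 1.0 / v
            seen.add((i, j))
        missing = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n) if (i, j) not in seen]
        if missing:
            raise MatrixValidationError("missing_pairs", f"unscored pairs: {missing}")
        return cls(group_id=group_id, factor_ids=ids, values=arr)

    @classmethod
    def from_csv(cls, path: str | Path, group_id: str | None = None) -> "ComparisonMatrix":
        """Read the matrix CSV dialect: header row = factor ids, one data row
        per factor (first column the row's factor id), cells decimals or
        fraction strings such as ``1/7``."""
        path = Path(path)
        df = pd.read_csv(path, index_col=0, dtype=str)
        ids = tuple(str(c) for c in df.columns)
        if tuple(str(i) for i in df.index) != ids:
            raise MatrixValidationError(
                "label_mismatch", f"row labels {tuple(df.index)} != column labels {ids}"
            )
        rows = [[parse_judgment(df.iloc[i, j]) for j in range(len(ids))] for i in range(len(ids))]
        return cls(group_id=group_id if group_id is not None else path.stem, factor_ids=ids,
                   values=np.array(rows))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.factor_ids),
                     columns=list(self.factor_ids)).to_csv(path)

    def permuted(self, order: Sequence[int]) -> "ComparisonMatrix":
        """Reorder factors; judgments move with their factor pair."""
        idx = np.asarray(order)
        return ComparisonMatrix(
            group_id=self.group_id,
            factor_ids=tuple(self.factor_ids[i] for i in idx),
            values=self.values[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class AhpResult:
    """Weights and consistency diagnostics for one comparison matrix."""

    group_id: str
    factor_ids: tuple[str, ...]
    weights: np.ndarray
    aw: np.ndarray
    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool
    column_sums: np.ndarray

    @property
    def n(self) -> int:
        return len(self.factor_ids)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "factor_ids": list(self.factor_ids),
            "weights": [float(w) for w in self.weights],
            "aw": [float(a) for a in self.aw],
            "lambda_max": float(self.lambda_max),
            "ci": float(self.ci),
            "ri": float(self.ri),
            "cr": float(self.cr),
            "consistent": bool(self.consistent),
            "column_sums": [float(s) for s in self.column_sums],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def _is_saaty(value: float) -> bool:
    return any(abs(value - s) <= _SAATY_RTOL * s for s in SAATY_VALUES)


def validate_matrix(m: ComparisonMatrix, strict_saaty: bool = False) -> list[Violation]:
    """Check the reciprocal-matrix invariants; return all violations found.

    An empty list means the matrix is valid.  ``strict_saaty=True``
    additionally requires every entry to sit on the Saaty grid
    (1..9 and reciprocals); aggregated expert means are generally off-grid,
    so strict mode is for raw single-expert input.

    Raises
    ------
    MatrixValidationError
        For structurally unusable input: non-square shape (caught at
        construction), or order n > 9, for which the random consistency
        index is not tabulated.
    """
    a = m.values
    n = m.n
    if n > MAX_ORDER:
        raise MatrixValidationError(
            "unsupported_order", f"matrix order {n} > {MAX_ORDER}: random index undefined"
        )
    out: list[Violation] = []
    for i in range(n):
        for j in range(n):
            if a[i, j] <= 0 or not np.isfinite(a[i, j]):
                out.append(Violation("nonpositive", i, j,
                                     f"entry ({i},{j}) = {a[i, j]} is not positive"))
    if any(v.code == "nonpositive" for v in out):
        return out  # reciprocity/scale checks meaningless on nonpositive entries
    for i in range(n):
        if not np.isclose(a[i, i], 1.0, rtol=_RECIPROCITY_RTOL, atol=0.0):
            out.append(Violation("diagonal", i, i, f"diagonal entry ({i},{i}) = {a[i, i]} != 1"))
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isclose(a[j, i], 1.0 / a[i, j], rtol=_RECIPROCITY_RTOL, atol=0.0):
                out.append(Violation(
                    "reciprocity", j, i,
                    f"entry ({j},{i}) = {a[j, i]:.6g} is not the reciprocal of "
                    f"({i},{j}) = {a[i, j]:.6g}",
                ))
    if strict_saaty:
        for i in range(n):
            for j in range(n):
                if i != j and not _is_saaty(a[i, j]):
                    out.append(Violation("off_scale", i, j,
                                         f"entry ({i},{j}) = {a[i, j]:.6g} is not a Saaty value"))
    return out


def _require_valid(m: ComparisonMatrix) -> None:
    violations = validate_matrix(m, strict_saaty=False)
    if violations:
        raise MatrixValidationError(
            violations[0].code,
            "invalid comparison matrix: " + "; ".join(str(v) for v in violations),
        )


# --------------------------------------------------------------------------
# weights / AW / consistency
# --------------------------------------------------------------------------

def compute_weights(m: ComparisonMatrix) -> np.ndarray:
    """Sum-product weight estimate: normalize each column to sum 1, then
    average each row of the normalized matrix.  Weights are positive and
    sum to 1."""
    _require_valid(m)
    a = m.values
    return np.asarray((a / a.sum(axis=0)).mean(axis=1))


def compute_aw(m: ComparisonMatrix, weights: np.ndarray) -> np.ndarray:
    """AW = (original judgment matrix) @ weights.

    Note: the *original* matrix, not the column-normalized one.  For a
    perfectly consistent matrix AW = n * weights.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (m.n,):
        raise ValueError(f"weights shape {w.shape} does not match matrix order {m.n}")
    return m.values @ w


def consistency(m: ComparisonMatrix, ri_table: dict[int, float] | None = None,
                cr_threshold: float = 0.1) -> AhpResult:
    """Full AHP diagnostics for one matrix.

    lambda_max is the mean of (A w)_i / w_i; CI = (lambda_max - n)/(n - 1);
    CR = CI/RI with CR defined as 0 when RI = 0 (n <= 2, always consistent).
    The matrix passes when CR < ``cr_threshold`` strictly: CR exactly at the
    threshold fails.
    """
    ri_table = ri_table if ri_table is not None else RANDOM_INDEX
    n = m.n
    if n > MAX_ORDER:
        raise MatrixValidationError(
            "unsupported_order", f"matrix order {n} > {MAX_ORDER}: random index undefined"
        )
    if n == 1:
        return AhpResult(m.group_id, m.factor_ids, np.array([1.0]), np.array([1.0]),
                         1.0, 0.0, ri_table.get(1, 0.0), 0.0, True, np.array([1.0]))
    _require_valid(m)
    w = compute_weights(m)
    aw = compute_aw(m, w)
    lam = float(np.mean(aw / w))
    ci = (lam - n) / (n - 1)
    ri = ri_table[n]
    cr = 0.0 if ri == 0.0 else ci / ri
    return AhpResult(
        group_id=m.group_id,
        factor_ids=m.factor_ids,
        weights=w,
        aw=aw,
        lambda_max=lam,
        ci=float(ci),
        ri=float(ri),
        cr=float(cr),
        consistent=bool(cr < cr_threshold),
        column_sums=m.values.sum(axis=0),
    )


def principal_eigenvector(m: ComparisonMatrix) -> np.ndarray:
    """Normalized principal right eigenvector of the judgment matrix.

    Provided as an independent reference method; the pipeline itself uses
    :func:`compute_weights` (sum-product) throughout.
    """
    eigvals, eigvecs = np.linalg.eig(m.values)
    k = int(np.argmax(eigvals.real))
    v = np.abs(eigvecs[:, k].real)
    return v / v.sum()
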