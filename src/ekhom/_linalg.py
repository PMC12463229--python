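"""Sparse exact linear algebra over Q and GF(p), plus Smith normal form.

Matrices are lists of sparse columns (dict row-index -> coefficient).
Coefficients are Fractions over Q and plain ints over GF(p).  The
elimination style ("reduce the highest nonzero row of each column against
earlier pivots") is the column reduction used by persistence algorithms,
which doubles as ordinary Gaussian elimination for rank/kernel purposes.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

Column = Dict[int, object]


def _normalize(col: Column, p: Optional[int]) -> None:
    if p is not None:
        dead = []
        for r, c in col.items():
            c %= p
            if c:
                col[r] = c
            else:
                dead.append(r)
        for r in dead:
            del col[r]


def _div(a, b, p: Optional[int]):
    if p is None:
        return Fraction(a) / Fraction(b)
    return a * pow(b, p - 2, p) % p


def _axpy(col: Column, factor, other: Column, p: Optional[int]) -> None:
    """col -= factor * other, in place."""
    for r, c in other.items():
        v = col.get(r, 0) - factor * c
        if p is not None:
            v %= p
        if v:
            col[r] = v
        else:
            col.pop(r, None)


def reduce_columns(cols: Sequence[Column], p: Optional[int] = None,
                   track: bool = False):
    """Left-to-right column reduction.

    Returns ``(reduced, pivots, combos)`` where ``pivots`` maps pivot row ->
    column index and, if ``track``, ``combos[j]`` expresses reduced column j
    as a combination of the input columns (dict input-index -> coefficient).
    """
    reduced: List[Column] = []
    combos: List[Column] = []
    pivots: Dict[int, int] = {}
    for j, col in enumerate(cols):
        cur = dict(col)
        _normalize(cur, p)
        combo: Column = {j: Fraction(1) if p is None else 1}
        while cur:
            low = max(cur)
            k = pivots.get(low)
            if k is None:
                break
            factor = _div(cur[low], reduced[k][low], p)
            _axpy(cur, factor, reduced[k], p)
            if track:
                _axpy(combo, factor, combos[k], p)
        reduced.append(cur)
        combos.append(combo)
        if cur:
            pivots[max(cur)] = j
    return reduced, pivots, combos


def rank(cols: Sequence[Column], p: Optional[int] = None) -> int:
    _reduced, pivots, _ = reduce_columns(cols, p)
    return len(pivots)


def kernel_basis(cols: Sequence[Column], p: Optional[int] = None) -> List[Column]:
    """Basis (as combinations of input columns) of the kernel of the matrix
    whose columns are ``cols``."""
    reduced, _pivots, combos = reduce_columns(cols, p, track=True)
    return [combos[j] for j, col in enumerate(reduced) if not col]


def rank_of_union(base: Sequence[Column], extra: Sequence[Column],
                  p: Optional[int] = None) -> Tuple[int, int]:
    """Rank of span(base) and of span(base + extra)."""
    reduced, pivots, _ = reduce_columns(list(base) + list(extra), p)
    r_base = sum(1 for j, col in enumerate(reduced[:len(base)]) if col)
    return r_base, len(pivots)


def smith_invariant_factors(cols: Sequence[Column], nrows: int) -> List[int]:
    """Nontrivial invariant factors (absolute value > 1) of the integer
    matrix with the given sparse columns."""
    if not cols or nrows == 0:
        return []
    from sympy import Matrix
    from sympy.matrices.normalforms import smith_normal_form

    dense = [[0] * len(cols) for _ in range(nrows)]
    for j, col in enumerate(cols):
        for r, c in col.items():
            num = int(c)
            if Fraction(c) != num:
                raise ValueError("Smith normal form needs integer entries")
            dense[r][j] = num
    snf = smith_normal_form(Matrix(dense))
    out = []
    for i in range(min(snf.shape)):
        v = abs(int(snf[i, i]))
        if v > 1:
            out.append(v)
    return sorted(out)
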