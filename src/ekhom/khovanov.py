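"""The Khovanov cochain complex and its (graded) homology.

The complex of an n-crossing diagram is spanned by the vertices of the
state cube {0,1}^n: a state s resolves every crossing (coordinates in
sorted crossing-id order), its circles each carry a label v+ or v-, and a
basis vector sits in homological height k = l(s) - n_- and q-degree

    deg = (#v+ - #v-) + l(s) + n_+ - 2 n_-,

where l(s) is the number of 1-smoothings in s.  Cube edges flip one
coordinate 0 -> 1; the edge map merges two circles (the Frobenius product
m) or splits one (the coproduct Delta), with the checkerboard sign
(-1)^(number of 1s before the flipped coordinate).  The differential
preserves q-degree and squares to zero.

Homology is computed blockwise per (height, q-degree): over a field by
rank-nullity, over Z by Smith normal form (free ranks plus invariant
factors, i.e. torsion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple, Union

from . import _linalg
from .diagram import LinkDiagram
from .laurent import LaurentPolynomial, TwoVarPolynomial

__all__ = [
    "BasisVector", "KhovanovComplex", "HomologySummary",
    "build_complex", "homology", "graded_betti", "poincare", "graded_euler",
    "Coeff", "RATIONALS", "INTEGERS",
]

MAX_COMPLEX_CROSSINGS = 14

# coefficient descriptors: "Q", "Z", or an int prime p for GF(p)
Coeff = Union[str, int]
RATIONALS: Coeff = "Q"
INTEGERS: Coeff = "Z"


def _char(coeff: Coeff) -> Optional[int]:
    """Field characteristic for rank computations (None = Q; Z uses Q ranks)."""
    if coeff in ("Q", "Z"):
        return None
    p = int(coeff)
    if p < 2:
        raise ValueError(f"invalid coefficient descriptor {coeff!r}")
    return p


@dataclass(frozen=True)
class BasisVector:
    """A state together with a v+/v- labeling of its circles.

    ``labels[i]`` (+1 for v+, -1 for v-) labels the i-th circle of the
    resolved state, circles being ordered by their smallest contained arc.
    """
    state: Tuple[int, ...]
    labels: Tuple[int, ...]

    def height(self, n_minus: int) -> int:
        return sum(self.state) - n_minus

    def qdeg(self, n_plus: int, n_minus: int) -> int:
        return sum(self.labels) + sum(self.state) + n_plus - 2 * n_minus


class KhovanovComplex:
    """Per-height basis lists and sparse integer differentials."""

    def __init__(self, diagram: LinkDiagram):
        self.diagram = diagram
        self.ids = diagram.crossing_ids()
        self.n_plus = diagram.n_plus
        self.n_minus = diagram.n_minus
        self.basis: Dict[int, List[BasisVector]] = {}
        self.qdegs: Dict[int, List[int]] = {}
        self.index: Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], Tuple[int, int]] = {}
        # differentials[k]: list of sparse columns C^k -> C^(k+1)
        self.differentials: Dict[int, List[Dict[int, int]]] = {}
        self._circles: Dict[Tuple[int, ...], Tuple[frozenset, ...]] = {}

    # -- structure ----------------------------------------------------
    def heights(self) -> List[int]:
        return sorted(self.basis)

    def rank(self, k: Optional[int] = None) -> int:
        if k is None:
            return sum(len(v) for v in self.basis.values())
        return len(self.basis.get(k, []))

    def matrix(self, k: int) -> List[Dict[int, int]]:
        """Sparse columns of d^k : C^k -> C^(k+1)."""
        return self.differentials.get(k, [])

    def dense_matrix(self, k: int) -> List[List[int]]:
        """d^k as a dense row-major matrix (rows index C^(k+1))."""
        cols = self.matrix(k)
        nrows = self.rank(k + 1)
        out = [[0] * len(cols) for _ in range(nrows)]
        for j, col in enumerate(cols):
            for r, c in col.items():
                out[r][j] = c
        return out

    def graded_euler_of_chains(self) -> LaurentPolynomial:
        total = LaurentPolynomial.zero("q")
        for k, degs in self.qdegs.items():
            sign = (-1) ** (k % 2)
            for l in degs:
                total = total + LaurentPolynomial.monomial(l, sign, "q")
        return total


def build_complex(d: LinkDiagram,
                  max_crossings: int = MAX_COMPLEX_CROSSINGS) -> KhovanovComplex:
    """Build the Khovanov cochain complex of a diagram.

    Enumerates all 2^n states; refuses diagrams above ``max_crossings``.
    """
    if d.n > max_crossings:
        raise ValueError(
            f"diagram has {d.n} crossings, above the bound {max_crossings}; "
            f"pass max_crossings to override")
    cx = KhovanovComplex(d)
    n = d.n
    nmi = d.n_minus

    # states, circles, basis
    for state in product((0, 1), repeat=n):
        resolved = d.resolve(state)
        cx._circles[state] = resolved.circles
        k = sum(state) - nmi
        for labels in product((1, -1), repeat=resolved.count):
            vec = BasisVector(state, labels)
            lst = cx.basis.setdefault(k, [])
            cx.index[(state, labels)] = (k, len(lst))
            lst.append(vec)
            cx.qdegs.setdefault(k, []).append(vec.qdeg(d.n_plus, nmi))

    # differentials
    for k in cx.heights():
        if k + 1 not in cx.basis:
            cx.differentials[k] = [dict() for _ in cx.basis[k]]
            continue
        cols: List[Dict[int, int]] = []
        for vec in cx.basis[k]:
            col: Dict[int, int] = {}
            for i in range(n):
                if vec.state[i] == 1:
                    continue
                sign = -1 if sum(vec.state[:i]) % 2 else 1
                target_state = vec.state[:i] + (1,) + vec.state[i + 1:]
                for labels, coeff in _edge_images(
                        cx._circles[vec.state], cx._circles[target_state],
                        vec.labels):
                    _k, row = cx.index[(target_state, labels)]
                    col[row] = col.get(row, 0) + sign * coeff
                    if col[row] == 0:
                        del col[row]
            cols.append(col)
        cx.differentials[k] = cols
    return cx


def _edge_images(src_circles: Sequence[frozenset],
                 dst_circles: Sequence[frozenset],
                 labels: Tuple[int, ...]):
    """Images of a labeled source state along one cube edge.

    Circles are matched by their arc content; exactly one merge (two
    circles become one) or one split (one becomes two) happens per edge.
    Yields (destination label tuple, coefficient).
    """
    src_set = {c: i for i, c in enumerate(src_circles)}
    dst_set = {c: i for i, c in enumerate(dst_circles)}
    gone = [c for c in src_circles if c not in dst_set]
    new = [c for c in dst_circles if c not in src_set]

    if len(gone) == 2 and len(new) == 1:
        a, b = src_set[gone[0]], src_set[gone[1]]
        la, lb = labels[a], labels[b]
        if la == lb == -1:      # m(v- (x) v-) = 0
            return
        merged = -1 if -1 in (la, lb) else 1
        out = [None] * len(dst_circles)
        for c, i in src_set.items():
            if c in dst_set:
                out[dst_set[c]] = labels[i]
        out[dst_set[new[0]]] = merged
        yield tuple(out), 1
    elif len(gone) == 1 and len(new) == 2:
        a = src_set[gone[0]]
        base = [None] * len(dst_circles)
        for c, i in src_set.items():
            if c in dst_set:
                base[dst_set[c]] = labels[i]
        i1, i2 = dst_set[new[0]], dst_set[new[1]]
        if labels[a] == 1:      # Delta(v+) = v+ (x) v- + v- (x) v+
            for l1, l2 in ((1, -1), (-1, 1)):
                out = list(base)
                out[i1], out[i2] = l1, l2
                yield tuple(out), 1
        else:                   # Delta(v-) = v- (x) v-
            out = list(base)
            out[i1] = out[i2] = -1
            yield tuple(out), 1
    else:  # pragma: no cover - would indicate a resolution bug
        raise AssertionError("cube edge changes more than one circle")


@dataclass
class HomologySummary:
    """Khovanov homology organized by (height k, q-degree l).

    ``ranks[(k, l)]`` is the free rank (field dimension for field
    coefficients); ``torsion[(k, l)]`` lists invariant factors (Z only).
    """
    coeff: Coeff
    ranks: Dict[Tuple[int, int], int] = field(default_factory=dict)
    torsion: Dict[Tuple[int, int], Tuple[int, ...]] = field(default_factory=dict)

    @property
    def is_field(self) -> bool:
        return self.coeff != "Z"

    def rank(self, k: int, l: Optional[int] = None) -> int:
        if l is not None:
            return self.ranks.get((k, l), 0)
        return sum(r for (kk, _l), r in self.ranks.items() if kk == k)

    def total_rank(self) -> int:
        return sum(self.ranks.values())

    def heights(self) -> List[int]:
        ks = {k for (k, _l) in self.ranks} | {k for (k, _l) in self.torsion}
        return sorted(ks)

    def support(self) -> List[Tuple[int, int]]:
        return sorted(k_l for k_l, r in self.ranks.items() if r)

    def to_rows(self) -> List[dict]:
        """CSV-friendly rows (k, l, rank, torsion)."""
        keys = sorted(set(self.ranks) | set(self.torsion))
        return [{"k": k, "l": l, "rank": self.ranks.get((k, l), 0),
                 "torsion": ";".join(map(str, self.torsion.get((k, l), ())))}
                for (k, l) in keys]


def _block_columns(cx: KhovanovComplex, k: int, l: int) -> Tuple[List[Dict[int, object]], int]:
    """The degree-l block of d^k as sparse columns with re-indexed rows;
    returns (columns, number of block rows)."""
    src = [j for j, d_ in enumerate(cx.qdegs.get(k, [])) if d_ == l]
    dst = [i for i, d_ in enumerate(cx.qdegs.get(k + 1, [])) if d_ == l]
    rowmap = {r: i for i, r in enumerate(dst)}
    cols = []
    full = cx.matrix(k)
    for j in src:
        col = full[j] if j < len(full) else {}
        cols.append({rowmap[r]: Fraction(c) for r, c in col.items()})
    return cols, len(dst)


def homology(cx: KhovanovComplex, coeff: Coeff = RATIONALS) -> HomologySummary:
    """Khovanov homology of a built complex.

    ``coeff`` is "Q" (rationals), a prime p (the field GF(p)) or "Z"
    (integral homology: free ranks plus torsion invariant factors).
    """
    summary = HomologySummary(coeff=coeff)
    p = _char(coeff)
    for k in cx.heights():
        for l in sorted(set(cx.qdegs[k])):
            dim = sum(1 for d_ in cx.qdegs[k] if d_ == l)
            out_cols, _ = _block_columns(cx, k, l)
            in_cols, nrows = _block_columns(cx, k - 1, l)
            if coeff == "Z":
                r_out = _linalg.rank(out_cols, None)
                r_in = _linalg.rank(in_cols, None)
                free = dim - r_out - r_in
                tors = _linalg.smith_invariant_factors(in_cols, dim) if in_cols else []
            else:
                if p is not None:
                    out_cols = [{r: int(c) % p for r, c in col.items()}
                                for col in out_cols]
                    in_cols = [{r: int(c) % p for r, c in col.items()}
                               for col in in_cols]
                r_out = _linalg.rank(out_cols, p)
                r_in = _linalg.rank(in_cols, p)
                free = dim - r_out - r_in
                tors = []
            if free:
                summary.ranks[(k, l)] = free
            if tors:
                summary.torsion[(k, l)] = tuple(tors)
    return summary


# ----------------------------------------------------------- invariants

def graded_betti(summary: HomologySummary, k: int) -> LaurentPolynomial:
    """beta_k(q) = sum_l dim H^{k,l} q^l (field coefficients only)."""
    if not summary.is_field:
        raise ValueError("graded dimension needs field coefficients")
    out: Dict[int, Fraction] = {}
    for (kk, l), r in summary.ranks.items():
        if kk == k:
            out[l] = Fraction(r)
    return LaurentPolynomial(out, "q")


def poincare(summary: HomologySummary) -> TwoVarPolynomial:
    """Graded Poincare polynomial Kh(L) = sum_k qdim H^k t^k."""
    if not summary.is_field:
        raise ValueError("graded dimension needs field coefficients")
    return TwoVarPolynomial({(k, l): Fraction(r)
                             for (k, l), r in summary.ranks.items()})


def graded_euler(summary: HomologySummary) -> LaurentPolynomial:
    """Graded Euler characteristic chi_q = sum_k (-1)^k qdim H^k.

    By the categorification theorem this equals the unnormalized Jones
    polynomial of the underlying diagram.
    """
    if not summary.is_field:
        raise ValueError("graded dimension needs field coefficients")
    out: Dict[int, Fraction] = {}
    for (k, l), r in summary.ranks.items():
        out[l] = out.get(l, Fraction(0)) + ((-1) ** (k % 2)) * r
    return LaurentPolynomial(out, "q")
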