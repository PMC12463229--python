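"""Evolutionary Khovanov homology: filtered complexes, image ranks, barcodes.

A weighted link determines a tower of a-indexed links.  Smoothing a
left-handed crossing embeds the smaller Khovanov complex into the larger
one as the subcube of states whose coordinate at that crossing is 1, with
a q-degree shift of -1 per smoothing event; iterating gives a filtration
of cochain complexes

    C(most smoothed)  <=  ...  <=  C(rho_{x1} L)  <=  C(L),

all realized inside the ambient complex C(L).  The evolutionary Khovanov
homology H_{a,b}^k is the image of H^k(more smoothed stage) in H^k(less
smoothed stage); as a persistence module over the threshold parameter it
decomposes into interval summands, the bars of a barcode.  Each bar also
carries a q-degree profile: the inclusions are degree-shifting, so the
degree of a class is stage-dependent (ambient degree + number of smoothed
crossings at that stage, for all-left-handed diagrams).

Smoothing a *right-handed* crossing instead realizes the smaller complex
as a quotient (the forced cube coordinate is 0, and that subspace is not
closed under the differential), so a tower that smooths right-handed
crossings is a zigzag and has no single-direction persistence module.
Barcodes and image ranks therefore require the smoothed crossings to be
left-handed; :meth:`LinkDiagram.mirror` is the standard workaround, and
stage-wise summaries (:func:`poincare_over_filtration`) work regardless.

The barcode is computed by the standard column-reduction persistence
algorithm run over the increasing tower (most smoothed first), blockwise
per ambient q-degree since the differential is degree-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

from . import _linalg
from .diagram import DiagramError, LinkDiagram
from .filtration import WeightedLink, filtration_sequence
from .khovanov import (KhovanovComplex, build_complex, homology, poincare,
                       Coeff, RATIONALS)
from .laurent import LaurentPolynomial, TwoVarPolynomial

__all__ = [
    "FilteredComplex", "Bar", "Barcode", "FiltrationError",
    "build_filtered_complex", "ekh_rank", "barcode",
    "evolutionary_betti", "evolutionary_jones", "poincare_over_filtration",
]


class FiltrationError(DiagramError):
    pass


def _field_char(coeff: Coeff) -> Optional[int]:
    if coeff == "Z":
        raise FiltrationError(
            "persistence needs field coefficients; use 'Q' or a prime")
    if coeff == "Q":
        return None
    return int(coeff)


def _require_left_handed(d: LinkDiagram, xs) -> None:
    bad = sorted(x for x in xs if d.crossings[x].sign > 0)
    if bad:
        raise FiltrationError(
            f"crossings {bad} are right-handed: smoothing them gives a "
            f"quotient complex, not a subcomplex, so the tower is not a "
            f"filtration; consider diagram.mirror()")


@dataclass
class FilteredComplex:
    """Ambient Khovanov complex plus per-basis-vector entry data.

    Stage i (0 = the original link) smooths the cumulative crossing set
    ``smoothed_sets[i]``; an ambient basis vector belongs to stage i iff
    its state has coordinate 1 at every smoothed crossing.  ``last_stage``
    maps each (height, row) basis index to the largest stage containing
    it; the sub-bases are nested and closed under the differential.
    ``degree_offset[i]`` is the intrinsic-minus-ambient q-degree shift of
    stage i (= number of smoothed crossings, all left-handed).
    """
    weighted: WeightedLink
    complex: KhovanovComplex
    parameters: List[float]
    smoothed_sets: List[frozenset]
    last_stage: Dict[Tuple[int, int], int]
    degree_offset: List[int]
    coeff: Coeff = RATIONALS

    @property
    def n_stages(self) -> int:
        return len(self.parameters)

    def stage_members(self, i: int) -> List[Tuple[int, int]]:
        return [idx for idx, t in self.last_stage.items() if t >= i]

    def stage_rank(self, i: int) -> int:
        return sum(1 for t in self.last_stage.values() if t >= i)


def build_filtered_complex(w: WeightedLink,
                           coeff: Coeff = RATIONALS) -> FilteredComplex:
    """Realize the whole filtration inside the ambient Khovanov complex."""
    _field_char(coeff)
    d = w.diagram
    _require_left_handed(d, d.crossings)
    cx = build_complex(d)
    ids = cx.ids
    pos_of = {x: i for i, x in enumerate(ids)}
    seq_params = w.stage_parameters()
    sets = [w.smoothed_set(a) for a in seq_params]
    sets[0] = frozenset()
    m = len(seq_params) - 1

    last_stage: Dict[Tuple[int, int], int] = {}
    for k, vecs in cx.basis.items():
        for row, vec in enumerate(vecs):
            t = m
            for i in range(1, m + 1):
                if any(vec.state[pos_of[x]] != 1 for x in sets[i] - sets[i - 1]):
                    t = i - 1
                    break
            last_stage[(k, row)] = t
    offsets = [len(s) for s in sets]
    return FilteredComplex(w, cx, seq_params, sets, last_stage, offsets, coeff)


# ----------------------------------------------------------------- barcode

@dataclass
class Bar:
    """One interval summand of the EKH persistence module.

    Stages run from 0 (the original link) to n_stages-1 (fully smoothed);
    the bar is alive at stages ``stage_lo .. stage_hi`` inclusive.  Bars
    with ``reaches_original`` are the free summands (alive all the way to
    the original link, the (-infinity, b] intervals); the degree profile
    maps each alive stage to the intrinsic q-degree of the class there.
    """
    height: int
    stage_lo: int
    stage_hi: int
    param_lo: float
    param_hi: float
    reaches_original: bool
    degree_profile: Dict[int, int] = field(default_factory=dict)

    def length(self) -> int:
        """Number of module arrows the bar spans (0 = single stage)."""
        return self.stage_hi - self.stage_lo

    def alive_at_stage(self, i: int) -> bool:
        return self.stage_lo <= i <= self.stage_hi

    def to_json(self) -> dict:
        return {"height": self.height,
                "stage_span": [self.stage_lo, self.stage_hi],
                "param_span": [self.param_lo, self.param_hi],
                "reaches_original": self.reaches_original,
                "degree_profile": {str(i): d
                                   for i, d in sorted(self.degree_profile.items())}}


@dataclass
class Barcode:
    bars: List[Bar]
    mode: str
    parameters: List[float]
    coeff: Coeff = RATIONALS

    def alive_at_stage(self, i: int, height: Optional[int] = None) -> int:
        return sum(1 for b in self.bars
                   if b.alive_at_stage(i)
                   and (height is None or b.height == height))

    def spanning(self, lo: int, hi: int) -> List[Bar]:
        """Bars alive at every stage of [lo, hi]."""
        return [b for b in self.bars
                if b.stage_lo <= lo and b.stage_hi >= hi]

    def positive_length(self) -> List[Bar]:
        return [b for b in self.bars if b.length() > 0]

    def to_json(self) -> dict:
        return {"mode": self.mode, "parameters": list(self.parameters),
                "coeff": str(self.coeff),
                "bars": [b.to_json() for b in self.bars]}

    def persistence_pairs(self) -> List[Tuple[float, float, int]]:
        """(birth_param, death_param, height) triples; birth is the
        parameter of the most-smoothed alive stage."""
        return [(self.parameters[b.stage_hi], self.parameters[b.stage_lo],
                 b.height) for b in self.bars]


def barcode(w: WeightedLink, coeff: Coeff = RATIONALS) -> Barcode:
    """Interval decomposition of the EKH module of a weighted link.

    Standard persistence column reduction over the increasing tower (most
    smoothed complex first), run independently on each ambient q-degree
    block.  Bars of length 0 (alive at a single stage) are kept so that
    the number of bars alive at any stage with height k equals
    dim H^k of that stage's complex.
    """
    fc = build_filtered_complex(w, coeff)
    p = _field_char(coeff)
    cx = fc.complex
    m = fc.n_stages - 1

    # group basis vectors by ambient q-degree
    by_deg: Dict[int, List[Tuple[int, int]]] = {}
    for k in cx.heights():
        for row, l in enumerate(cx.qdegs[k]):
            by_deg.setdefault(l, []).append((k, row))

    bars: List[Bar] = []
    for l, members in sorted(by_deg.items()):
        entry = {idx: m - fc.last_stage[idx] for idx in members}
        # faces (higher height) first within an entry step
        order = sorted(members, key=lambda idx: (entry[idx], -idx[0], idx[1]))
        pos = {idx: i for i, idx in enumerate(order)}
        cols: List[Dict[int, object]] = []
        for (k, row) in order:
            dcol = cx.matrix(k)[row] if cx.matrix(k) else {}
            col = {}
            for r, c in dcol.items():
                tgt = (k + 1, r)
                if tgt in pos:  # same degree block by construction
                    col[pos[tgt]] = Fraction(c) if p is None else int(c) % p
            cols.append(col)
        reduced, pivots, _ = _linalg.reduce_columns(cols, p)

        death_of: Dict[int, int] = {}   # creator position -> death step
        is_creator = [not rc for rc in reduced]
        for low, j in pivots.items():
            # column j kills the class created by `low`
            death_of[low] = entry[order[j]]
        for i, idx in enumerate(order):
            if not is_creator[i]:
                continue
            birth = entry[idx]
            death = death_of.get(i)  # None = never dies
            if death is not None and death <= birth:
                continue  # empty interval: class never alive at a stage
            hi_step = m if death is None else death - 1
            stage_lo = m - hi_step
            stage_hi = m - birth
            profile = {s: l + fc.degree_offset[s]
                       for s in range(stage_lo, stage_hi + 1)}
            bars.append(Bar(
                height=idx[0], stage_lo=stage_lo, stage_hi=stage_hi,
                param_lo=fc.parameters[stage_lo],
                param_hi=fc.parameters[stage_hi],
                reaches_original=(death is None),
                degree_profile=profile))
    bars.sort(key=lambda b: (b.height, b.stage_lo, b.stage_hi,
                             b.degree_profile.get(b.stage_lo, 0)))
    return Barcode(bars, w.mode, fc.parameters, coeff)


# --------------------------------------------------------------- EKH ranks

def _stage_block_columns(cx: KhovanovComplex, members: set, k: int, l: int,
                         p: Optional[int]):
    """Columns of the stage differential d^k at degree l.

    Columns run over stage members only and rows are *compressed* to stage
    members (for a pure subcomplex nothing is dropped; for a stage that
    quotients right-handed forced-0 coordinates this is the subquotient
    differential)."""
    cols = []
    mat = cx.matrix(k)
    for row, deg in enumerate(cx.qdegs.get(k, [])):
        if deg != l or (k, row) not in members:
            continue
        src = mat[row] if mat else {}
        col = {}
        for r, c in src.items():
            if (k + 1, r) in members:
                col[r] = Fraction(c) if p is None else int(c) % p
        cols.append(((k, row), col))
    return cols


def _forced_values(d: LinkDiagram, S) -> Dict[int, int]:
    """Forced cube coordinate per smoothed crossing: 1 at left-handed
    (subcomplex), 0 at right-handed (quotient)."""
    return {x: (1 if d.crossings[x].sign < 0 else 0) for x in S}


def ekh_rank(w: WeightedLink, a: float, b: float,
             k: Optional[int] = None, coeff: Coeff = RATIONALS):
    """Rank of H(more smoothed stage) -> H(less smoothed stage).

    In ascending mode this is the image of H^k at threshold b inside H^k
    at threshold a (a <= b); descending mode mirrors the roles per its
    covariant convention.  With ``k`` given, returns the integer rank at
    that height; otherwise a dict (height, q-degree at the less-smoothed
    stage) -> rank.  At a == b this is the stage homology itself, for any
    diagram; a strict window needs the crossings smoothed inside it to be
    left-handed (right-handed ones reverse the arrow direction).
    """
    if a > b:
        raise FiltrationError("ekh_rank needs a <= b")
    p = _field_char(coeff)
    S_small, S_big = w.smoothed_set(a), w.smoothed_set(b)
    if w.mode == "descending":
        S_small, S_big = S_big, S_small
    # S_small ⊆ S_big; big = more smoothed = smaller complex
    _require_left_handed(w.diagram, S_big - S_small)
    cx = build_complex(w.diagram)
    ids = cx.ids
    pos_of = {x: i for i, x in enumerate(ids)}

    def members_of(S) -> set:
        forced = _forced_values(w.diagram, S)
        out = set()
        for kk, vecs in cx.basis.items():
            for row, vec in enumerate(vecs):
                if all(vec.state[pos_of[x]] == v for x, v in forced.items()):
                    out.add((kk, row))
        return out

    mem_small, mem_big = members_of(S_small), members_of(S_big)
    # intrinsic q-degree at the less-smoothed stage = ambient degree
    # + (#left-handed - #right-handed) smoothed crossings there
    deg_shift = sum(1 if w.diagram.crossings[x].sign < 0 else -1
                    for x in S_small)

    table: Dict[Tuple[int, int], int] = {}
    heights = cx.heights() if k is None else [k]
    for kk in heights:
        degs = sorted(set(cx.qdegs.get(kk, [])))
        for l in degs:
            # cycles of the big (more smoothed) stage at (kk, l)
            zcols = []
            big_cols = _stage_block_columns(cx, mem_big, kk, l, p)
            idxs = [idx for idx, _ in big_cols]
            kernel = _linalg.kernel_basis([c for _, c in big_cols], p)
            for comb in kernel:
                vec: Dict[Tuple[int, int], object] = {}
                for j, c in comb.items():
                    vec[idxs[j]] = c
                zcols.append(vec)
            if not zcols:
                continue
            # boundaries of the small (less smoothed) stage into height kk,
            # re-keyed to a common row indexing with the cycle vectors
            bnd = [{(kk, r): c for r, c in colb.items()}
                   for _, colb in _stage_block_columns(cx, mem_small, kk - 1, l, p)]
            allrows: Dict[Tuple[int, int], int] = {}

            def flat(col):
                out = {}
                for key, c in col.items():
                    if key not in allrows:
                        allrows[key] = len(allrows)
                    out[allrows[key]] = c
                return out

            bnd3 = [flat(c3) for c3 in bnd]
            z3 = [flat(c3) for c3 in zcols]
            r_b, r_all = _linalg.rank_of_union(bnd3, z3, p)
            r = r_all - r_b
            if r:
                table[(kk, l + deg_shift)] = table.get((kk, l + deg_shift), 0) + r
    if k is not None:
        return sum(v for (kk, _l), v in table.items() if kk == k)
    return table


def evolutionary_betti(w: WeightedLink, a: float, b: float,
                       coeff: Coeff = RATIONALS) -> Dict[Tuple[int, int], int]:
    """(height, q-degree at the less-smoothed stage) -> evolutionary Betti
    number of the window (a, b)."""
    return ekh_rank(w, a, b, None, coeff)


def evolutionary_jones(w: WeightedLink, a: float, b: float,
                       coeff: Coeff = RATIONALS) -> LaurentPolynomial:
    """Jhat_{a,b} = sum_k (-1)^k qdim H_{a,b}^k (graded alternating sum)."""
    table = evolutionary_betti(w, a, b, coeff)
    out: Dict[int, Fraction] = {}
    for (k, l), r in table.items():
        out[l] = out.get(l, Fraction(0)) + ((-1) ** (k % 2)) * r
    return LaurentPolynomial(out, "q")


def poincare_over_filtration(w: WeightedLink, coeff: Coeff = RATIONALS
                             ) -> List[Tuple[float, TwoVarPolynomial]]:
    """Graded Poincare polynomial of every a-indexed link in the
    filtration (stage-wise; works for any crossing handedness)."""
    _field_char(coeff)
    seq = filtration_sequence(w)
    out = []
    for a, d in zip(seq.parameters, seq.diagrams):
        h = homology(build_complex(d), coeff)
        out.append((a, poincare(h)))
    return out
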