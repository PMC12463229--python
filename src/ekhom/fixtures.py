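"""Built-in knot table and synthetic curve generators.

Everything a test or demo needs is constructed programmatically: a small
table of reference diagrams (unknot, kinks, Hopf links, trefoils,
figure-eight, a 7_6 diagram, and the four-crossing unlink used in the
worked weighted-link example) plus parametric space curves.  Fixture
entries carry expected invariants and are verified against the bracket
module when the table is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bracket import unnormalized_jones_q
from .diagram import Crossing, DiagramError, LinkDiagram, parse_pd
from .laurent import LaurentPolynomial
from .projection import SpaceCurve

__all__ = ["FixtureEntry", "fixture_table", "from_braid", "synthetic_curve",
           "EXAMPLE_76_CROSSING_COORDS"]


# 3D coordinates of the seven crossings of a 7_6 knot projection used in
# the distance-filtration worked example; the xy-projection of these
# points drives the critical-radius computation.
EXAMPLE_76_CROSSING_COORDS: Tuple[Tuple[float, float, float], ...] = (
    (-3.68122, 2.1618, 0.520849),
    (-2.31313, 4.52637, -0.526226),
    (-0.291898, -0.0329635, 0.5289),
    (-0.000160251, -3.82999, -0.657526),
    (1.29451, 3.02755, -0.309725),
    (2.99467, 4.45183, 0.450002),
    (3.79753, 2.50471, -0.482759),
)


# ------------------------------------------------------------------ braids

def from_braid(word: Sequence[int], strands: Optional[int] = None,
               closure: str = "trace") -> LinkDiagram:
    """Build a diagram from a braid word.

    ``word`` lists Artin generators: i > 0 is sigma_i (strand i crosses
    over strand i+1, a right-handed crossing for upward-oriented strands),
    i < 0 its inverse.  ``closure="trace"`` joins top to bottom column by
    column; ``closure="plat"`` (even strand count) caps columns (1,2),
    (3,4), ... at top and bottom.  Plat closures re-derive signs from an
    actual traversal, since caps reverse strand directions.
    """
    if not word and strands is None:
        raise DiagramError("empty braid word needs an explicit strand count")
    k = strands or (max(abs(g) for g in word) + 1)
    if any(g == 0 or abs(g) >= k for g in word):
        raise DiagramError("braid letters must be nonzero and < strand count")
    if closure not in ("trace", "plat"):
        raise DiagramError(f"unknown closure {closure!r}")
    if closure == "plat" and k % 2:
        raise DiagramError("plat closure needs an even number of strands")

    arc = 0

    def new_arc() -> int:
        nonlocal arc
        arc += 1
        return arc

    if closure == "plat":
        init = {}
        for c in range(1, k, 2):
            a = new_arc()
            init[c], init[c + 1] = a, a
    else:
        init = {c: new_arc() for c in range(1, k + 1)}
    cur = dict(init)

    crossings: List[Crossing] = []
    for cid, g in enumerate(word, start=1):
        i = abs(g)
        L, R = cur[i], cur[i + 1]
        nL, nR = new_arc(), new_arc()
        if g > 0:
            # under: right strand SE -> NW; over: left strand SW -> NE
            crossings.append(Crossing(cid, +1, (R, nR, nL, L)))
        else:
            crossings.append(Crossing(cid, -1, (L, R, nR, nL)))
        cur[i], cur[i + 1] = nL, nR

    # closure gluings
    pairs = []
    if closure == "trace":
        pairs = [(init[c], cur[c]) for c in range(1, k + 1)]
    else:
        for c in range(1, k, 2):
            pairs.append((cur[c], cur[c + 1]))

    parent: Dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    remap = {x: find(x) for x in range(1, arc + 1)}
    used = set()
    out = []
    for c in crossings:
        ends = tuple(remap[e] for e in c.ends)
        used.update(ends)
        out.append(Crossing(c.id, c.sign, ends))
    # arc classes never touching a crossing are closed circles
    loops = len(set(remap.values()) - used)
    d = LinkDiagram(out, loops)
    if closure == "plat":
        d = d.with_consistent_orientation()
    return d


# ----------------------------------------------------------------- fixtures

@dataclass(frozen=True)
class FixtureEntry:
    """A named diagram with its expected invariants."""
    name: str
    diagram: LinkDiagram
    components: int
    writhe: int
    jones_hat: LaurentPolynomial
    note: str = ""


def _J(coeffs: Dict[int, int]) -> LaurentPolynomial:
    return LaurentPolynomial(coeffs, "q")


def example31_diagram() -> LinkDiagram:
    """The four-crossing two-component unlink of the worked weighted-link
    example: a right-handed clasp x1, x3 stacked against a left-handed
    clasp x2, x4 between the same two circles.

    Found by exhaustive search over planar 4-crossing shadows (see
    scripts/search_example31.py): smoothing {x1, x3} by rho leaves the
    negative Hopf link, while smoothing in the order x1, x2, x3, x4 passes
    only through unlink diagrams.  Signs are explicit because one circle
    runs over the other everywhere, so no strand orientation is forced by
    the code text alone.
    """
    return LinkDiagram([
        Crossing(1, +1, (1, 5, 2, 8)),
        Crossing(2, -1, (2, 5, 3, 6)),
        Crossing(3, +1, (3, 7, 4, 6)),
        Crossing(4, -1, (4, 7, 1, 8)),
    ])


def seven_six_diagram() -> LinkDiagram:
    """A 7-crossing diagram of the 7_6 knot, as a 4-strand plat closure.

    The word was found by scanning small twist-region plat words for
    determinant 19: among knots admitting a 7-crossing diagram the
    determinant (|bracket| at a = e^{i pi/4}) equals 19 only for 7_6
    (the 2-bridge knot b(19,7)), so the identification needs no table
    lookup."""
    return from_braid([2, -1, 2, -1, -1, 2, 2], strands=4, closure="plat")


def fixture_table() -> Dict[str, FixtureEntry]:
    """The built-in knot table, self-checked at load time.

    Raises :class:`DiagramError` naming the fixture if a stored expected
    invariant disagrees with what the bracket module computes.
    """
    specs = [
        ("unknot", LinkDiagram([], free_loops=1), 1, 0,
         _J({1: 1, -1: 1}), "crossing-free circle"),
        ("kink_positive", parse_pd("X(1,1,2,2)"), 1, 1,
         _J({1: 1, -1: 1}), "one right-handed curl"),
        ("kink_negative", parse_pd("X(1,1,2,2)").mirror(), 1, -1,
         _J({1: 1, -1: 1}), "one left-handed curl"),
        ("unknot_2x", from_braid([1, 1], strands=2, closure="plat"), 1, None,
         _J({1: 1, -1: 1}), "two-crossing unknot (plat of sigma_1^2)"),
        ("hopf_negative", from_braid([-1, -1]), 2, -2,
         _J({0: 1, -2: 1, -4: 1, -6: 1}), "negative Hopf link"),
        ("hopf_positive", from_braid([1, 1]), 2, 2,
         _J({0: 1, 2: 1, 4: 1, 6: 1}), "positive Hopf link"),
        ("trefoil_left", parse_pd("X(1,4,2,5) X(3,6,4,1) X(5,2,6,3)"), 1, -3,
         _J({-1: 1, -3: 1, -5: 1, -9: -1}), "left-handed trefoil"),
        ("trefoil_right", from_braid([1, 1, 1]), 1, 3,
         _J({1: 1, 3: 1, 5: 1, 9: -1}), "right-handed trefoil"),
        ("figure_eight", from_braid([1, -2, 1, -2]), 1, 0,
         _J({5: 1, -5: 1}), "figure-eight knot"),
        ("example31", example31_diagram(), 2, 0,
         _J({2: 1, 0: 2, -2: 1}),
         "4-crossing unlink whose {x1,x3}-smoothing is the negative Hopf link"),
        ("seven_six", seven_six_diagram(), 1, -3,
         None, "7_6 knot (2-bridge b(19,7)) from a plat closure"),
    ]
    table: Dict[str, FixtureEntry] = {}
    for name, d, comps, wr, jhat, note in specs:
        got_c = d.n_components()
        got_w = d.writhe()
        if got_c != comps:
            raise DiagramError(
                f"fixture {name}: component count {got_c}, expected {comps}")
        if wr is not None and got_w != wr:
            raise DiagramError(
                f"fixture {name}: writhe {got_w}, expected {wr}")
        wr = got_w
        got_j = unnormalized_jones_q(d)
        if jhat is not None and got_j != jhat:
            raise DiagramError(
                f"fixture {name}: Jhat {got_j.pretty()} != expected {jhat.pretty()}")
        table[name] = FixtureEntry(name, d, comps, wr, got_j, note)
    return table


# ------------------------------------------------------------------ curves

def synthetic_curve(kind: str = "torus", samples: int = 60, seed: int = 0,
                    p: int = 2, q: int = 3) -> SpaceCurve:
    """Reproducible parametric space curves.

    ``torus`` samples a (p, q) torus knot (the default (2, 3) projects to
    a 3-crossing trefoil diagram for samples >= 40), ``circle`` a flat
    round circle, and ``random_walk`` a drift-corrected closed random
    polygon.
    """
    if samples < 12:
        raise DiagramError("synthetic curves need at least 12 samples")
    t = np.linspace(0.0, 2.0 * np.pi, samples, endpoint=False)
    if kind == "torus":
        R, r = 2.0, 1.0
        x = (R + r * np.cos(q * t)) * np.cos(p * t)
        y = (R + r * np.cos(q * t)) * np.sin(p * t)
        z = r * np.sin(q * t)   # this chirality projects to left-handed crossings
        pts = np.column_stack([x, y, z])
    elif kind == "circle":
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
    elif kind == "random_walk":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(samples, 3))
        pts = np.cumsum(steps, axis=0)
        drift = pts[-1] - pts[0]
        pts = pts - np.outer(np.arange(samples) / (samples - 1), drift)
        pts = pts[:-1]  # the corrected endpoint duplicates the start
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
        pts = pts[keep]
    else:
        raise DiagramError(f"unknown curve kind {kind!r}")
    return SpaceCurve([pts], closed=True)
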