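"""Planar link diagrams: crossings, smoothing, state resolution, Gauss codes.

A link diagram is stored combinatorially.  Each crossing carries four
*arc-ends* in counterclockwise rotational order starting from the incoming
under-strand (the usual planar-diagram, "PD", convention):

    position 0: incoming under-strand
    position 1: over-strand end (east of the under strand)
    position 2: outgoing under-strand
    position 3: over-strand end (west)

The crossing sign encodes the over-strand direction: a right-handed
(positive) crossing has its incoming over-strand at position 3, a
left-handed (negative) one at position 1.  Equivalently, writing ``u`` and
``o`` for the planar direction vectors of the under- and over-strands, the
sign is the sign of det(o, u).

Smoothings are rotational and orientation-free: the 0-smoothing (the
Kauffman "A" smoothing, coefficient ``a`` in the bracket) joins ends
(0,1) and (2,3); the 1-smoothing joins (0,3) and (1,2).

Crossing-free circle components ("free loops") are first-class: smoothing
can split off circles that touch no crossing, and the bracket and Khovanov
constructions need them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "Crossing", "LinkDiagram", "ResolvedDiagram", "GaussEntry",
    "parse_pd", "emit_pd", "format_gauss", "DiagramError", "PDParseError",
]

SMOOTH_JOINS = {0: ((0, 1), (2, 3)), 1: ((0, 3), (1, 2))}


class DiagramError(ValueError):
    pass


class PDParseError(DiagramError):
    pass


@dataclass(frozen=True)
class Crossing:
    """A crossing: id, handedness sign and the 4 incident arc-ends.

    ``ends`` lists arc identifiers counterclockwise from the incoming
    under-strand.  ``sign`` is +1 (right-handed) or -1 (left-handed).
    """
    id: int
    sign: int
    ends: Tuple[int, int, int, int]

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise DiagramError(f"crossing {self.id}: sign must be +1 or -1")
        if len(self.ends) != 4:
            raise DiagramError(f"crossing {self.id}: needs exactly 4 arc-ends")

    @property
    def over_in_pos(self) -> int:
        return 3 if self.sign > 0 else 1

    @property
    def over_out_pos(self) -> int:
        return 1 if self.sign > 0 else 3

    def role_of_pos(self, pos: int) -> str:
        if pos == 0:
            return "under_in"
        if pos == 2:
            return "under_out"
        return "over_in" if pos == self.over_in_pos else "over_out"


@dataclass(frozen=True)
class ResolvedDiagram:
    """Result of resolving every crossing of a diagram at a given state."""
    circles: Tuple[frozenset, ...]   # each circle = frozenset of arc ids / loop markers
    count: int


GaussEntry = Tuple[int, int, str]  # (label, +1 over / -1 under, 'R' / 'L')


class _DSU:
    __slots__ = ("parent",)

    def __init__(self):
        self.parent: Dict = {}

    def find(self, x):
        p = self.parent
        if x not in p:
            p[x] = x
            return x
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


class LinkDiagram:
    """An (oriented) planar link diagram.

    Parameters
    ----------
    crossings:
        Iterable of :class:`Crossing`; insertion order is preserved but all
        state-cube coordinates use sorted crossing ids.
    free_loops:
        Number of crossing-free circle components.
    coords:
        Optional planar coordinates per crossing id (2-tuples).
    """

    def __init__(self, crossings: Iterable[Crossing] = (), free_loops: int = 0,
                 coords: Optional[Mapping[int, Tuple[float, float]]] = None):
        self.crossings: Dict[int, Crossing] = {}
        for c in crossings:
            if c.id in self.crossings:
                raise DiagramError(f"duplicate crossing id {c.id}")
            self.crossings[c.id] = c
        if free_loops < 0:
            raise DiagramError("free_loops must be >= 0")
        self.free_loops = int(free_loops)
        self.coords: Dict[int, Tuple[float, float]] = dict(coords or {})
        self._validate_arcs()

    # ---------------------------------------------------------------- basics
    @property
    def n(self) -> int:
        return len(self.crossings)

    @property
    def n_plus(self) -> int:
        return sum(1 for c in self.crossings.values() if c.sign > 0)

    @property
    def n_minus(self) -> int:
        return sum(1 for c in self.crossings.values() if c.sign < 0)

    def crossing_ids(self) -> List[int]:
        """Sorted crossing ids; this is the state-cube coordinate order."""
        return sorted(self.crossings)

    def writhe(self) -> int:
        """Writhe w(L) = n+ - n- (sum of crossing signs)."""
        return sum(c.sign for c in self.crossings.values())

    def arc_ids(self) -> List[int]:
        seen = set()
        for c in self.crossings.values():
            seen.update(c.ends)
        return sorted(seen)

    def _slots_by_arc(self) -> Dict[int, List[Tuple[int, int]]]:
        occ: Dict[int, List[Tuple[int, int]]] = {}
        for c in self.crossings.values():
            for pos, arc in enumerate(c.ends):
                occ.setdefault(arc, []).append((c.id, pos))
        return occ

    def _validate_arcs(self) -> None:
        for arc, slots in self._slots_by_arc().items():
            if len(slots) != 2:
                raise DiagramError(
                    f"arc {arc} has {len(slots)} endpoint(s); expected exactly 2")

    def __eq__(self, other):
        return (isinstance(other, LinkDiagram)
                and self.crossings == other.crossings
                and self.free_loops == other.free_loops)

    def __repr__(self):
        return (f"LinkDiagram(n={self.n}, n+={self.n_plus}, n-={self.n_minus}, "
                f"free_loops={self.free_loops})")

    # ------------------------------------------------------------- smoothing
    def _as_state(self, state) -> Dict[int, int]:
        ids = self.crossing_ids()
        if isinstance(state, Mapping):
            missing = [i for i in ids if i not in state]
            if missing:
                raise DiagramError(f"state leaves crossings unassigned: {missing}")
            return {i: int(state[i]) for i in ids}
        state = tuple(state)
        if len(state) != len(ids):
            raise DiagramError(
                f"state of length {len(state)} for {len(ids)} crossings")
        return dict(zip(ids, (int(s) for s in state)))

    def resolve(self, state) -> ResolvedDiagram:
        """Replace every crossing by its chosen smoothing and trace circles.

        ``state`` maps each crossing id to 0 or 1 (or is a tuple in sorted-id
        order).  Returns the circles as sets of arc ids; the count includes
        free loops.
        """
        smap = self._as_state(state)
        dsu = _DSU()
        for arc, slots in self._slots_by_arc().items():
            dsu.union(slots[0], slots[1])
        for cid, choice in smap.items():
            if choice not in (0, 1):
                raise DiagramError(f"state value for crossing {cid} must be 0/1")
            for p, q in SMOOTH_JOINS[choice]:
                dsu.union((cid, p), (cid, q))
        groups: Dict = {}
        for c in self.crossings.values():
            for pos, arc in enumerate(c.ends):
                groups.setdefault(dsu.find((c.id, pos)), set()).add(arc)
        circles = [frozenset(g) for g in groups.values()]
        circles += [frozenset({("free", i)}) for i in range(self.free_loops)]
        circles.sort(key=min_arc_key)
        return ResolvedDiagram(tuple(circles), len(circles))

    def smooth(self, x: int, choice: int) -> "LinkDiagram":
        """Return the diagram with crossing ``x`` replaced by a smoothing.

        Remaining crossings keep their ids, signs and planar coordinates;
        merged arcs keep the smaller of the two ids; circles that no longer
        touch a crossing become free loops.
        """
        if x not in self.crossings:
            raise DiagramError(f"unknown crossing id {x}")
        if choice not in (0, 1):
            raise DiagramError("smoothing choice must be 0 or 1")
        cx = self.crossings[x]
        dsu = _DSU()
        for p, q in SMOOTH_JOINS[choice]:
            dsu.union(cx.ends[p], cx.ends[q])
        classes: Dict[int, List[int]] = {}
        for arc in set(cx.ends):
            classes.setdefault(dsu.find(arc), []).append(arc)
        remap: Dict[int, int] = {}
        for members in classes.values():
            keep = min(members)
            for m in members:
                remap[m] = keep
        new_crossings = []
        used = set()
        for c in self.crossings.values():
            if c.id == x:
                continue
            ends = tuple(remap.get(a, a) for a in c.ends)
            used.update(ends)
            new_crossings.append(Crossing(c.id, c.sign, ends))
        loops = self.free_loops
        for members in classes.values():
            if min(members) not in used:
                loops += 1
        coords = {i: p for i, p in self.coords.items() if i != x}
        return LinkDiagram(new_crossings, loops, coords)

    def rho(self, x: int) -> "LinkDiagram":
        """The handedness-adapted smoothing operator: the *oriented*
        resolution, i.e. the 1-smoothing at a left-handed crossing and the
        0-smoothing at a right-handed one.

        This is the choice that respects strand orientations (remaining
        crossing signs are geometrically unchanged) and, at a left-handed
        crossing, the one whose Khovanov complex embeds into the original
        complex as the ``s_x = 1`` subcube, with a q-degree shift of -1.
        Smoothing the other way at a left-handed crossing of a trefoil
        would leave a two-kink unknot rather than the Hopf link.
        """
        if x not in self.crossings:
            raise DiagramError(f"unknown crossing id {x}")
        return self.smooth(x, 1 if self.crossings[x].sign < 0 else 0)

    def rho_set(self, xs: Iterable[int]) -> "LinkDiagram":
        """Apply ``rho`` at every crossing in ``xs`` (order-independent)."""
        d = self
        for x in sorted(set(xs)):
            d = d.rho(x)
        return d

    def with_consistent_orientation(self) -> "LinkDiagram":
        """Re-derive crossing roles and signs from an actual traversal.

        Assemblies such as plat closures can leave stored in/out roles that
        no strand orientation realizes.  This walks every component in a
        fixed direction, rotates each crossing's end tuple so position 0 is
        the genuine incoming under-strand, and recomputes the sign from
        where the incoming over-strand lands.
        """
        occ = self._slots_by_arc()
        head: Dict[int, Tuple[int, int]] = {}
        for comp in self.components():
            # walk in the direction the smallest arc's stored role claims,
            # so an already-consistent diagram is returned unchanged
            s0, s1 = occ[comp[0]]
            cid, pos = s1
            target = s1 if self.crossings[cid].role_of_pos(pos).endswith("_in") \
                else s0
            arc, slot = comp[0], target
            while True:
                head[arc] = slot
                cid, pos = slot
                exit_pos = (pos + 2) % 4
                nxt = self.crossings[cid].ends[exit_pos]
                a, b = occ[nxt]
                arc, slot = nxt, (b if a == (cid, exit_pos) else a)
                if arc == comp[0] and slot == target:
                    break
        out = []
        for c in self.crossings.values():
            under_in = next(p for p in (0, 2) if head[c.ends[p]] == (c.id, p))
            over_in = next(p for p in (1, 3) if head[c.ends[p]] == (c.id, p))
            r = under_in
            ends = tuple(c.ends[(r + i) % 4] for i in range(4))
            sign = +1 if (over_in - r) % 4 == 3 else -1
            out.append(Crossing(c.id, sign, ends))
        return LinkDiagram(out, self.free_loops, self.coords)

    def mirror(self) -> "LinkDiagram":
        """Switch every crossing (over <-> under); flips all signs."""
        out = []
        for c in self.crossings.values():
            e = c.ends
            ends = (e[3], e[0], e[1], e[2]) if c.sign > 0 else (e[1], e[2], e[3], e[0])
            out.append(Crossing(c.id, -c.sign, ends))
        return LinkDiagram(out, self.free_loops, self.coords)

    # ------------------------------------------------------------ components
    def components(self) -> List[List[int]]:
        """Partition of arcs into closed strands (unoriented traversal).

        Free loops are not listed (they carry no arcs); each component is a
        list of arc ids in traversal order starting from its smallest arc.
        """
        occ = self._slots_by_arc()
        unvisited = set(occ)
        comps: List[List[int]] = []
        while unvisited:
            start = min(unvisited)
            comp: List[int] = []
            arc, slot = start, occ[start][1]
            while True:
                comp.append(arc)
                unvisited.discard(arc)
                cid, pos = slot
                exit_pos = (pos + 2) % 4
                nxt = self.crossings[cid].ends[exit_pos]
                a, b = occ[nxt]
                arc, slot = nxt, (b if a == (cid, exit_pos) else a)
                if arc == start and slot == occ[start][1]:
                    break
            comps.append(comp)
        comps.sort(key=lambda c: c[0])
        return comps

    def n_components(self) -> int:
        return len(self.components()) + self.free_loops

    # -------------------------------------------------- oriented arc structure
    def arc_heads(self) -> Dict[int, Tuple[int, int]]:
        """Map arc -> (crossing, pos) where the arc flows *into* a crossing.

        Raises :class:`DiagramError` if the stored roles do not define a
        consistent orientation (possible for diagrams produced by smoothing,
        which are fine for everything except oriented traversal).
        """
        heads: Dict[int, Tuple[int, int]] = {}
        tails: Dict[int, Tuple[int, int]] = {}
        for c in self.crossings.values():
            for pos, arc in enumerate(c.ends):
                role = c.role_of_pos(pos)
                book = heads if role.endswith("_in") else tails
                if arc in book:
                    raise DiagramError(f"arc {arc} is not consistently oriented")
                book[arc] = (c.id, pos)
        return heads

    # ------------------------------------------------------------- Gauss code
    def gauss_code(self, start: Optional[int] = None, direction: int = 1,
                   extended: bool = True) -> List[List[GaussEntry]]:
        """Emit the (extended) Gauss code by traversing the diagram.

        Starting on the over-passage of crossing ``start`` and leaving along
        the outgoing over-strand (direction +1; -1 walks the strand the
        other way), crossings are numbered 1, 2, ... in first-visit order.
        A passage on the over-strand gets sign +1, an under-passage -1; the
        extended form appends the handedness mark R (right-handed) or L.
        One entry list is returned per component; components after the first
        are visited in order of their smallest incident arc id.
        """
        if self.n == 0:
            return []
        if start is None:
            start = min(self.crossings)
        if start not in self.crossings:
            raise DiagramError(f"start {start} is not a crossing id")
        if direction not in (1, -1):
            raise DiagramError("direction must be +1 or -1")
        occ = self._slots_by_arc()
        labels: Dict[int, int] = {}
        visited = set()  # (crossing id, axis) with axis 0=under, 1=over

        def axis_of(pos: int) -> int:
            return 1 if pos in (1, 3) else 0

        def walk(cid: int, exit_pos: int) -> List[GaussEntry]:
            code: List[GaussEntry] = []
            while True:
                axis = axis_of(exit_pos)
                if (cid, axis) in visited:
                    break
                visited.add((cid, axis))
                if cid not in labels:
                    labels[cid] = len(labels) + 1
                cr = self.crossings[cid]
                code.append((labels[cid], +1 if axis else -1,
                             "R" if cr.sign > 0 else "L"))
                arc = cr.ends[exit_pos]
                a, b = occ[arc]
                ncid, npos = b if a == (cid, exit_pos) else a
                cid, exit_pos = ncid, (npos + 2) % 4
            return code

        c0 = self.crossings[start]
        first_exit = c0.over_out_pos if direction == 1 else c0.over_in_pos
        codes = [walk(start, first_exit)]
        for comp in self.components():
            arc = min(comp)
            cid, pos = occ[arc][1]
            if (cid, axis_of(pos)) not in visited:
                codes.append(walk(cid, (pos + 2) % 4))
        if not extended:
            codes = [[(l, s, "") for (l, s, _h) in code] for code in codes]
        self._last_gauss_labels = dict(labels)
        return codes

    def gauss_labels(self, start: Optional[int] = None,
                     direction: int = 1) -> Dict[int, int]:
        """First-visit number of each crossing along the Gauss traversal."""
        self.gauss_code(start, direction)
        return dict(self._last_gauss_labels)

    # ---------------------------------------------------------- serialization
    def to_json(self) -> dict:
        return {
            "crossings": [
                {"id": c.id, "sign": c.sign, "ends": list(c.ends)}
                for c in self.crossings.values()],
            "free_loops": self.free_loops,
            "coords": {str(i): list(p) for i, p in self.coords.items()},
        }

    @classmethod
    def from_json(cls, data: dict) -> "LinkDiagram":
        crossings = [Crossing(d["id"], d["sign"], tuple(d["ends"]))
                     for d in data.get("crossings", [])]
        coords = {int(i): tuple(p) for i, p in data.get("coords", {}).items()}
        return cls(crossings, data.get("free_loops", 0), coords)


def min_arc_key(circle: frozenset):
    """Sort key for circles: smallest contained arc id; free-loop markers
    sort after numeric arcs."""
    nums = [a for a in circle if isinstance(a, int)]
    if nums:
        return (0, min(nums))
    return (1, min(i for (_tag, i) in circle))


def format_gauss(codes: Sequence[Sequence[GaussEntry]]) -> str:
    """Text form, e.g. ``+1L,-2R,+3R``, with ``|`` between components."""
    return "|".join(
        ",".join(f"{'+' if s > 0 else '-'}{l}{h}" for (l, s, h) in code)
        for code in codes)


# ------------------------------------------------------------------ PD codes

_PD_TUPLE = re.compile(
    r"X[\(\[]\s*(-?\d+)\s*,\s*(-?\d+)\s*,\s*(-?\d+)\s*,\s*(-?\d+)\s*[\)\]]")
_PD_TOKEN = re.compile(r"(X[\(\[][^\)\]]*[\)\]]|O)")


def parse_pd(text: str, free_loops: int = 0) -> LinkDiagram:
    """Parse a PD-code string such as ``X(1,4,2,5) X(3,6,4,1) X(5,2,6,3)``.

    Tuples list the four arcs counterclockwise starting from the incoming
    under-strand.  Crossing signs are recovered from the over-strand
    orientation, which is propagated from the under-strand data (every arc
    appears exactly once as incoming and once as outgoing); any strand whose
    orientation is not forced is oriented so that arc ids ascend along it.
    A literal token ``O`` adds a crossing-free loop.
    """
    tuples: List[Tuple[int, int, int, int]] = []
    loops = free_loops
    consumed = []
    for m in _PD_TOKEN.finditer(text):
        consumed.append(m.span())
        tok = m.group(0)
        if tok == "O":
            loops += 1
            continue
        mt = _PD_TUPLE.match(tok)
        if not mt:
            raise PDParseError(
                f"malformed PD tuple {tok!r} at position {m.start()}")
        tuples.append(tuple(int(g) for g in mt.groups()))
    leftover = _PD_TOKEN.sub("", text)
    if leftover.strip().strip(",;"):
        raise PDParseError(
            f"unrecognized PD content {leftover.strip()!r}")

    occ: Dict[int, List[Tuple[int, int]]] = {}
    for ci, tup in enumerate(tuples):
        for p, arc in enumerate(tup):
            occ.setdefault(arc, []).append((ci, p))
    for arc, slots in occ.items():
        if len(slots) != 2:
            raise PDParseError(
                f"dangling arc id {arc}: occurs {len(slots)} time(s), expected 2")

    # orientation roles per slot: "in", "out" or None (unknown)
    role: List[List[Optional[str]]] = [[None] * 4 for _ in tuples]
    for ci in range(len(tuples)):
        role[ci][0] = "in"
        role[ci][2] = "out"

    def other_slot(arc: int, slot: Tuple[int, int]) -> Tuple[int, int]:
        a, b = occ[arc]
        return b if a == slot else a

    def propagate() -> None:
        changed = True
        while changed:
            changed = False
            for ci, tup in enumerate(tuples):
                for p in (1, 3):
                    if role[ci][p] is not None:
                        continue
                    arc = tup[p]
                    oc, op = other_slot(arc, (ci, p))
                    if role[oc][op] is not None:
                        role[ci][p] = "out" if role[oc][op] == "in" else "in"
                        changed = True
                    elif role[ci][4 - p] is not None:
                        role[ci][p] = "out" if role[ci][4 - p] == "in" else "in"
                        changed = True

    propagate()
    for ci, tup in enumerate(tuples):
        for p in (1, 3):
            if role[ci][p] is None:
                # strand never goes under anything: orient by ascending ids
                arc = tup[p]
                oc, op = other_slot(arc, (ci, p))
                neighbour = tuples[oc][(op + 2) % 4]
                role[ci][p] = "in" if neighbour >= arc else "out"
                propagate()

    crossings = []
    for ci, tup in enumerate(tuples):
        if role[ci][1] == role[ci][3]:
            raise PDParseError(
                f"crossing {ci + 1}: inconsistent over-strand orientation")
        sign = +1 if role[ci][3] == "in" else -1
        crossings.append(Crossing(ci + 1, sign, tup))
    return LinkDiagram(crossings, loops)


def emit_pd(d: LinkDiagram) -> str:
    """Inverse of :func:`parse_pd` (up to arc relabeling)."""
    parts = ["X({},{},{},{})".format(*c.ends) for c in d.crossings.values()]
    parts += ["O"] * d.free_loops
    return " ".join(parts)
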