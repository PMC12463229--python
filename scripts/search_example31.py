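"""Bounded brute-force search for the 4-crossing demonstration fixture.

Wanted: a planar 4-crossing link diagram L with crossings labelable
x1..x4 such that

  * L is an unlink diagram (Jhat = (q+q^-1)^components);
  * rho_{x3} rho_{x1} L is the negative Hopf link
    (Jhat = 1 + q^-2 + q^-4 + q^-6);
  * the filtration rho_{x1}, rho_{x2}rho_{x1}, ... (ascending label
    order) passes only through unlink diagrams.

Shadows are enumerated as pairings of 8 strand passages distributed over
one or two circles; planarity is checked by counting rotation-system
faces (V - E + F = 2).  Every under/over choice, handedness choice and
crossing labeling is tried.  The scan is deterministic; the first hit in
sort order is the one committed to ekhom.fixtures.example31_diagram.

Result of the full scan: all solutions are relabelings/reflections of a
single two-component configuration — a right-handed clasp x1, x3 stacked
against a left-handed clasp x2, x4 between the same two circles — with
signs (+1, -1, +1, -1).  No all-left-handed solution exists.

Usage: python scripts/search_example31.py   (takes a few minutes)
"""

from itertools import permutations, product

from ekhom.bracket import unnormalized_jones_q
from ekhom.diagram import Crossing, LinkDiagram, emit_pd
from ekhom.laurent import LaurentPolynomial

UNKNOT = LaurentPolynomial({1: 1, -1: 1}, "q")
HOPF_NEG = LaurentPolynomial({0: 1, -2: 1, -4: 1, -6: 1}, "q")


def pairings(slots):
    if not slots:
        yield []
        return
    a = slots[0]
    for i in range(1, len(slots)):
        b = slots[i]
        rest = slots[1:i] + slots[i + 1:]
        for rem in pairings(rest):
            yield [(a, b)] + rem


def build(split, pairing, unders, signs):
    """Diagram from a shadow: ``split`` gives passage counts per circle,
    passages are numbered blockwise along each circle."""
    inarc, outarc = {}, {}
    base = 0
    for k in split:
        for j in range(k):
            inarc[base + j] = base + j + 1
            outarc[base + j] = base + (j + 1) % k + 1
        base += k
    crossings = []
    for cid, ((i, j), under_first, sign) in enumerate(
            zip(pairing, unders, signs), start=1):
        u, o = (i, j) if under_first else (j, i)
        if sign > 0:
            ends = (inarc[u], outarc[o], outarc[u], inarc[o])
        else:
            ends = (inarc[u], inarc[o], outarc[u], outarc[o])
        crossings.append(Crossing(cid, sign, ends))
    return LinkDiagram(crossings)


def is_planar(d: LinkDiagram) -> bool:
    occ = d._slots_by_arc()

    def alpha(slot):
        a, b = occ[d.crossings[slot[0]].ends[slot[1]]]
        return b if a == slot else a

    seen, faces = set(), 0
    for dart in [(c, p) for c in d.crossings for p in range(4)]:
        if dart in seen:
            continue
        faces += 1
        cur = dart
        while cur not in seen:
            seen.add(cur)
            c, p = alpha(cur)
            cur = (c, (p + 1) % 4)
    return faces == d.n + 2


def main():
    hits = {}
    for split in [(8,), (1, 7), (2, 6), (3, 5), (4, 4)]:
        for pairing in pairings(list(range(8))):
            for unders in product((True, False), repeat=4):
                for signs in product((-1, 1), repeat=4):
                    try:
                        d = build(split, pairing, unders, signs)
                    except Exception:
                        continue
                    if len(d.components()) != len(split):
                        continue
                    if not is_planar(d):
                        continue
                    unlink = UNKNOT ** d.n_components()
                    if unnormalized_jones_q(d) != unlink:
                        continue
                    stage = {}
                    ids = d.crossing_ids()
                    for r in range(1, 5):
                        for S in permutations(ids, r):
                            S = frozenset(S)
                            if S not in stage:
                                sd = d.rho_set(S)
                                stage[S] = (unnormalized_jones_q(sd),
                                            sd.n_components())
                    for perm in permutations(ids):
                        lab = {i + 1: perm[i] for i in range(4)}
                        jh, _ = stage[frozenset({lab[1], lab[3]})]
                        if jh != HOPF_NEG:
                            continue
                        ok = True
                        for stop in range(1, 5):
                            S = frozenset(lab[i] for i in range(1, stop + 1))
                            jhs, nc = stage[S]
                            if jhs != UNKNOT ** nc:
                                ok = False
                                break
                        if not ok:
                            continue
                        relabeled = LinkDiagram(
                            [Crossing(i, d.crossings[lab[i]].sign,
                                      d.crossings[lab[i]].ends)
                             for i in (1, 2, 3, 4)])
                        sgns = tuple(relabeled.crossings[i].sign
                                     for i in (1, 2, 3, 4))
                        hits[emit_pd(relabeled)] = (split, sgns)
    print(f"{len(hits)} labeled hits")
    for key in sorted(hits)[:5]:
        print(" ", hits[key], key)
    if hits:
        first = sorted(hits)[0]
        print("committed candidate:", first, "signs", hits[first][1])


if __name__ == "__main__":
    main()
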