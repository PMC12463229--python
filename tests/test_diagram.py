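"""Link diagram model: PD parsing, smoothing, resolution, Gauss codes."""

from itertools import combinations, product

import pytest

from ekhom.bracket import unnormalized_jones_q
from ekhom.diagram import (DiagramError, LinkDiagram, PDParseError,
                           emit_pd, format_gauss, parse_pd)

from conftest import random_braid_diagram

TREFOIL_PD = "X(1,4,2,5) X(3,6,4,1) X(5,2,6,3)"
HOPF_PD = "X(4,1,3,2) X(2,3,1,4)"


class TestParsePD:
    def test_left_trefoil_signs(self):
        d = parse_pd(TREFOIL_PD)
        assert (d.n, d.n_plus, d.n_minus) == (3, 0, 3)

    def test_crossingless_unknot(self):
        d = parse_pd("O")
        assert d.n == 0 and d.free_loops == 1
        assert parse_pd("", free_loops=1) == d

    def test_hopf_two_components(self):
        d = parse_pd(HOPF_PD)
        assert d.n == 2
        assert d.n_components() == 2
        assert {c.sign for c in d.crossings.values()} == {-1}

    def test_dangling_arc_is_reported(self):
        with pytest.raises(PDParseError, match="arc"):
            parse_pd("X(1,2,3,4)")

    def test_malformed_tuple_is_reported(self):
        with pytest.raises(PDParseError):
            parse_pd("X(1,2,3) X(1,2,3,4)")

    def test_round_trip(self, table):
        for name in ("trefoil_left", "figure_eight", "hopf_negative",
                     "seven_six"):
            d = table[name].diagram
            again = parse_pd(emit_pd(d))
            assert [c.ends for c in again.crossings.values()] == \
                   [c.ends for c in d.crossings.values()]
            assert [c.sign for c in again.crossings.values()] == \
                   [c.sign for c in d.crossings.values()]

    def test_json_round_trip(self, example31):
        # explicit-sign serialization survives where PD text would not
        # (one component of this link never passes under the other)
        again = LinkDiagram.from_json(example31.to_json())
        assert again == example31


class TestWrithe:
    def test_paper_values(self, table):
        assert table["trefoil_left"].diagram.writhe() == -3
        assert table["unknot"].diagram.writhe() == 0

    def test_mirror_negates(self, table):
        for entry in table.values():
            assert entry.diagram.mirror().writhe() == -entry.diagram.writhe()


class TestResolve:
    @pytest.mark.parametrize("state,circles", [
        ((0, 0, 0), 3), ((1, 0, 1), 1), ((1, 1, 1), 2)])
    def test_trefoil_circle_counts(self, trefoil, state, circles):
        assert trefoil.resolve(state).count == circles

    def test_every_state_has_a_circle(self, table):
        for entry in table.values():
            d = entry.diagram
            if d.n > 5:
                continue
            states = list(product((0, 1), repeat=d.n))
            assert len(states) == 2 ** d.n
            assert all(d.resolve(s).count >= 1 for s in states)

    def test_incomplete_state_error(self, trefoil):
        with pytest.raises(DiagramError, match="unassigned"):
            trefoil.resolve({1: 0, 2: 1})


class TestSmoothing:
    def test_rho_of_trefoil_is_hopf(self, trefoil, table):
        for x in trefoil.crossing_ids():
            h = trefoil.rho(x)
            assert h.n == 2
            assert unnormalized_jones_q(h) == table["hopf_negative"].jones_hat

    def test_kink_smoothings(self):
        kink = parse_pd("X(1,1,2,2)")  # right-handed curl
        split = kink.smooth(1, 0)
        merged = kink.smooth(1, 1)
        assert (split.n, split.free_loops) == (0, 2)
        assert (merged.n, merged.free_loops) == (0, 1)

    def test_unknown_crossing_error(self, trefoil):
        with pytest.raises(DiagramError):
            trefoil.smooth(99, 0)
        with pytest.raises(DiagramError):
            LinkDiagram([], free_loops=1).rho(1)

    def test_rho_commutes(self, table):
        # smoothing operators commute pairwise on every fixture
        for entry in table.values():
            d = entry.diagram
            for x, y in combinations(d.crossing_ids(), 2):
                assert d.rho(x).rho(y) == d.rho(y).rho(x)

    def test_rho_set_order_independent(self, rng, seven_six):
        ids = seven_six.crossing_ids()
        ref = seven_six.rho_set(ids)
        for _ in range(5):
            order = list(rng.permutation(ids))
            d = seven_six
            for x in order:
                d = d.rho(x)
            assert d == ref

    def test_rho_set_identities(self, example31, table):
        assert example31.rho_set(set()) == example31
        hopf = example31.rho_set({1, 3})
        assert unnormalized_jones_q(hopf) == table["hopf_negative"].jones_hat
        for entry in table.values():
            full = entry.diagram.rho_set(entry.diagram.crossing_ids())
            assert full.n == 0 and full.free_loops >= 1

    def test_smooth_preserves_signs_and_coords(self, trefoil):
        d = LinkDiagram(trefoil.crossings.values(),
                        coords={1: (0, 0), 2: (1, 0), 3: (0, 1)})
        s = d.smooth(2, 0)
        assert {c.sign for c in s.crossings.values()} == {-1}
        assert s.coords == {1: (0, 0), 3: (0, 1)}


class TestGaussCode:
    def test_trefoil_code(self, trefoil):
        codes = trefoil.gauss_code(1)
        assert len(codes) == 1
        code = codes[0]
        assert len(code) == 6
        signs = [s for (_l, s, _h) in code]
        assert signs == [1, -1, 1, -1, 1, -1] or signs == [-1, 1, -1, 1, -1, 1]
        assert {h for (_l, _s, h) in code} == {"L"}
        assert format_gauss(codes).count(",") == 5

    @pytest.mark.parametrize("name", ["trefoil_left", "figure_eight",
                                      "seven_six", "unknot_2x"])
    def test_labels_appear_twice_with_opposite_passage(self, table, name):
        d = table[name].diagram
        code = d.gauss_code(min(d.crossings))[0]
        by_label = {}
        for (l, s, h) in code:
            by_label.setdefault(l, []).append((s, h))
        assert len(by_label) == d.n
        for l, occ in by_label.items():
            assert sorted(s for s, _ in occ) == [-1, 1]
            assert len({h for _, h in occ}) == 1

    def test_direction_reverses(self, trefoil):
        fwd = trefoil.gauss_code(1, 1)[0]
        bwd = trefoil.gauss_code(1, -1)[0]
        assert len(fwd) == len(bwd) == 6
        assert fwd[0][0] == bwd[0][0] == 1

    def test_bad_start(self, trefoil):
        with pytest.raises(DiagramError):
            trefoil.gauss_code(17)

    def test_random_diagram_label_invariant(self, rng):
        for _ in range(10):
            d = random_braid_diagram(rng, 6)
            if d.n == 0:
                continue
            counts = {}
            for code in d.gauss_code():
                for (l, s, _h) in code:
                    counts[l] = counts.get(l, 0) + 1
            assert all(v == 2 for v in counts.values())
            assert len(counts) == d.n


class TestOrientation:
    def test_consistent_orientation_idempotent(self, table):
        for name in ("trefoil_left", "figure_eight", "hopf_negative"):
            d = table[name].diagram
            assert d.with_consistent_orientation() == d

    def test_arc_heads_total(self, trefoil):
        heads = trefoil.arc_heads()
        assert sorted(heads) == trefoil.arc_ids()
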