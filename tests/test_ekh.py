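"""Evolutionary Khovanov homology: filtered complexes, ranks, barcodes."""

from itertools import product

import pytest

from ekhom.bracket import unnormalized_jones_q
from ekhom.diagram import LinkDiagram
from ekhom.ekh import (FiltrationError, barcode, build_filtered_complex,
                       ekh_rank, evolutionary_betti, evolutionary_jones,
                       poincare_over_filtration)
from ekhom.filtration import WeightedLink, filtration_sequence, indexed_link
from ekhom.khovanov import build_complex, homology
from ekhom.laurent import LaurentPolynomial

from conftest import random_braid_diagram

P = LaurentPolynomial


def weighted_trefoil(trefoil):
    return WeightedLink(trefoil, {1: 1, 2: 2, 3: 3}, "ascending")


def random_negative_weighted(rng, max_crossings=5):
    d = random_braid_diagram(rng, max_crossings, all_negative=True)
    weights = {x: float(rng.integers(1, 4)) for x in d.crossing_ids()}
    return WeightedLink(d, weights, "ascending")


class TestFilteredComplex:
    def test_trefoil_stage_ranks_match_state_sum(self, trefoil):
        w = weighted_trefoil(trefoil)
        fc = build_filtered_complex(w)
        seq = filtration_sequence(w)
        expected = []
        for stage in seq.diagrams:
            total = sum(2 ** stage.resolve(s).count
                        for s in product((0, 1), repeat=stage.n))
            expected.append(total)
        assert expected == [30, 12, 6, 4]
        assert [fc.stage_rank(i) for i in range(fc.n_stages)] == expected

    def test_sub_bases_closed_under_differential(self, rng, trefoil):
        links = [weighted_trefoil(trefoil)]
        links += [random_negative_weighted(rng) for _ in range(5)]
        for w in links:
            fc = build_filtered_complex(w)
            cx = fc.complex
            for i in range(fc.n_stages):
                members = set(fc.stage_members(i))
                for (k, row) in members:
                    col = cx.matrix(k)[row] if cx.matrix(k) else {}
                    for r in col:
                        assert (k + 1, r) in members

    def test_fully_smoothed_stage_is_single_state(self, trefoil):
        fc = build_filtered_complex(weighted_trefoil(trefoil))
        last = fc.n_stages - 1
        members = fc.stage_members(last)
        states = {fc.complex.basis[k][r].state for (k, r) in members}
        assert len(states) == 1
        gamma = filtration_sequence(weighted_trefoil(trefoil)) \
            .diagrams[-1].free_loops
        assert len(members) == 2 ** gamma

    def test_integral_coefficients_rejected(self, trefoil):
        with pytest.raises(FiltrationError, match="field"):
            build_filtered_complex(weighted_trefoil(trefoil), "Z")

    def test_right_handed_tower_rejected(self, table):
        d = table["trefoil_right"].diagram
        w = WeightedLink(d, {x: x for x in d.crossing_ids()}, "ascending")
        with pytest.raises(FiltrationError, match="right-handed"):
            barcode(w)


class TestEkhRank:
    def test_trefoil_window(self, trefoil):
        w = weighted_trefoil(trefoil)
        assert ekh_rank(w, 0, 1) == {(-2, -5): 1, (0, -3): 1, (0, -1): 1}
        assert ekh_rank(w, 0, 1, k=0) == 2

    def test_diagonal_equals_stage_homology(self, trefoil, example31):
        for d, weights in [(trefoil, {1: 1, 2: 2, 3: 3}),
                           (example31, {1: 1, 2: 3, 3: 2, 4: 4})]:
            w = WeightedLink(d, weights, "ascending")
            for a in [0.0] + sorted(set(weights.values())):
                table = ekh_rank(w, a, a)
                h = homology(build_complex(indexed_link(w, a)), "Q")
                got = {}
                for (k, l), r in table.items():
                    got[k] = got.get(k, 0) + r
                assert got == {k: h.rank(k) for k in h.heights() if h.rank(k)}

    def test_bad_window(self, trefoil):
        with pytest.raises(FiltrationError):
            ekh_rank(weighted_trefoil(trefoil), 2, 1)

    def test_functoriality_rank_inequality(self, rng):
        for _ in range(6):
            w = random_negative_weighted(rng)
            params = [0.0] + sorted(set(w.weights.values()))
            if len(params) < 3:
                continue
            a, b, c = params[0], params[1], params[-1]
            for k in range(-w.diagram.n, 1):
                rac = ekh_rank(w, a, c, k)
                rab = ekh_rank(w, a, b, k)
                rbc = ekh_rank(w, b, c, k)
                assert rac <= min(rab, rbc)

    def test_rank_agrees_with_barcode(self, rng, trefoil):
        links = [weighted_trefoil(trefoil)]
        links += [random_negative_weighted(rng) for _ in range(4)]
        for w in links:
            bc = barcode(w)
            params = w.stage_parameters()
            for i in range(len(params)):
                for j in range(i, len(params)):
                    spanning = bc.spanning(i, j)
                    for k in {b.height for b in bc.bars}:
                        direct = ekh_rank(w, params[i], params[j], k)
                        alive = sum(1 for b in spanning if b.height == k)
                        assert direct == alive


class TestBarcode:
    def test_trefoil_window_bars(self, trefoil):
        bc = barcode(weighted_trefoil(trefoil))
        span = bc.spanning(0, 1)
        assert len(span) == 3
        assert sorted(b.degree_profile[0] for b in span) == [-5, -3, -1]
        assert sorted(b.degree_profile[1] for b in span) == [-4, -2, 0]
        assert sorted(b.height for b in span) == [-2, 0, 0]

    def test_trefoil_torsion_class_is_short_bar(self, trefoil):
        bc = barcode(weighted_trefoil(trefoil))
        short = [b for b in bc.bars if b.height == -2 and b.length() == 0]
        assert len(short) == 1
        assert short[0].degree_profile == {1: -6}

    def test_alive_counts_match_stage_homology(self, rng, trefoil):
        links = [weighted_trefoil(trefoil)]
        links += [random_negative_weighted(rng, 6) for _ in range(6)]
        for w in links:
            bc = barcode(w)
            seq = filtration_sequence(w)
            for i, stage in enumerate(seq.diagrams):
                h = homology(build_complex(stage), "Q")
                heights = set(h.heights()) | {b.height for b in bc.bars}
                for k in heights:
                    assert bc.alive_at_stage(i, k) == h.rank(k), (i, k)

    def test_crossingless_unknot_immortal_pair(self):
        w = WeightedLink(LinkDiagram([], free_loops=1), {}, "ascending")
        bc = barcode(w)
        assert len(bc.bars) == 2
        assert all(b.reaches_original and b.height == 0 for b in bc.bars)
        assert sorted(b.degree_profile[0] for b in bc.bars) == [-1, 1]

    def test_degree_profile_shifts_by_smoothing_count(self, rng):
        for _ in range(4):
            w = random_negative_weighted(rng)
            fc_params = w.stage_parameters()
            sets = [w.smoothed_set(a) for a in fc_params]
            sets[0] = frozenset()
            for b in barcode(w).bars:
                base = b.degree_profile[b.stage_lo]
                for i, deg in b.degree_profile.items():
                    assert deg - base == len(sets[i]) - len(sets[b.stage_lo])

    def test_mode_metadata(self, trefoil):
        bc = barcode(weighted_trefoil(trefoil))
        assert bc.mode == "ascending"
        assert bc.parameters == [0.0, 1, 2, 3]
        assert bc.to_json()["bars"]


class TestExampleContrast:
    """An unlink diagram whose EKH depends on the weighting: the
    headline "unknotted yet non-trivial" phenomenon."""

    def test_f_weights_stay_trivial(self, example31):
        w = WeightedLink(example31, {1: 1, 2: 2, 3: 3, 4: 5}, "ascending")
        for a in [0] + sorted(w.weights.values()):
            h = homology(build_complex(indexed_link(w, a)), "Q")
            assert h.heights() == [0]

    def test_g_weights_detect_hopf(self, example31):
        g = WeightedLink(example31, {1: 1, 2: 3, 3: 2, 4: 4}, "ascending")
        t = ekh_rank(g, 2, 2)
        assert sum(t.values()) == 4
        by_height = {}
        for (k, l), r in t.items():
            by_height[k] = by_height.get(k, 0) + r
        assert by_height == {-2: 2, 0: 2}


class TestEvolutionaryInvariants:
    def test_trefoil_window_jones(self, trefoil):
        w = weighted_trefoil(trefoil)
        assert evolutionary_jones(w, 0, 1) == P({-1: 1, -3: 1, -5: 1})

    def test_diagonal_equals_unnormalized_jones(self, rng, trefoil):
        links = [weighted_trefoil(trefoil)]
        links += [random_negative_weighted(rng) for _ in range(4)]
        for w in links:
            for a in w.stage_parameters():
                stage = indexed_link(w, a)
                got = evolutionary_jones(w, a, a)
                assert got == unnormalized_jones_q(stage)

    def test_empty_image_has_zero_rank(self, trefoil):
        # the torsion-born class at height -2 exists only at the Hopf stage:
        # any window across later stages has empty image there
        w = weighted_trefoil(trefoil)
        assert ekh_rank(w, 1, 3, k=-2) == 0
        assert all(k != -2 for (k, _l) in evolutionary_betti(w, 1, 3))

    def test_betti_table_keys(self, trefoil):
        w = weighted_trefoil(trefoil)
        t = evolutionary_betti(w, 0, 1)
        assert set(t) == {(-2, -5), (0, -3), (0, -1)}


class TestPoincareOverFiltration:
    def test_trefoil_stage_euler_equals_jones(self, trefoil):
        w = weighted_trefoil(trefoil)
        stages = poincare_over_filtration(w)
        seq = filtration_sequence(w)
        for (a, poly), d in zip(stages, seq.diagrams):
            assert poly.specialize_t(-1) == unnormalized_jones_q(d)

    def test_crossingless_stage_is_delta_power(self, trefoil):
        w = weighted_trefoil(trefoil)
        a, poly = poincare_over_filtration(w)[-1]
        gamma = filtration_sequence(w).diagrams[-1].free_loops
        assert poly.specialize_t(-1) == P({1: 1, -1: 1}) ** gamma
        assert all(t == 0 for (t, _q) in poly.coeffs)

    def test_mixed_handedness_supported(self, table):
        # stage-wise summaries need no maps, so any diagram works
        d = table["figure_eight"].diagram
        w = WeightedLink(d, {x: x for x in d.crossing_ids()}, "ascending")
        stages = poincare_over_filtration(w)
        assert len(stages) == 5
        for a, poly in stages:
            sd = indexed_link(w, a)
            assert poly.specialize_t(-1) == unnormalized_jones_q(sd)
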