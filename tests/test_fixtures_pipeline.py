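"""Fixture table self-consistency, synthetic curves, pipeline and CLI."""

import cmath
import json

import pytest
from click.testing import CliRunner

from ekhom.bracket import bracket_a, unnormalized_jones_q
from ekhom.cli import main as cli_main
from ekhom.diagram import DiagramError
from ekhom.ekh import barcode, poincare_over_filtration
from ekhom.filtration import WeightedLink
from ekhom.fixtures import (EXAMPLE_76_CROSSING_COORDS, fixture_table,
                            from_braid, synthetic_curve)
from ekhom.khovanov import build_complex, graded_euler, homology
from ekhom.laurent import LaurentPolynomial
from ekhom.pipeline import RunConfig, load_diagram, run_pipeline
from ekhom.projection import project

P = LaurentPolynomial


class TestFixtureTable:
    def test_loads_and_self_checks(self, table):
        assert {"unknot", "hopf_negative", "trefoil_left", "figure_eight",
                "seven_six", "example31"} <= set(table)

    def test_every_fixture_satisfies_categorification(self, table):
        for entry in table.values():
            if entry.diagram.n > 5:
                continue
            h = homology(build_complex(entry.diagram), "Q")
            assert graded_euler(h) == entry.jones_hat, entry.name

    def test_example31_smoothing_has_rank_four(self, table):
        d = table["example31"].diagram
        h = homology(build_complex(d.rho_set({1, 3})), "Q")
        assert h.total_rank() == 4
        assert {k: h.rank(k) for k in h.heights()} == {-2: 2, 0: 2}

    def test_trefoil_fixture_jones(self, table):
        assert table["trefoil_left"].jones_hat == \
            P({-1: 1, -3: 1, -5: 1, -9: -1})

    def test_hopf_fixture_homology(self, table):
        h = homology(build_complex(table["hopf_negative"].diagram), "Q")
        assert {k: h.rank(k) for k in h.heights()} == {-2: 2, 0: 2}

    def test_seven_six_is_det_19_alternating(self, seven_six):
        det = abs(bracket_a(seven_six).evaluate(cmath.exp(1j * cmath.pi / 4)))
        assert det == pytest.approx(19.0)
        assert seven_six.n == 7 and seven_six.n_components() == 1
        code = seven_six.gauss_code(1)[0]
        assert all(code[i][1] != code[i + 1][1] for i in range(len(code) - 1))


class TestBraids:
    def test_trace_closures(self, table):
        assert unnormalized_jones_q(from_braid([1, 1, 1])) == \
            table["trefoil_right"].jones_hat
        assert from_braid([-1, -1]).n_components() == 2

    def test_unused_strand_becomes_free_loop(self):
        d = from_braid([1], strands=3)
        assert d.free_loops == 1

    def test_plat_needs_even_strands(self):
        with pytest.raises(DiagramError, match="even"):
            from_braid([1, 1], strands=3, closure="plat")

    def test_bad_word(self):
        with pytest.raises(DiagramError):
            from_braid([0], strands=2)
        with pytest.raises(DiagramError):
            from_braid([], strands=None)


class TestSyntheticCurves:
    def test_torus_projects_to_three_crossings(self):
        d = project(synthetic_curve("torus", 60), "xy").diagram
        assert d.n == 3

    def test_circle_has_no_crossings(self):
        for samples in (12, 30):
            d = project(synthetic_curve("circle", samples), "xy").diagram
            assert d.n == 0

    def test_random_walk_deterministic(self):
        a = project(synthetic_curve("random_walk", 30, seed=5), "xy", seed=0)
        b = project(synthetic_curve("random_walk", 30, seed=5), "xy", seed=0)
        assert a.diagram == b.diagram

    def test_too_few_samples(self):
        with pytest.raises(DiagramError, match="12"):
            synthetic_curve("circle", 8)


class TestPipeline:
    def test_explicit_weights_trefoil(self, tmp_path):
        cfg = RunConfig(source="fixture:trefoil_left", mode="explicit",
                        weights={1: 1, 2: 2, 3: 3},
                        out_dir=str(tmp_path / "out"))
        bundle = run_pipeline(cfg)
        bars = bundle["barcode"]["bars"]
        spanning = [b for b in bars
                    if b["stage_span"][0] <= 0 and b["stage_span"][1] >= 1]
        assert len(spanning) == 3
        assert (tmp_path / "out" / "barcode.json").exists()
        assert (tmp_path / "out" / "homology.csv").exists()

    def test_curve_end_to_end(self, tmp_path):
        path = tmp_path / "curve.csv"
        pts = synthetic_curve("torus", 50).components[0]
        path.write_text("x,y,z\n" + "\n".join(
            f"{x},{y},{z}" for (x, y, z) in pts))
        cfg = RunConfig(source=str(path), mode="unzip",
                        out_dir=str(tmp_path / "out"))
        bundle = run_pipeline(cfg)
        assert bundle["diagram"]["crossings"] == 3
        assert bundle["barcode"] is not None

    def test_mixed_handedness_reports_skip(self):
        cfg = RunConfig(source="fixture:figure_eight", mode="unzip")
        bundle = run_pipeline(cfg)
        assert bundle["barcode"] is None
        assert "right-handed" in bundle["barcode_skipped"]
        assert bundle["stage_homology"]

    def test_determinism_byte_identical(self, tmp_path):
        outs = []
        for run in ("a", "b"):
            cfg = RunConfig(source="fixture:trefoil_left", mode="unzip",
                            out_dir=str(tmp_path / run))
            run_pipeline(cfg)
            outs.append((tmp_path / run / "manifest.json").read_bytes())
        assert outs[0] == outs[1]

    def test_config_round_trip(self, tmp_path):
        cfg = RunConfig(source="fixture:trefoil_left", mode="explicit",
                        weights={1: 1.0, 2: 2.0, 3: 3.0})
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps(cfg.to_json()))
        again = RunConfig.from_file(path)
        assert again.weights == {1: 1.0, 2: 2.0, 3: 3.0}
        assert again.source == cfg.source

    def test_load_diagram_sources(self, trefoil):
        assert load_diagram("fixture:trefoil_left") == trefoil
        assert load_diagram("X(1,4,2,5) X(3,6,4,1) X(5,2,6,3)").n == 3
        with pytest.raises(ValueError, match="fixture"):
            load_diagram("fixture:nope")


class TestCLI:
    def run(self, *args):
        result = CliRunner().invoke(cli_main, list(args))
        assert result.exit_code == 0, result.output
        return result.output

    def test_diagram(self):
        out = self.run("diagram", "fixture:trefoil_left")
        assert "writhe:     -3" in out

    def test_jones(self):
        out = self.run("jones", "fixture:trefoil_left")
        assert "q^-1 + q^-3 + q^-5 - q^-9" in out

    def test_khovanov(self):
        out = self.run("khovanov", "fixture:trefoil_left", "--coeff", "Z")
        assert "torsion=2" in out

    def test_filter_and_ekh(self, tmp_path):
        out = self.run("filter", "fixture:trefoil_left", "--mode", "unzip")
        assert "weight" in out
        out = self.run("ekh", "fixture:trefoil_left", "--mode", "unzip",
                       "--out", str(tmp_path / "bc.json"))
        assert "reaches original" in out
        assert (tmp_path / "bc.json").exists()

    def test_ekh_window_unzip(self):
        out = self.run("ekh", "fixture:trefoil_left", "--mode", "unzip",
                       "--window", "0,1")
        assert "rank=1" in out

    def test_pipeline_command(self, tmp_path):
        out = self.run("pipeline", "--source", "fixture:trefoil_left",
                       "--mode", "unzip", "--out-dir", str(tmp_path / "o"))
        assert (tmp_path / "o" / "manifest.json").exists()


class TestPlotting:
    def test_barcode_and_surface_helpers(self, trefoil):
        from ekhom.plotting import plot_barcode, plot_poincare_surface
        w = WeightedLink(trefoil, {1: 1, 2: 2, 3: 3}, "ascending")
        ax = plot_barcode(barcode(w))
        assert ax is not None
        ax2 = plot_poincare_surface(poincare_over_filtration(w))
        assert ax2 is not None
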