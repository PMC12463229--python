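"""End-to-end runs: read -> close -> project -> weight -> filter -> EKH.

The pipeline is deliberately thin glue over the library modules; each step
logs the diagram statistics it produced and its wall time.  Outputs are
JSON/CSV; identical configuration and seed give byte-identical files
(timings are logged, not serialized).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional

from .bracket import unnormalized_jones_q
from .diagram import LinkDiagram, emit_pd, parse_pd
from .ekh import FiltrationError, barcode
from .filtration import (WeightedLink, distance_weights, filtration_sequence,
                         unzip_weights)
from .khovanov import build_complex, homology
from .projection import close_curve, project, read_backbone, read_xyz

__all__ = ["RunConfig", "run_pipeline", "load_diagram"]

log = logging.getLogger("ekhom")


@dataclass
class RunConfig:
    """Configuration of a pipeline run; all defaults documented inline."""
    source: str                      # path, "fixture:<name>", or a PD code
    plane: str = "xy"                # projection plane for curve inputs
    atom: str = "P"                  # backbone atom for PDB inputs (P or CA)
    chain: Optional[str] = None      # PDB chain selector (None = all chains)
    close: bool = True               # close open curves end-to-end
    mode: str = "distance"           # distance | unzip | explicit
    convention: str = "half"         # distance convention: half | full
    start: Optional[int] = None      # unzip start crossing (None = smallest id)
    direction: int = 1               # unzip traversal direction (+1 / -1)
    weights: Optional[Dict[int, float]] = None   # explicit crossing weights
    coeff: str = "Q"                 # field: "Q" or a prime such as 2
    seed: int = 0                    # seed for projection regularity retries
    out_dir: Optional[str] = None    # write JSON/CSV artifacts here
    log_level: str = "INFO"

    def to_json(self) -> dict:
        d = asdict(self)
        d.pop("out_dir", None)   # keep serialized manifests path-free
        if d["weights"] is not None:
            d["weights"] = {str(k): v for k, v in d["weights"].items()}
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if data.get("weights"):
            data["weights"] = {int(k): float(v)
                               for k, v in data["weights"].items()}
        return cls(**data)


def load_diagram(source: str, cfg: Optional[RunConfig] = None) -> LinkDiagram:
    """Resolve a diagram from a fixture name, PD code, diagram JSON, or a
    curve file (xyz/CSV/PDB, projected per the config)."""
    cfg = cfg or RunConfig(source=source)
    if source.startswith("fixture:"):
        from .fixtures import fixture_table
        name = source.split(":", 1)[1]
        table = fixture_table()
        if name not in table:
            raise ValueError(
                f"unknown fixture {name!r}; available: {sorted(table)}")
        return table[name].diagram
    if source.lstrip().startswith("X"):
        return parse_pd(source)
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return LinkDiagram.from_json(json.loads(path.read_text()))
    if suffix in (".pd", ".txt"):
        return parse_pd(path.read_text())
    if suffix in (".pdb", ".ent"):
        curve = read_backbone(path, atom=cfg.atom, chain=cfg.chain)
    elif suffix in (".xyz", ".csv"):
        curve = read_xyz(path)
    else:
        raise ValueError(f"cannot infer input kind of {source!r}")
    if cfg.close:
        curve = close_curve(curve)
    result = project(curve, cfg.plane, seed=cfg.seed)
    log.info("projection: plane=%s retries=%d -> %r",
             cfg.plane, result.retries, result.diagram)
    return result.diagram


def _coeff(cfg: RunConfig):
    return "Q" if cfg.coeff.upper() == "Q" else int(cfg.coeff.lstrip("Ff"))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and return the artifact bundle.

    The bundle maps stage names to JSON-serializable results; if
    ``cfg.out_dir`` is set, ``manifest.json``, ``weights.csv``,
    ``filtration.json``, ``homology.csv`` and (when defined)
    ``barcode.json`` are written there.
    """
    logging.basicConfig(level=cfg.log_level)
    timings: Dict[str, float] = {}
    bundle: Dict[str, object] = {"config": cfg.to_json()}

    def step(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0
                log.info("stage %-12s %.3f s", name, timings[name])
        return _T()

    with step("read"):
        d = load_diagram(cfg.source, cfg)
    bundle["diagram"] = {
        "pd": emit_pd(d), "crossings": d.n, "n_plus": d.n_plus,
        "n_minus": d.n_minus, "components": d.n_components(),
        "writhe": d.writhe(),
        "jones_hat": unnormalized_jones_q(d).to_dict(),
    }
    log.info("diagram: %r writhe=%d components=%d",
             d, d.writhe(), d.n_components())

    with step("weights"):
        if cfg.mode == "distance":
            weights = distance_weights(d, cfg.convention)
            mode = "descending"
        elif cfg.mode == "unzip":
            weights = unzip_weights(d, cfg.start, cfg.direction)
            mode = "ascending"
        elif cfg.mode == "explicit":
            if not cfg.weights:
                raise ValueError("explicit mode needs cfg.weights")
            weights = dict(cfg.weights)
            mode = "ascending"
        else:
            raise ValueError(f"unknown mode {cfg.mode!r}")
        w = WeightedLink(d, weights, mode)
    bundle["weights"] = {"mode": mode,
                         "values": {str(k): v for k, v in sorted(weights.items())}}

    with step("filtration"):
        seq = filtration_sequence(w)
    bundle["filtration"] = seq.to_json()

    coeff = _coeff(cfg)
    with step("homology"):
        stage_rows: List[dict] = []
        for a, sd in zip(seq.parameters, seq.diagrams):
            h = homology(build_complex(sd), coeff)
            for row in h.to_rows():
                row["parameter"] = a
                stage_rows.append(row)
            log.info("stage a=%-8s total rank %d (heights %s)",
                     a, h.total_rank(), h.heights())
    bundle["stage_homology"] = stage_rows

    with step("ekh"):
        try:
            bc = barcode(w, coeff)
            bundle["barcode"] = bc.to_json()
        except FiltrationError as err:
            bundle["barcode"] = None
            bundle["barcode_skipped"] = str(err)
            log.warning("barcode unavailable: %s", err)

    bundle_out = dict(bundle)
    if cfg.out_dir:
        with step("serialize"):
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "manifest.json").write_text(
                json.dumps(bundle_out, indent=2, sort_keys=True))
            import pandas as pd
            pd.DataFrame(
                [{"crossing": k, "weight": v} for k, v in sorted(weights.items())]
            ).to_csv(out / "weights.csv", index=False)
            (out / "filtration.json").write_text(
                json.dumps(bundle["filtration"], indent=2, sort_keys=True))
            pd.DataFrame(stage_rows).to_csv(out / "homology.csv", index=False)
            if bundle["barcode"] is not None:
                (out / "barcode.json").write_text(
                    json.dumps(bundle["barcode"], indent=2, sort_keys=True))
    bundle_out["timings"] = timings
    return bundle_out
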