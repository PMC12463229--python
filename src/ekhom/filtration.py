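"""Weighted links and smoothing filtrations.

A weighted link is a diagram plus a real weight per crossing.  Thresholding
the weights and applying the smoothing operator rho yields *a-indexed
links* and, sweeping the threshold through the critical weights, a
filtration of links that untangles the diagram crossing by crossing until
only disjoint circles remain.

Two weighting schemes are provided:

* distance weights — each crossing is weighted by the radius at which a
  disk grown around it (in the projection plane) first touches another
  crossing; isolated crossings get smoothed first, so these pair with
  *descending* mode;
* unzipping weights — the first-visit number of each crossing along a
  Gauss-code traversal; the link is "unzipped" from the start onward, so
  these pair with *ascending* mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .diagram import DiagramError, LinkDiagram

__all__ = [
    "WeightedLink", "FiltrationSequence", "indexed_link",
    "filtration_sequence", "distance_weights", "critical_radii",
    "unzip_weights",
]


@dataclass
class WeightedLink:
    """A diagram with a total crossing -> weight map and a threshold mode.

    ``mode="ascending"`` smooths crossings with f(x) <= a at threshold a;
    ``mode="descending"`` smooths those with f(x) >= a.
    """
    diagram: LinkDiagram
    weights: Dict[int, float]
    mode: str = "ascending"

    def __post_init__(self):
        if self.mode not in ("ascending", "descending"):
            raise DiagramError(f"unknown filtration mode {self.mode!r}")
        missing = [x for x in self.diagram.crossings if x not in self.weights]
        if missing:
            raise DiagramError(f"weights missing for crossings {missing}")
        extra = [x for x in self.weights if x not in self.diagram.crossings]
        if extra:
            raise DiagramError(f"weights given for unknown crossings {extra}")

    # -- thresholding --------------------------------------------------
    def smoothed_set(self, a: float) -> frozenset:
        if self.mode == "ascending":
            return frozenset(x for x, f in self.weights.items() if f <= a)
        return frozenset(x for x, f in self.weights.items() if f >= a)

    def critical_weights(self) -> List[float]:
        """Distinct weights, in smoothing order for the mode."""
        vals = sorted(set(self.weights.values()))
        return vals if self.mode == "ascending" else vals[::-1]

    def base_parameter(self) -> float:
        """A threshold at which nothing is smoothed yet (the original link).

        0 is used when it lies strictly on the un-smoothed side of every
        critical weight (the natural origin for weights 1, 2, 3, ...);
        otherwise one unit beyond the extremal weight.
        """
        if not self.weights:
            return 0.0
        vals = self.weights.values()
        if self.mode == "ascending":
            lo = min(vals)
            return 0.0 if lo > 0 else lo - 1.0
        hi = max(vals)
        return 0.0 if hi < 0 else hi + 1.0

    def stage_parameters(self) -> List[float]:
        return [self.base_parameter()] + self.critical_weights()


@dataclass
class FiltrationSequence:
    """The tower of a-indexed links at the critical parameters.

    ``parameters[0]`` is the base parameter (nothing smoothed); entry i
    smooths ``smoothed_sets[i]`` (cumulative) yielding ``diagrams[i]``.
    """
    parameters: List[float]
    smoothed_sets: List[frozenset]
    diagrams: List[LinkDiagram]

    def __len__(self):
        return len(self.parameters)

    def to_json(self) -> dict:
        from .diagram import emit_pd
        return {"parameters": list(self.parameters),
                "smoothed": [sorted(s) for s in self.smoothed_sets],
                "pd_codes": [emit_pd(d) for d in self.diagrams]}


def indexed_link(w: WeightedLink, a: float) -> LinkDiagram:
    """The a-indexed link: rho applied at every crossing passing the
    threshold (f(x) <= a ascending, f(x) >= a descending)."""
    return w.diagram.rho_set(w.smoothed_set(a))


def filtration_sequence(w: WeightedLink) -> FiltrationSequence:
    """One entry per distinct critical weight, plus the original link.

    Equal weights are smoothed simultaneously (smoothing is
    order-independent, so a single event is well defined).  The final
    diagram is always crossingless.
    """
    params = [w.base_parameter()]
    sets: List[frozenset] = [frozenset()]
    diagrams = [w.diagram]
    for a in w.critical_weights():
        params.append(a)
        s = w.smoothed_set(a)
        sets.append(s)
        diagrams.append(w.diagram.rho_set(s))
    return FiltrationSequence(params, sets, diagrams)


# ------------------------------------------------------------ weight makers

def distance_weights(d: LinkDiagram, convention: str = "half") -> Dict[int, float]:
    """Disk-growth weights from planar crossing coordinates.

    ``full`` assigns each crossing its nearest-neighbour distance in the
    projection plane (the largest radius with no other crossing strictly
    inside the disk); ``half`` (default) assigns half of it — the radius at
    which disks grown simultaneously around all crossings first touch,
    which is the scale on which critical distances of a filtration are
    usually quoted.  Pair with descending mode: isolated crossings (large
    weight) get smoothed first.
    """
    if convention not in ("half", "full"):
        raise DiagramError(f"unknown distance convention {convention!r}")
    ids = d.crossing_ids()
    if len(ids) < 2:
        raise DiagramError("distance weights need at least 2 crossings")
    missing = [i for i in ids if i not in d.coords]
    if missing:
        raise DiagramError(f"planar coordinates missing for crossings {missing}")
    out: Dict[int, float] = {}
    for i in ids:
        xi, yi = d.coords[i]
        best = min(math.hypot(xi - d.coords[j][0], yi - d.coords[j][1])
                   for j in ids if j != i)
        out[i] = best / 2.0 if convention == "half" else best
    return out


def critical_radii(coords: Sequence[Tuple[float, float]], count: int) -> List[float]:
    """The ``count`` smallest half pairwise distances, ascending.

    These are the radii at which disks growing around the points first
    meet pairwise.
    """
    pts = [tuple(p) for p in coords]
    if len(pts) < 2:
        raise DiagramError("need at least 2 points")
    dists = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dists.append(math.hypot(pts[i][0] - pts[j][0],
                                    pts[i][1] - pts[j][1]) / 2.0)
    if count > len(dists):
        raise DiagramError(
            f"requested {count} radii but only {len(dists)} pairs exist")
    return sorted(dists)[:count]


def unzip_weights(d: LinkDiagram, start: Optional[int] = None,
                  direction: int = 1) -> Dict[int, int]:
    """Traversal weights: the first-visit Gauss number of each crossing.

    A bijection onto {1, ..., n}; pair with ascending mode (the link is
    unzipped from the start crossing onward).
    """
    if d.n == 0:
        return {}
    return d.gauss_labels(start, direction)
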