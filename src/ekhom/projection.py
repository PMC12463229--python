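"""From 3D polyline curves (e.g. nucleic-acid backbones) to link diagrams.

A space curve is a closed polygonal curve (one or more components).  It is
projected onto a coordinate plane; every transverse intersection of two
non-adjacent segments becomes a crossing, with over/under decided by the
interpolated coordinate along the discarded axis (larger = over) and
handedness by the planar cross product of the over- and under-strand
directions.  Projections failing regularity (triple points, tangencies,
endpoint hits, equal depths) are retried after a small seeded random 3D
rotation, which preserves inter-crossing distances far better than point
perturbation would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .diagram import Crossing, DiagramError, LinkDiagram

__all__ = [
    "SpaceCurve", "ProjectionResult", "ProjectionError",
    "close_curve", "project", "read_xyz", "read_backbone",
]

PLANES = {"xy": (0, 1, 2), "xz": (0, 2, 1), "yz": (1, 2, 0)}


class ProjectionError(DiagramError):
    pass


@dataclass
class SpaceCurve:
    """An ordered 3D polyline, possibly with several components.

    ``components`` holds one (n_i, 3) array per strand; ``closed`` states
    whether the final segment back to the first point is implied.
    """
    components: List[np.ndarray]
    closed: bool = False

    def __post_init__(self):
        comps = []
        for pts in self.components:
            arr = np.asarray(pts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ProjectionError("curve points must be an (n, 3) array")
            if arr.shape[0] < 3:
                raise ProjectionError("each component needs at least 3 points")
            if np.any(np.all(np.isclose(arr[1:], arr[:-1]), axis=1)):
                raise ProjectionError("consecutive points must be distinct")
            comps.append(arr)
        self.components = comps

    @property
    def n_points(self) -> int:
        return sum(len(c) for c in self.components)

    @classmethod
    def single(cls, points, closed: bool = False) -> "SpaceCurve":
        return cls([np.asarray(points, dtype=float)], closed)


@dataclass
class ProjectionResult:
    diagram: LinkDiagram
    plane: str
    seed: int
    retries: int

    @property
    def perturbed(self) -> bool:
        return self.retries > 0


def close_curve(c: SpaceCurve) -> SpaceCurve:
    """Close the curve by joining last point to first (idempotent).

    For molecular chains this is the closure that turns an open backbone
    into a topologically meaningful loop.
    """
    if c.closed:
        return c
    comps = []
    for pts in c.components:
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ProjectionError("closing needs at least 3 distinct points")
        comps.append(pts)
    return SpaceCurve(comps, closed=True)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C]])


class _Regularity(Exception):
    pass


def _find_crossings(comps: List[np.ndarray], axes: Tuple[int, int, int],
                    scale: float):
    """All transverse intersections between non-adjacent segments.

    Returns a list of (point2d, depth/dir data per strand).  Raises
    :class:`_Regularity` on tangency, endpoint hits, equal depths or
    near-coincident crossing points.
    """
    ix, iy, iz = axes
    segs = []  # (comp, idx, p0_2d, p1_2d, z0, z1)
    for ci, pts in enumerate(comps):
        npts = len(pts)
        for i in range(npts):
            p0, p1 = pts[i], pts[(i + 1) % npts]
            segs.append((ci, i, np.array([p0[ix], p0[iy]]),
                         np.array([p1[ix], p1[iy]]), p0[iz], p1[iz]))
    eps_t = 1e-9
    eps_depth = 1e-9 * scale
    eps_sep = 1e-7 * scale
    found = []
    for a in range(len(segs)):
        ca, ia, a0, a1, za0, za1 = segs[a]
        for b in range(a + 1, len(segs)):
            cb, ib, b0, b1, zb0, zb1 = segs[b]
            if ca == cb:
                na = len(comps[ca])
                if ia == ib or (ia + 1) % na == ib or (ib + 1) % na == ia:
                    continue
            da, db = a1 - a0, b1 - b0
            det = da[0] * db[1] - da[1] * db[0]
            rhs = b0 - a0
            if abs(det) < 1e-14 * scale * scale:
                # parallel: regular unless colinear and overlapping
                cross = rhs[0] * da[1] - rhs[1] * da[0]
                if abs(cross) < eps_sep * max(np.linalg.norm(da), 1e-30):
                    ta0 = np.dot(b0 - a0, da) / np.dot(da, da)
                    ta1 = np.dot(b1 - a0, da) / np.dot(da, da)
                    if min(ta0, ta1) < 1 and max(ta0, ta1) > 0:
                        raise _Regularity("colinear overlapping segments")
                continue
            s = (rhs[0] * db[1] - rhs[1] * db[0]) / det
            t = (rhs[0] * da[1] - rhs[1] * da[0]) / det
            if s < -eps_t or s > 1 + eps_t or t < -eps_t or t > 1 + eps_t:
                continue
            if min(s, 1 - s) < 1e-6 or min(t, 1 - t) < 1e-6:
                raise _Regularity("intersection at a segment endpoint")
            za = za0 + s * (za1 - za0)
            zb = zb0 + t * (zb1 - zb0)
            if abs(za - zb) < eps_depth:
                raise _Regularity("equal depths at an intersection")
            pt = a0 + s * da
            found.append({
                "point": pt,
                "strands": [
                    {"comp": ca, "seg": ia, "t": s, "depth": za, "dir": da},
                    {"comp": cb, "seg": ib, "t": t, "depth": zb, "dir": db}],
            })
    for i in range(len(found)):
        for j in range(i + 1, len(found)):
            if np.linalg.norm(found[i]["point"] - found[j]["point"]) < eps_sep:
                raise _Regularity("near-coincident crossing points")
    return found


def _assemble(comps: List[np.ndarray], crossings_raw) -> LinkDiagram:
    """Wire the crossings found along the curve into a LinkDiagram."""
    passages: Dict[int, List[Tuple[int, float, int, int]]] = {
        ci: [] for ci in range(len(comps))}
    for xid, cr in enumerate(crossings_raw, start=1):
        for si, st in enumerate(cr["strands"]):
            passages[st["comp"]].append((st["seg"], st["t"], xid, si))

    arc = 0
    in_arc: Dict[Tuple[int, int], int] = {}   # (crossing, strand idx) -> arc
    out_arc: Dict[Tuple[int, int], int] = {}
    free_loops = 0
    for ci in range(len(comps)):
        plist = sorted(passages[ci])
        if not plist:
            free_loops += 1
            continue
        base = arc
        k = len(plist)
        for j, (_seg, _t, xid, si) in enumerate(plist):
            in_arc[(xid, si)] = base + j + 1
            out_arc[(xid, si)] = base + (j + 1) % k + 1
        arc += k

    out: List[Crossing] = []
    coords = {}
    for xid, cr in enumerate(crossings_raw, start=1):
        s0, s1 = cr["strands"]
        over_i, under_i = (0, 1) if s0["depth"] > s1["depth"] else (1, 0)
        o, u = cr["strands"][over_i]["dir"], cr["strands"][under_i]["dir"]
        sign = 1 if (o[0] * u[1] - o[1] * u[0]) > 0 else -1
        u_in, u_out = in_arc[(xid, under_i)], out_arc[(xid, under_i)]
        o_in, o_out = in_arc[(xid, over_i)], out_arc[(xid, over_i)]
        if sign > 0:
            ends = (u_in, o_out, u_out, o_in)
        else:
            ends = (u_in, o_in, u_out, o_out)
        out.append(Crossing(xid, sign, ends))
        coords[xid] = (float(cr["point"][0]), float(cr["point"][1]))
    return LinkDiagram(out, free_loops, coords)


def project(c: SpaceCurve, plane: str = "xy", seed: int = 0,
            max_retries: int = 20, base_angle: float = 1e-3) -> ProjectionResult:
    """Project a closed curve onto a coordinate plane.

    The first two axes of ``plane`` are kept; the third is the depth with
    "over" = larger value.  On a regularity failure the curve is rotated
    by a small seeded random rotation (angle doubling per retry, starting
    at ``base_angle`` radians).
    """
    if plane not in PLANES:
        raise ProjectionError(f"unknown plane {plane!r}; use xy, xz or yz")
    if not c.closed:
        raise ProjectionError("projection needs a closed curve; "
                              "use close_curve first")
    axes = PLANES[plane]
    rng = np.random.default_rng(seed)
    comps = [p.copy() for p in c.components]
    all_pts = np.vstack(comps)
    scale = float(np.linalg.norm(all_pts.max(axis=0) - all_pts.min(axis=0)))
    scale = scale if scale > 0 else 1.0
    angle = base_angle
    last_err = None
    for attempt in range(max_retries + 1):
        try:
            raw = _find_crossings(comps, axes, scale)
            diagram = _assemble(comps, raw)
            return ProjectionResult(diagram, plane, seed, attempt)
        except _Regularity as err:
            last_err = err
            axis = rng.normal(size=3)
            center = all_pts.mean(axis=0)
            R = _rotation_matrix(axis, angle)
            comps = [(p - center) @ R.T + center for p in comps]
            angle *= 2
    raise ProjectionError(
        f"no regular projection after {max_retries} retries: {last_err}")


# ------------------------------------------------------------------ readers

def read_xyz(path) -> SpaceCurve:
    """Read a coordinate table (CSV with x, y, z and optional component
    column; a headerless 3/4-column file also works)."""
    import pandas as pd
    try:
        df = pd.read_csv(path)
        cols = {c.lower().strip(): c for c in df.columns}
        if not {"x", "y", "z"} <= set(cols):
            raise ValueError
        xyz = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
        comp = (df[cols["component"]].to_numpy()
                if "component" in cols else np.zeros(len(df), dtype=int))
    except ValueError:
        df = pd.read_csv(path, header=None)
        if df.shape[1] < 3:
            raise ProjectionError(f"{path}: need at least 3 columns")
        xyz = df.iloc[:, :3].to_numpy(dtype=float)
        comp = (df.iloc[:, 3].to_numpy()
                if df.shape[1] > 3 else np.zeros(len(df), dtype=int))
    comps = []
    for key in dict.fromkeys(comp):
        comps.append(xyz[comp == key])
    return SpaceCurve(comps, closed=False)


def read_backbone(path, atom: str = "P", chain: Optional[str] = None) -> SpaceCurve:
    """Extract a backbone polyline from a PDB file.

    One point per residue, taken from the named atom (``P`` for nucleic
    acids, ``CA`` for proteins), in file (5'->3' / N->C) order; each
    selected chain becomes one component.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("backbone", str(path))
    model = next(structure.get_models())
    comps = []
    seen_chains = []
    for ch in model:
        seen_chains.append(ch.id)
        if chain is not None and ch.id != chain:
            continue
        pts = []
        for res in ch:
            for at in res:
                if at.get_name().strip() == atom:
                    pts.append(at.get_coord())
                    break
        if pts:
            comps.append(np.asarray(pts, dtype=float))
    if not comps:
        raise ProjectionError(
            f"no {atom!r} atoms found"
            + (f" in chain {chain!r} (chains present: {seen_chains})"
               if chain is not None else ""))
    return SpaceCurve(comps, closed=False)
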