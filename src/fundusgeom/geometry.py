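"""Vessel geometry: centerlines, diameters, annulus calibers, AVR, angles.

The measurement chain mirrors standard fundus morphometry practice:

1. the binary vessel mask is thinned to a one-pixel, topology-preserving
   skeleton and converted to a graph of junction/endpoint nodes joined by
   ordered pixel chains (short spurs pruned);
2. at each centerline point the local diameter is the length of the chord
   orthogonal to the centerline tangent, with sub-pixel boundary crossings
   found by bilinear interpolation of the mask;
3. calibers are summarized inside the annulus 1.0-1.5 optic-disc diameters
   (DD) from the disc center: each vessel's retained run is split into at
   least ten equal-arc sections, section means are pooled per A/V class,
   and relative calibers are class means divided by DD, so
   AVR = relative arteriolar / relative venular caliber by construction;
4. branching angles are the first angle subtended between the two daughter
   vessels at each degree-3 bifurcation (degree >= 4 crossings excluded),
   assigned to superior/inferior x nasal/temporal quadrants relative to the
   disc center with laterality-aware nasal/temporal orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "CenterlineGraph",
    "DiameterProfile",
    "CaliberSummary",
    "BifurcationAngle",
    "extract_centerline",
    "measure_diameters",
    "annulus_calibers",
    "detect_bifurcations",
    "branching_angle",
    "bifurcation_angles",
    "assign_quadrant",
    "quadrant_angle_means",
    "label_edges",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CenterlineGraph:
    """Skeleton topology: nodes are junctions/endpoints, edges pixel chains.

    ``graph`` is a :class:`networkx.MultiGraph`; node attributes carry the
    representative pixel ``pos`` (row, col); edge attributes carry ``chain``,
    an ``(n, 2)`` array of 8-connected (row, col) skeleton pixels ordered
    from the ``u`` node to the ``v`` node, and optionally ``label``.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_degree(self, degree: int) -> list[int]:
        return [n for n in self.graph.nodes if self.graph.degree(n) == degree]

    def edges(self):
        return self.graph.edges(keys=True, data=True)

    def trees(self) -> list[set[int]]:
        """Connected components (each a vascular tree or crossing complex)."""
        return [set(c) for c in nx.connected_components(self.graph)]


def _chain_length(chain: np.ndarray) -> float:
    if len(chain) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(chain.astype(float), axis=0).T)))


def _build_graph(skel: np.ndarray) -> nx.MultiGraph:
    """Trace a skeleton into a node/chain multigraph.

    Node sites are skeleton pixels whose 8-neighborhood count differs
    from 2 (endpoints, junctions, isolated pixels); adjacent node pixels
    are merged into one node. Pure cycles without any node pixel get a
    single anchor node with a self-loop chain.
    """
    g = nx.MultiGraph()
    if not skel.any():
        return g
    nbr_count = ndimage.convolve(skel.astype(np.uint8), np.array(
        [[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant")
    node_px = skel & (nbr_count != 2)
    node_lbl, n_nodes = ndimage.label(node_px, structure=np.ones((3, 3), int))
    for nid in range(1, n_nodes + 1):
        rr, cc = np.nonzero(node_lbl == nid)
        g.add_node(nid, pos=(float(rr.mean()), float(cc.mean())),
                   pixels=set(zip(rr.tolist(), cc.tolist())))

    px_node: dict[tuple[int, int], int] = {}
    for nid, data in g.nodes(data=True):
        for p in data["pixels"]:
            px_node[p] = nid

    visited = np.zeros_like(skel, dtype=bool)

    def walk(first: tuple[int, int], origin: tuple[int, int]):
        """Follow degree-2 pixels from ``first`` until hitting a node pixel."""
        chain = [origin, first]
        prev, cur = origin, first
        if first in px_node:
            return chain, px_node[first]
        visited[first] = True
        while True:
            nxt = None
            for dr, dc in _NEIGHBORS:
                q = (cur[0] + dr, cur[1] + dc)
                if q == prev:
                    continue
                if 0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1] and skel[q]:
                    if q in px_node or not visited[q]:
                        nxt = q
                        break
            if nxt is None:
                return chain, None  # dead end (degenerate skeletons)
            chain.append(nxt)
            prev, cur = cur, nxt
            if cur in px_node:
                return chain, px_node[cur]
            visited[cur] = True

    for nid, data in list(g.nodes(data=True)):
        for (r, c) in sorted(data["pixels"]):
            for dr, dc in _NEIGHBORS:
                q = (r + dr, c + dc)
                if not (0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]):
                    continue
                if not skel[q] or q in px_node or visited[q]:
                    continue
                chain, end_node = walk(q, (r, c))
                if end_node is None:
                    end_node = nid  # fold rare dead ends back on the start
                g.add_edge(nid, end_node, chain=np.array(chain, dtype=float))
    # direct node-to-node adjacencies with no intermediate chain pixel
    for nid, data in list(g.nodes(data=True)):
        for (r, c) in data["pixels"]:
            for dr, dc in _NEIGHBORS:
                q = (r + dr, c + dc)
                other = px_node.get(q)
                if other is not None and other > nid and not g.has_edge(nid, other):
                    g.add_edge(nid, other, chain=np.array([(r, c), q], dtype=float))
    # pure cycles: remaining untraced degree-2 pixels
    remaining = skel & ~visited & (node_lbl == 0)
    while remaining.any():
        r, c = map(int, np.argwhere(remaining)[0])
        nid = g.number_of_nodes() + 1
        g.add_node(nid, pos=(float(r), float(c)), pixels={(r, c)})
        px_node[(r, c)] = nid
        chain = [(r, c)]
        prev, cur = None, (r, c)
        remaining[(r, c)] = False
        while True:
            nxt = None
            for dr, dc in _NEIGHBORS:
                q = (cur[0] + dr, cur[1] + dc)
                if q == prev or not (0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]):
                    continue
                if remaining[q]:
                    nxt = q
                    break
            if nxt is None:
                break
            chain.append(nxt)
            remaining[nxt] = False
            visited[nxt] = True
            prev, cur = cur, nxt
        if len(chain) > 1:
            chain.append((r, c))
            g.add_edge(nid, nid, chain=np.array(chain, dtype=float))
    return g


def _ends_at(chain: np.ndarray, pos: tuple[float, float]) -> bool:
    p = np.asarray(pos)
    return np.hypot(*(chain[-1] - p)) <= np.hypot(*(chain[0] - p))


def _merge_degree2(g: nx.MultiGraph) -> None:
    """Fuse pass-through nodes, concatenating their two chains."""
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) != 2 or g.number_of_edges(n, n) > 0:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:
                continue
            (u1, v1, _k1, d1), (u2, v2, _k2, d2) = inc
            a = u1 if v1 == n else v1
            b = u2 if v2 == n else v2
            pos = g.nodes[n]["pos"]
            c1 = d1["chain"] if _ends_at(d1["chain"], pos) else d1["chain"][::-1]
            c2 = d2["chain"] if not _ends_at(d2["chain"], pos) else d2["chain"][::-1]
            merged = np.vstack([c1, c2[1:]])
            g.remove_node(n)
            g.add_edge(a, b, chain=merged)
            changed = True
            break


def extract_centerline(vessel_mask: np.ndarray, spur_len: float = 5.0) -> CenterlineGraph:
    """Thin a binary vessel mask to its centerline graph.

    Topology-preserving thinning (a pure morphological erosion would
    disconnect the skeleton), then spur pruning: terminal chains shorter
    than ``spur_len`` pixels hanging off a junction are removed, and any
    junction thereby reduced to a pass-through node is fused, so thinning
    artifacts at vessel tips and junctions do not masquerade as
    bifurcations.  An empty mask yields an empty graph.
    """
    mask = np.asarray(vessel_mask).astype(bool)
    if not mask.any():
        return CenterlineGraph()
    skel = skeletonize(mask)
    g = _build_graph(skel)
    while True:
        # skeleton bubbles: tiny self-loops and short parallel duplicate
        # edges at junctions are thinning artifacts, not vascular loops
        bubbles = []
        seen_pairs: dict[tuple, list] = {}
        for u, v, k, d in g.edges(keys=True, data=True):
            ln = _chain_length(d["chain"])
            if u == v and ln < max(3.0 * spur_len, 8.0):
                bubbles.append((u, v, k))
            elif u != v:
                seen_pairs.setdefault(tuple(sorted((u, v))), []).append((u, v, k, ln))
        for pair, edges_ in seen_pairs.items():
            if len(edges_) > 1:
                edges_.sort(key=lambda e: e[3])
                for u, v, k, ln in edges_[:-1]:
                    if ln < max(3.0 * spur_len, 8.0):
                        bubbles.append((u, v, k))
        if bubbles:
            for u, v, k in bubbles:
                if g.has_edge(u, v, k):
                    g.remove_edge(u, v, k)
            _merge_degree2(g)
        spurs = []
        for u, v, k, d in g.edges(keys=True, data=True):
            if u == v:
                continue
            du, dv = g.degree(u), g.degree(v)
            # keep isolated short segments (both ends free): real tiny
            # vessels, not thinning artifacts
            if (du == 1) != (dv == 1) and _chain_length(d["chain"]) < spur_len:
                spurs.append((u, v, k))
        if not spurs:
            break
        for u, v, k in spurs:
            if g.has_edge(u, v, k):
                g.remove_edge(u, v, k)
        for n in [n for n in list(g.nodes) if g.degree(n) == 0]:
            g.remove_node(n)
        _merge_degree2(g)
    _merge_degree2(g)
    return CenterlineGraph(graph=g)


def label_edges(clg: CenterlineGraph, av_mask: np.ndarray) -> None:
    """Attach an A/V label to each edge by majority vote along its chain."""
    for _u, _v, _k, d in clg.edges():
        rr, cc = np.round(d["chain"]).astype(int).T
        rr = np.clip(rr, 0, av_mask.shape[0] - 1)
        cc = np.clip(cc, 0, av_mask.shape[1] - 1)
        vals = av_mask[rr, cc]
        vals = vals[vals > 0]
        if len(vals) == 0:
            d["label"] = "unlabeled"
        else:
            d["label"] = "artery" if (vals == 1).sum() >= (vals == 2).sum() else "vein"


# --------------------------------------------------------------------------
# diameters
# --------------------------------------------------------------------------


@dataclass
class DiameterProfile:
    """Per-centerline-point diameters.

    ``df`` columns: ``x, y`` (pixel position), ``tx, ty`` (unit tangent),
    ``s`` (arc length along the parent chain), ``diameter_px``, ``label``,
    ``edge_id``.  ``n_skipped`` counts points whose orthogonal chord failed
    to cross the vessel boundary (e.g. at the mask border).
    """

    df: pd.DataFrame
    n_skipped: int = 0


def _chord_halfwidths(mask_f: np.ndarray, pts: np.ndarray, normals: np.ndarray,
                      max_radius: float, step: float) -> np.ndarray:
    """Sub-pixel half-chord lengths on both sides of each point.

    Samples the (0/1) mask bilinearly along the +-normal rays and linearly
    interpolates the 0.5 crossing. Returns (n, 2); NaN where no crossing.
    """
    ts = np.arange(0.0, max_radius + step, step)
    out = np.full((len(pts), 2), np.nan)
    for side, sign in enumerate((1.0, -1.0)):
        rows = pts[:, 0][:, None] + sign * ts[None, :] * normals[:, 0][:, None]
        cols = pts[:, 1][:, None] + sign * ts[None, :] * normals[:, 1][:, None]
        vals = ndimage.map_coordinates(mask_f, [rows, cols], order=1, mode="constant")
        below = vals < 0.5
        below[:, 0] = False  # the point itself must be inside
        first = np.argmax(below, axis=1)
        has = below.any(axis=1) & (vals[:, 0] >= 0.5)
        idx = np.nonzero(has)[0]
        f = first[idx]
        v0 = vals[idx, f - 1]
        v1 = vals[idx, f]
        frac = (v0 - 0.5) / np.maximum(v0 - v1, 1e-12)
        out[idx, side] = ts[f - 1] + frac * step
    return out


def measure_diameters(
    vessel_mask: np.ndarray,
    clg: CenterlineGraph,
    end_exclude_px: float = 3.0,
    junction_exclude_px: float = 2.0,
    tangent_halfspan: int = 3,
    max_radius: float = 40.0,
    step: float = 0.25,
) -> DiameterProfile:
    """Measure local vessel diameters along every centerline chain.

    The tangent at a chain pixel comes from centered finite differences
    over ``+-tangent_halfspan`` chain pixels; the diameter is the length
    of the orthogonal chord through the point between the two sub-pixel
    boundary crossings of the mask.  Points within
    ``junction_exclude_px`` of a junction node, and within
    ``end_exclude_px`` of either chain end, are excluded (junction blobs
    and rounded tips bias the chord); failed chords are tallied in
    ``n_skipped``.
    """
    mask_f = np.asarray(vessel_mask).astype(np.float64)
    rows = []
    n_skipped = 0
    for eid, (u, v, _k, d) in enumerate(clg.edges()):
        chain = d["chain"]
        n = len(chain)
        if n < 2 * tangent_halfspan + 1:
            continue
        steps = np.hypot(*np.diff(chain, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(steps)])
        total = s[-1]
        h = tangent_halfspan
        idx = np.arange(h, n - h)
        lo = end_exclude_px + (junction_exclude_px if clg.graph.degree(u) >= 3 else 0.0)
        hi = end_exclude_px + (junction_exclude_px if clg.graph.degree(v) >= 3 else 0.0)
        idx = idx[(s[idx] >= lo) & (total - s[idx] >= hi)]
        if len(idx) == 0:
            continue
        tang = chain[idx + h] - chain[idx - h]
        norms = np.hypot(tang[:, 0], tang[:, 1])
        good = norms > 0
        idx, tang = idx[good], tang[good] / norms[good, None]
        normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        pts = chain[idx]
        half = _chord_halfwidths(mask_f, pts, normal, max_radius, step)
        dia = half.sum(axis=1)
        ok = np.isfinite(dia)
        n_skipped += int((~ok).sum())
        lab = d.get("label", "unlabeled")
        for i in np.nonzero(ok)[0]:
            rows.append((pts[i, 1], pts[i, 0], tang[i, 1], tang[i, 0],
                         s[idx[i]], dia[i], lab, eid))
    df = pd.DataFrame(rows, columns=["x", "y", "tx", "ty", "s",
                                     "diameter_px", "label", "edge_id"])
    return DiameterProfile(df=df, n_skipped=n_skipped)


# --------------------------------------------------------------------------
# annulus calibers / AVR
# --------------------------------------------------------------------------


@dataclass
class CaliberSummary:
    """Eye-level caliber summary in the measurement annulus.

    Relative calibers are mean diameters divided by the optic-disc
    diameter DD; ``avr`` is mean arteriolar / mean venular diameter, which
    equals ``rel_arteriolar / rel_venular`` identically.  ``complete`` is
    False (and ``avr`` None) when either vessel class has no points in the
    annulus.
    """

    mean_arteriolar_px: float | None
    mean_venular_px: float | None
    n_sections_arteriolar: int
    n_sections_venular: int
    rel_arteriolar: float | None
    rel_venular: float | None
    avr: float | None
    dd_px: float
    complete: bool


def _section_means(sub: pd.DataFrame, min_sections: int) -> list[float]:
    """Split one vessel's retained run into equal-arc sections; mean each."""
    s = sub["s"].to_numpy()
    dia = sub["diameter_px"].to_numpy()
    lo, hi = s.min(), s.max()
    if hi <= lo:
        return [float(dia.mean())]
    edges = np.linspace(lo, hi, min_sections + 1)
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, min_sections - 1)
    return [float(dia[which == b].mean()) for b in range(min_sections) if (which == b).any()]


def annulus_calibers(
    profile: DiameterProfile,
    disc,
    zone: tuple[float, float] = (1.0, 1.5),
    zone_from_margin: bool = False,
    min_sections: int = 10,
) -> CaliberSummary:
    """Average A/V diameters in the 1.0-1.5 DD annulus around the disc.

    ``disc`` needs ``center`` (x, y) and ``dd`` (diameter, px) attributes.
    Points are kept when their distance from the disc center lies in
    ``[zone[0]*DD, zone[1]*DD]`` (or, with ``zone_from_margin``, the same
    window measured outward from the disc margin at DD/2).  Each vessel's
    retained run is split into ``min_sections`` equal-arc sections whose
    means are pooled per A/V class with equal weight; relative calibers
    are class means over DD and AVR their ratio.
    """
    dd = float(disc.dd)
    cx, cy = disc.center
    df = profile.df
    if len(df) == 0:
        return CaliberSummary(None, None, 0, 0, None, None, None, dd, False)
    dist = np.hypot(df["x"] - cx, df["y"] - cy)
    lo, hi = zone
    if zone_from_margin:
        lo, hi = dd / 2.0 + lo * dd, dd / 2.0 + hi * dd
    else:
        lo, hi = lo * dd, hi * dd
    kept = df[(dist >= lo) & (dist <= hi)]
    sections: dict[str, list[float]] = {"artery": [], "vein": []}
    for (_eid, lab), sub in kept.groupby(["edge_id", "label"]):
        if lab in sections:
            sections[lab].extend(_section_means(sub, min_sections))
    mean_a = float(np.mean(sections["artery"])) if sections["artery"] else None
    mean_v = float(np.mean(sections["vein"])) if sections["vein"] else None
    complete = mean_a is not None and mean_v is not None
    rel_a = mean_a / dd if mean_a is not None else None
    rel_v = mean_v / dd if mean_v is not None else None
    return CaliberSummary(
        mean_arteriolar_px=mean_a,
        mean_venular_px=mean_v,
        n_sections_arteriolar=len(sections["artery"]),
        n_sections_venular=len(sections["vein"]),
        rel_arteriolar=rel_a,
        rel_venular=rel_v,
        avr=(rel_a / rel_v) if complete else None,
        dd_px=dd,
        complete=complete,
    )


# --------------------------------------------------------------------------
# bifurcations and branching angles
# --------------------------------------------------------------------------


@dataclass
class BifurcationAngle:
    position: tuple[float, float]  # (x, y)
    angle_deg: float
    label: str
    quadrant: str | None = None
    laterality: str | None = None
    short_daughter: bool = False


def detect_bifurcations(clg: CenterlineGraph) -> tuple[list[int], list[int]]:
    """Split graph nodes into bifurcations (degree 3) and crossings (>= 4).

    Arteriovenous crossings thin to degree-4 (or higher) nodes and are
    excluded from angle analysis; they are returned separately for tally.
    """
    bif = [n for n in clg.graph.nodes if clg.graph.degree(n) == 3]
    crossings = [n for n in clg.graph.nodes if clg.graph.degree(n) >= 4]
    return bif, crossings


def _edge_direction(clg: CenterlineGraph, node: int, d: dict,
                    probe_len: float, probe_skip: float = 4.0) -> tuple[np.ndarray, bool]:
    """Least-squares direction of a chain over its first ``probe_len``
    pixels walking away from ``node``, oriented away from the node.

    The first ``probe_skip`` pixels are excluded: inside the junction blob
    the skeleton bends toward the bisector and would bias the fit.
    """
    chain = d["chain"]
    pos = np.asarray(clg.graph.nodes[node]["pos"])
    if np.hypot(*(chain[0] - pos)) > np.hypot(*(chain[-1] - pos)):
        chain = chain[::-1]
    steps = np.hypot(*np.diff(chain, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    short = s[-1] < probe_skip + probe_len
    sub = chain if short else chain[(s >= probe_skip) & (s <= probe_skip + probe_len)]
    if len(sub) < 2:
        sub = chain[-2:] if short else chain[:2]
    centered = sub - sub.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, sub[-1] - sub[0]) < 0:
        direction = -direction
    return direction, short


def _edge_ids(clg: CenterlineGraph) -> dict:
    return {(u, v, k): i for i, (u, v, k, _d) in enumerate(clg.edges())}


def branching_angle(clg: CenterlineGraph, node: int,
                    profile: DiameterProfile | None = None,
                    probe_len: float = 16.0) -> tuple[float, bool]:
    """First angle between the two daughter vessels at a degree-3 node.

    The parent branch is the incident edge with the largest mean measured
    diameter (tie-break: longer chain); without a profile, the longest
    chain stands in for the widest.  Daughter directions are
    least-squares line fits over the first ``probe_len`` chain pixels
    from the node apex ("first" angle = at the bifurcation).  Returns
    ``(angle_deg, any_daughter_shorter_than_probe)``.
    """
    inc = list(clg.graph.edges(node, keys=True, data=True))
    if len(inc) != 3:
        raise ValueError(f"node {node} has degree {len(inc)}, expected 3")
    eids = _edge_ids(clg) if profile is not None and len(profile.df) else None

    def rank(e):
        u, v, k, d = e
        mean_dia = -1.0
        if eids is not None:
            eid = eids.get((u, v, k), eids.get((v, u, k)))
            sub = profile.df[profile.df["edge_id"] == eid]
            if len(sub):
                mean_dia = float(sub["diameter_px"].mean())
        return (mean_dia, _chain_length(d["chain"]))

    parent = max(inc, key=rank)
    daughters = [e for e in inc if e is not parent]
    d1, s1 = _edge_direction(clg, node, daughters[0][3], probe_len)
    d2, s2 = _edge_direction(clg, node, daughters[1][3], probe_len)
    cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    ang = math.degrees(math.acos(cosang))
    ang = min(max(ang, 1e-9), 180.0 - 1e-9)
    return ang, (s1 or s2)


def assign_quadrant(position: tuple[float, float], disc, laterality: str) -> str:
    """Quadrant of a retinal location relative to the disc center.

    Image-up is superior.  For a right eye (OD) the nasal retina is
    toward image-right; for a left eye (OS) the mapping mirrors.  Exact
    vertical/horizontal ties resolve to superior/nasal; the disc center
    itself has no quadrant and raises.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    cx, cy = disc.center
    dx = position[0] - cx
    dy = position[1] - cy
    if dx == 0 and dy == 0:
        raise ValueError("undefined quadrant: position coincides with disc center")
    vert = "superior" if dy <= 0 else "inferior"
    nasal_right = laterality == "OD"
    horiz_nasal = (dx >= 0) if nasal_right else (dx <= 0)
    horiz = "nasal" if horiz_nasal else "temporal"
    return f"{vert} {horiz}"


def bifurcation_angles(
    clg: CenterlineGraph,
    disc=None,
    laterality: str | None = None,
    profile: DiameterProfile | None = None,
    probe_len: float = 16.0,
) -> list[BifurcationAngle]:
    """Measure all bifurcation angles, optionally quadrant-stratified."""
    bif_nodes, _ = detect_bifurcations(clg)
    out = []
    for n in bif_nodes:
        ang, short = branching_angle(clg, n, profile=profile, probe_len=probe_len)
        pos_rc = clg.graph.nodes[n]["pos"]
        pos_xy = (pos_rc[1], pos_rc[0])
        labels = [d.get("label", "unlabeled")
                  for _u, _v, _k, d in clg.graph.edges(n, keys=True, data=True)]
        label = max(set(labels), key=labels.count)
        quad = None
        if disc is not None and laterality is not None:
            quad = assign_quadrant(pos_xy, disc, laterality)
        out.append(BifurcationAngle(position=pos_xy, angle_deg=ang, label=label,
                                    quadrant=quad, laterality=laterality,
                                    short_daughter=short))
    return out


def quadrant_angle_means(angles: list[BifurcationAngle]) -> dict[str, float]:
    """Eye-level mean branching angle per quadrant x vessel class.

    Keys look like ``"superior nasal artery"``; values in degrees.
    """
    groups: dict[str, list[float]] = {}
    for a in angles:
        if a.quadrant is None or a.label not in ("artery", "vein"):
            continue
        groups.setdefault(f"{a.quadrant} {a.label}", []).append(a.angle_deg)
    return {k: float(np.mean(v)) for k, v in groups.items()}
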