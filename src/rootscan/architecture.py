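"""Root-system architecture: skeleton graph, primary/lateral roots, local traits.

Builds a topological skeleton graph from a cleaned binary mask, identifies
the primary root (the gravitropically dominant axis from the seed point),
hangs first-order laterals off it, and measures SmartRoot-style local traits:
lengths, diameters (from the Euclidean distance transform), branching
density, and insertion angles. Second-order laterals are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .imaging import CM_PER_INCH, BinaryMask

MM_PER_INCH = 25.4

#: skeleton spurs shorter than this (px) are thinning artefacts, not laterals
DEFAULT_PRUNE_PX = 10

#: laterals shorter than this (cm) are discarded as unresolvable
DEFAULT_MIN_LATERAL_CM = 0.05


@dataclass
class RootGraph:
    """Skeleton graph: nodes are junctions/tips, edges are centerline polylines.

    ``graph`` is an undirected networkx graph whose nodes are (row, col)
    skeleton pixels of degree != 2 and whose edges carry:

    - ``points``: ordered (row, col) polyline including both endpoints
    - ``radii``: per-point Euclidean distance-transform value (px)
    - ``length_px``: polyline length in px steps
    """

    graph: nx.Graph
    dpi: float

    @property
    def cm_per_px(self) -> float:
        return CM_PER_INCH / self.dpi


@dataclass
class LateralRoot:
    points: np.ndarray  # (n, 2) row/col polyline from the junction outward
    length_cm: float
    diameter_mm: float
    insertion_angle_deg: float
    position_cm: float  # arc-length position of the junction along the primary
    emergence_das: float | None = None


@dataclass
class RootSystem:
    """A single plant: one primary root and its first-order laterals."""

    primary_points: np.ndarray  # (n, 2) row/col polyline, seed end first
    primary_length_cm: float
    primary_diameter_mm: float
    laterals: list[LateralRoot] = field(default_factory=list)
    dpi: float = 300.0
    plant_id: str = "plant"

    @property
    def branching_density(self) -> float:
        return len(self.laterals) / self.primary_length_cm


@dataclass(frozen=True)
class LocalTraits:
    primary_root_length: float  # cm
    primary_root_diameter: float  # mm
    lateral_branching_density: float  # cm^-1
    mean_lateral_length: float | None  # cm; None when there are no laterals
    mean_lateral_diameter: float | None  # mm
    mean_insertion_angle: float | None  # degrees
    total_lateral_length: float  # cm
    total_root_length: float  # cm


def _polyline_length_px(points: np.ndarray) -> float:
    d = np.diff(points.astype(float), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _neighbors(p: tuple[int, int], pix: set) -> list[tuple[int, int]]:
    r, c = p
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            q = (r + dr, c + dc)
            if q in pix:
                out.append(q)
    return out


def skeleton_graph(
    mask: BinaryMask,
    prune_px: float = DEFAULT_PRUNE_PX,
) -> RootGraph:
    """Thin the mask and partition the skeleton into a junction/tip graph.

    Skeleton pixels of degree != 2 become nodes; maximal degree-2 chains
    become edges with per-point radii taken from the Euclidean distance
    transform of the mask. Tip-ended spurs shorter than ``prune_px`` are
    removed (thinning artefacts at the margins of thick roots), after which
    pass-through nodes of degree 2 are merged away.
    """
    if not mask.pixels.any():
        raise ValueError("cannot build a skeleton graph from an empty mask")
    skel = skeletonize(mask.pixels)
    dist = ndimage.distance_transform_edt(mask.pixels)
    pix = set(zip(*np.nonzero(skel)))
    if not pix:
        raise ValueError("skeletonization produced no pixels")

    degree = {p: len(_neighbors(p, pix)) for p in pix}
    nodes = {p for p, d in degree.items() if d != 2}
    if not nodes:  # pure cycle; break it at an arbitrary pixel
        nodes = {next(iter(pix))}

    g = nx.Graph()
    for p in nodes:
        g.add_node(p)
    visited_from: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for start in nodes:
        for nb in _neighbors(start, pix):
            if (start, nb) in visited_from:
                continue
            path = [start, nb]
            prev, cur = start, nb
            while cur not in nodes:
                nxt = [q for q in _neighbors(cur, pix) if q != prev]
                if not nxt:
                    break  # dangling end (shouldn't happen: degree-1 pixels are nodes)
                prev, cur = cur, nxt[0]
                path.append(cur)
            end = path[-1]
            visited_from.add((start, nb))
            visited_from.add((end, path[-2]))
            pts = np.array(path)
            length = _polyline_length_px(pts)
            if g.has_edge(start, end) and g[start][end]["length_px"] <= length:
                continue  # keep the shorter of parallel edges
            g.add_edge(start, end, points=pts, radii=dist[pts[:, 0], pts[:, 1]], length_px=length)

    g = _contract_junction_clusters(g)
    _prune_spurs(g, prune_px)
    _merge_degree2(g)
    return RootGraph(g, mask.dpi)


def _contract_junction_clusters(g: nx.Graph) -> nx.Graph:
    """Merge 8-adjacent junction pixels into single junction nodes.

    Thinning a thick branch point leaves a small cluster of degree >= 3
    pixels rather than one; each cluster is contracted to its topmost
    (row-major minimum) pixel so one biological junction is one node.
    """
    junctions = {n for n in g.nodes if g.degree(n) >= 3}
    cluster_graph = nx.Graph()
    cluster_graph.add_nodes_from(junctions)
    for u in junctions:
        r, c = u
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                v = (r + dr, c + dc)
                if v != u and v in junctions:
                    cluster_graph.add_edge(u, v)
    rep = {}
    for comp in nx.connected_components(cluster_graph):
        root = min(comp)
        for n in comp:
            rep[n] = root

    out = nx.Graph()
    for n in g.nodes:
        out.add_node(rep.get(n, n))
    for u, v, data in g.edges(data=True):
        nu, nv = rep.get(u, u), rep.get(v, v)
        if nu == nv:
            continue
        pts, radii = _oriented(data, u)
        if nu != u:
            pts = np.vstack([np.array(nu), pts])
            radii = np.concatenate([[radii[0]], radii])
        if nv != v:
            pts = np.vstack([pts, np.array(nv)])
            radii = np.concatenate([radii, [radii[-1]]])
        length = _polyline_length_px(pts)
        if out.has_edge(nu, nv) and out[nu][nv]["length_px"] <= length:
            continue
        out.add_edge(nu, nv, points=pts, radii=radii, length_px=length)
    return out


def _prune_spurs(g: nx.Graph, prune_px: float) -> None:
    # the topmost tip is the seed end of the primary (where the seedling was
    # placed); a short stub there is real root, not a thinning artefact
    protected = min(g.nodes) if g.number_of_nodes() else None
    changed = True
    while changed:
        changed = False
        for u in list(g.nodes):
            if g.degree(u) != 1 or u == protected:
                continue
            (v,) = g.neighbors(u)
            if g.degree(v) > 1 and g[u][v]["length_px"] < prune_px:
                g.remove_node(u)
                changed = True


def _merge_degree2(g: nx.Graph) -> None:
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.degree(v) != 2:
                continue
            u, w = g.neighbors(v)
            if u == w:
                continue
            e1, e2 = g[u][v], g[v][w]
            p1 = e1["points"] if tuple(e1["points"][-1]) == v else e1["points"][::-1]
            r1 = e1["radii"] if tuple(e1["points"][-1]) == v else e1["radii"][::-1]
            p2 = e2["points"] if tuple(e2["points"][0]) == v else e2["points"][::-1]
            r2 = e2["radii"] if tuple(e2["points"][0]) == v else e2["radii"][::-1]
            pts = np.vstack([p1, p2[1:]])
            radii = np.concatenate([r1, r2[1:]])
            g.remove_node(v)
            g.add_edge(u, w, points=pts, radii=radii, length_px=_polyline_length_px(pts))
            changed = True


def _oriented(edge: dict, start: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    pts, radii = edge["points"], edge["radii"]
    if tuple(pts[0]) == start:
        return pts, radii
    return pts[::-1], radii[::-1]


def identify_primary(root_graph: RootGraph, seed: tuple[int, int] | None = None,
                     horizontal_penalty: float = 0.2) -> np.ndarray:
    """Trace the primary root from the seed point to its tip.

    The primary is the path from the node nearest the seed (default: the
    topmost node, where the seedling was placed) to the tip maximizing
    path length minus ``horizontal_penalty`` x cumulative horizontal
    deviation — a gravitropic prior that prefers the long, downward axis
    over long but sideways laterals. Deterministic: ties break on node order.
    """
    g = root_graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; clean the mask first")
    nodes = list(g.nodes)
    if seed is None:
        start = min(nodes)  # topmost, then leftmost (row-major order)
    else:
        seed_arr = np.asarray(seed, dtype=float)
        d = [np.hypot(*(np.asarray(n) - seed_arr)) for n in nodes]
        start = nodes[int(np.argmin(d))]
    tips = [n for n in nodes if g.degree(n) == 1 and n != start]
    if not tips:
        tips = [n for n in nodes if n != start] or [start]

    best_score, best_path = -np.inf, [start]
    for tip in sorted(tips):
        path = nx.shortest_path(g, start, tip, weight="length_px")
        length = 0.0
        horiz = 0.0
        for a, b in zip(path[:-1], path[1:]):
            pts, _ = _oriented(g[a][b], a)
            length += g[a][b]["length_px"]
            horiz += float(np.abs(np.diff(pts[:, 1].astype(float))).sum())
        score = length - horizontal_penalty * horiz
        if score > best_score:
            best_score, best_path = score, path

    segs = []
    for a, b in zip(best_path[:-1], best_path[1:]):
        pts, _ = _oriented(g[a][b], a)
        segs.append(pts if not segs else pts[1:])
    return np.vstack(segs) if segs else np.array([start])


def extract_laterals(
    root_graph: RootGraph,
    primary: np.ndarray,
    min_lateral_cm: float = DEFAULT_MIN_LATERAL_CM,
) -> list[np.ndarray]:
    """First-order laterals: one longest path into each subtree off the primary.

    Every junction node interior to the primary spawns one lateral per
    non-primary branch: the longest (px length) path from the junction into
    that subtree. Laterals shorter than ``min_lateral_cm`` are discarded.
    Returned in order of emergence position along the primary.
    """
    g = root_graph.graph
    primary_set = {tuple(p) for p in primary}
    cum = _cumulative_arclength(primary)
    primary_nodes = sorted(
        (n for n in g.nodes if n in primary_set),
        key=lambda n: _position_along(primary, cum, n),
    )

    laterals: list[tuple[float, np.ndarray]] = []
    claimed: set[frozenset] = set()  # edges already owned by an earlier lateral
    for junction in primary_nodes:
        for nb in sorted(g.neighbors(junction)):
            if frozenset((junction, nb)) in claimed:
                continue
            first_pts, _ = _oriented(g[junction][nb], junction)
            # skip branches that are part of the primary itself
            if _on_primary(first_pts, primary_set):
                continue
            pts, used = _longest_path_from(g, junction, nb, primary_set, claimed)
            claimed |= used
            length_cm = _polyline_length_px(pts) * root_graph.cm_per_px
            if length_cm < min_lateral_cm:
                continue
            pos = _position_along(primary, cum, junction) * root_graph.cm_per_px
            laterals.append((pos, pts))
    laterals.sort(key=lambda t: (t[0], len(t[1])))
    return [pts for _, pts in laterals]


def _on_primary(edge_points: np.ndarray, primary_set: set) -> bool:
    mid = edge_points[len(edge_points) // 2]
    return tuple(mid) in primary_set and tuple(edge_points[min(1, len(edge_points) - 1)]) in primary_set


def _longest_path_from(
    g: nx.Graph, junction, first, primary_set, claimed: set | None = None
) -> tuple[np.ndarray, set]:
    """Path from ``junction`` along edge (junction, first) to the farthest
    reachable tip, staying off the primary and off edges already claimed by
    other laterals. On a tree this is exactly the longest path into the
    subtree; where crossing roots create cycles it is the shortest route to
    the farthest node, which keeps extraction polynomial. Returns the
    polyline and the set of edges used."""
    claimed = claimed or set()

    def usable(u, v):
        return frozenset((u, v)) not in claimed and v not in primary_set

    # restrict to the branch entered through (junction, first)
    sub = nx.Graph()
    sub.add_node(first)
    queue = [first]
    seen = {junction, first}
    while queue:
        node = queue.pop()
        for nb in g.neighbors(node):
            if not usable(node, nb):
                continue
            sub.add_edge(node, nb, length_px=g[node][nb]["length_px"])
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    dist, paths = nx.single_source_dijkstra(sub, first, weight="length_px")
    far = max(sorted(dist), key=lambda n: dist[n])
    node_path = [junction] + paths[far]
    segs, edges = [], set()
    for a, b in zip(node_path[:-1], node_path[1:]):
        pts, _ = _oriented(g[a][b], a)
        segs.append(pts if not segs else pts[1:])
        edges.add(frozenset((a, b)))
    return np.vstack(segs), edges


def _cumulative_arclength(points: np.ndarray) -> np.ndarray:
    d = np.diff(points.astype(float), axis=0)
    return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])


def _position_along(primary: np.ndarray, cum: np.ndarray, point) -> float:
    d = np.hypot(primary[:, 0] - point[0], primary[:, 1] - point[1])
    return float(cum[int(np.argmin(d))])


def local_diameter(radii: np.ndarray, dpi: float, trim_frac: float = 0.15) -> float:
    """Root diameter in mm from the median distance-transform radius.

    The Euclidean distance transform at a skeleton pixel measures to the
    *centre* of the nearest background pixel, half a pixel past the true
    boundary on each side, so the diameter is 2 x median(radius) - 1 pixels
    (floored at one pixel). The first and last ``trim_frac`` of points are
    excluded from the median because the transform inflates at junctions
    and deflates at tapering tips. Edges with < 3 points fall back to all
    points.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size < 3:
        warnings.warn("edge too short for interior median; using all points")
        interior = radii
    else:
        k = int(np.floor(radii.size * trim_frac))
        interior = radii[k : radii.size - k] if radii.size - 2 * k >= 1 else radii
    diam_px = max(2.0 * float(np.median(interior)) - 1.0, 1.0)
    return diam_px * MM_PER_INCH / dpi


def _tangent(points: np.ndarray, window: int, skip: int = 0) -> np.ndarray:
    """Unit direction of a polyline over its initial ``window`` points.

    A secant (robust to 1-px jitter) from point ``skip`` to ``skip + window``;
    skipping the first few points avoids the junction zone, where thinning
    drags the lateral's centerline along the parent root.
    """
    pts = points.astype(float)
    k0 = min(skip, max(len(pts) - 2, 0))
    k1 = min(k0 + window, len(pts) - 1)
    if k1 <= k0:
        raise ValueError("degenerate polyline; cannot compute a tangent")
    v = pts[k1] - pts[k0]
    n = np.hypot(*v)
    if n == 0:
        raise ValueError("degenerate tangent (zero-length secant)")
    return v / n


def insertion_angle(
    primary: np.ndarray, lateral: np.ndarray, window: int = 20, skip: int = 0
) -> float:
    """Unsigned angle (degrees) between the primary's local axis and a lateral.

    The primary tangent is the secant over +/- ``window`` points around the
    junction (the lateral's first point); the lateral tangent is the secant
    over ``window`` points starting ``skip`` points in (clear of the junction
    zone, where thinning blends the two centerlines). Mirror-symmetric by
    construction.
    """
    junction = lateral[0]
    d = np.hypot(primary[:, 0] - junction[0], primary[:, 1] - junction[1])
    j = int(np.argmin(d))
    lo, hi = max(0, j - window), min(len(primary) - 1, j + window)
    if hi <= lo:
        raise ValueError("primary polyline too short around the junction")
    tp = primary[hi].astype(float) - primary[lo].astype(float)
    ntp = np.hypot(*tp)
    if ntp == 0:
        raise ValueError("degenerate primary tangent")
    tp /= ntp
    tl = _tangent(lateral, window, skip=skip)
    cosang = float(np.clip(np.dot(tp, tl), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def extract_root_system(
    mask: BinaryMask,
    seed: tuple[int, int] | None = None,
    prune_px: float = DEFAULT_PRUNE_PX,
    min_lateral_cm: float = DEFAULT_MIN_LATERAL_CM,
    plant_id: str = "plant",
) -> RootSystem:
    """Full architecture extraction: mask -> RootSystem with measured traits."""
    rg = skeleton_graph(mask, prune_px=prune_px)
    primary = identify_primary(rg, seed=seed)
    lateral_polys = extract_laterals(rg, primary, min_lateral_cm=min_lateral_cm)

    dist = ndimage.distance_transform_edt(mask.pixels)
    cmpx = rg.cm_per_px
    prim_len = _polyline_length_px(primary) * cmpx
    prim_diam = local_diameter(dist[primary[:, 0], primary[:, 1]], mask.dpi)
    cum = _cumulative_arclength(primary)

    laterals = []
    for pts in lateral_polys:
        radii = dist[pts[:, 0], pts[:, 1]]
        laterals.append(
            LateralRoot(
                points=pts,
                length_cm=_polyline_length_px(pts) * cmpx,
                diameter_mm=local_diameter(radii, mask.dpi),
                insertion_angle_deg=insertion_angle(primary, pts),
                position_cm=_position_along(primary, cum, pts[0]) * cmpx,
            )
        )
    return RootSystem(
        primary_points=primary,
        primary_length_cm=prim_len,
        primary_diameter_mm=prim_diam,
        laterals=laterals,
        dpi=mask.dpi,
        plant_id=plant_id,
    )


def measure_local_traits(system: RootSystem) -> LocalTraits:
    """Aggregate per-plant local traits from an extracted RootSystem."""
    if system.primary_length_cm <= 0:
        raise ValueError("zero-length primary root")
    lats = system.laterals
    total_lat = float(sum(l.length_cm for l in lats))
    return LocalTraits(
        primary_root_length=system.primary_length_cm,
        primary_root_diameter=system.primary_diameter_mm,
        lateral_branching_density=len(lats) / system.primary_length_cm,
        mean_lateral_length=float(np.mean([l.length_cm for l in lats])) if lats else None,
        mean_lateral_diameter=float(np.mean([l.diameter_mm for l in lats])) if lats else None,
        mean_insertion_angle=float(np.mean([l.insertion_angle_deg for l in lats])) if lats else None,
        total_lateral_length=total_lat,
        total_root_length=system.primary_length_cm + total_lat,
    )
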