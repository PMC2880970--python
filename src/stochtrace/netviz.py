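"""Reaction graphs: construction, degree-centrality ranking, neighborhoods,
layouts and color handling.

A reaction network becomes a directed multigraph with one node per species
and, for each reaction, an edge from every reactant to every product carrying
the reaction id and type tag.  Synthesis (no reactants) and degradation (no
products) reactions connect to a per-reaction environment pseudo-node so no
reaction is invisible in the graph.

Layouts: Circle (static, neighbor-following order), Spring (weighted force
embedder), Fruchterman-Reingold and Kamada-Kawai (via networkx, rescaled to
the canvas and packed per component), ISOM (self-organizing-map iteration),
and Temporal-Circuit, which needs simulated traces: species are placed in
columns by the rank of their first-appearance time, so species entering the
system later sit further right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import ReactionModel
from .simulate import TraceSet

__all__ = [
    "ENV_KIND",
    "Canvas",
    "Layout",
    "CentralityRanking",
    "HslColor",
    "build_reaction_graph",
    "degree_centrality",
    "rank_to_color",
    "neighborhood",
    "layout_circle",
    "layout_force",
    "layout_isom",
    "layout_temporal_circuit",
    "colorblind_filter",
]

ENV_KIND = "environment"


@dataclass(frozen=True)
class Canvas:
    width: float = 1000.0
    height: float = 1000.0
    margin: float = 50.0


@dataclass
class Layout:
    positions: dict[str, tuple[float, float]]
    algorithm: str
    canvas: Canvas
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, (x, y) in self.positions.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for node {node!r}")
            if not (0 <= x <= self.canvas.width and 0 <= y <= self.canvas.height):
                raise ValueError(f"node {node!r} placed outside the canvas")


@dataclass
class HslColor:
    hue: float  # degrees, [0, 360)
    saturation: float  # [0, 1]
    lightness: float  # [0, 1]

    def __post_init__(self) -> None:
        if not (0 <= self.hue < 360):
            raise ValueError("hue must be in [0, 360)")
        if not (0 <= self.saturation <= 1 and 0 <= self.lightness <= 1):
            raise ValueError("saturation and lightness must be in [0, 1]")


def build_reaction_graph(model: ReactionModel) -> nx.MultiDiGraph:
    """Species-node multigraph of a reaction model.

    Each reaction contributes a directed reactant -> product edge per
    (distinct reactant, distinct product) pair, tagged with the reaction id
    and rtype; zero-reactant / zero-product reactions attach to an
    ``env:<reaction id>`` pseudo-node of kind "environment".
    """
    g = nx.MultiDiGraph(name=model.name, directed=True)
    for s in model.species:
        g.add_node(s.id, kind=s.kind, annotations=list(s.annotations))
    for r in model.reactions:
        sources = sorted(set(r.reactants))
        targets = sorted(set(r.products))
        if not sources or not targets:
            env = f"env:{r.id}"
            g.add_node(env, kind=ENV_KIND, annotations=[])
            sources = sources or [env]
            targets = targets or [env]
        for u in sources:
            for v in targets:
                g.add_edge(u, v, reaction=r.id, rtype=r.rtype)
    return g


@dataclass
class CentralityRanking:
    scores: dict[str, float]  # C_D(v) = deg(v) / (n - 1), in [0, 1]*
    ranks: dict[str, int]  # dense ranks, 1 = most central, ties share
    mode: str

    # *parallel edges count with multiplicity, so multigraph scores can
    # exceed 1; simple graphs stay within [0, 1].


def degree_centrality(graph: nx.Graph, mode: str = "total") -> CentralityRanking:
    """Normalized degree centrality deg_mode(v)/(n-1) with dense ranking.

    mode "in"/"out" require a directed graph; "total" counts in+out (or
    plain degree on undirected graphs).  Parallel edges count with
    multiplicity.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    if mode == "total":
        deg = dict(graph.degree())
    elif mode == "in":
        if not graph.is_directed():
            raise ValueError("mode 'in' requires a directed graph")
        deg = dict(graph.in_degree())
    elif mode == "out":
        if not graph.is_directed():
            raise ValueError("mode 'out' requires a directed graph")
        deg = dict(graph.out_degree())
    else:
        raise ValueError(f"unknown degree mode {mode!r}")
    scores = {v: d / (n - 1) for v, d in deg.items()}
    distinct = sorted(set(scores.values()), reverse=True)
    level = {s: i + 1 for i, s in enumerate(distinct)}
    ranks = {v: level[s] for v, s in scores.items()}
    return CentralityRanking(scores=scores, ranks=ranks, mode=mode)


_LIGHT_LO, _LIGHT_HI = 0.2, 0.85


def rank_to_color(ranking: CentralityRanking, base: HslColor) -> dict[str, HslColor]:
    """Map centrality ranks onto lightness: the more central a node, the
    darker its tone.  Hue and saturation come from the base color; lightness
    runs over [0.2, 0.85], strictly decreasing with centrality, ties share a
    color."""
    if not ranking.scores:
        raise ValueError("empty ranking")
    levels = sorted(set(ranking.ranks.values()))
    k = len(levels)
    if k == 1:
        light = {levels[0]: (_LIGHT_LO + _LIGHT_HI) / 2.0}
    else:
        step = (_LIGHT_HI - _LIGHT_LO) / (k - 1)
        light = {lev: _LIGHT_LO + i * step for i, lev in enumerate(levels)}
    return {
        v: HslColor(base.hue, base.saturation, light[ranking.ranks[v]])
        for v in ranking.scores
    }


def neighborhood(graph: nx.Graph, node: str, depth: int) -> set[str]:
    """All nodes within <= depth undirected hops of `node` (inclusive)."""
    if node not in graph:
        raise ValueError(f"unknown node {node!r}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    und = graph.to_undirected(as_view=False) if graph.is_directed() else graph
    lengths = nx.single_source_shortest_path_length(und, node, cutoff=depth)
    return set(lengths)


def _ring_positions(order: list[str], canvas: Canvas) -> dict[str, tuple[float, float]]:
    cx, cy = canvas.width / 2.0, canvas.height / 2.0
    radius = 0.5 * min(canvas.width, canvas.height) - canvas.margin
    n = len(order)
    out = {}
    for k, v in enumerate(order):
        theta = 2.0 * math.pi * k / n
        out[v] = (cx + radius * math.cos(theta), cy + radius * math.sin(theta))
    return out


def layout_circle(graph: nx.Graph, canvas: Canvas = Canvas()) -> Layout:
    """Evenly spaced ring placement; graph-adjacent nodes are kept adjacent
    on the ring where possible by a greedy neighbor-following order.  Static:
    no iterations, no randomness."""
    if graph.number_of_nodes() == 0:
        return Layout({}, "circle", canvas)
    und = graph.to_undirected(as_view=False) if graph.is_directed() else graph
    unplaced = set(und.nodes)
    order: list[str] = []
    current = min(unplaced, key=str)
    while True:
        order.append(current)
        unplaced.discard(current)
        if not unplaced:
            break
        nxt = [v for v in und.neighbors(current) if v in unplaced]
        current = min(nxt, key=str) if nxt else min(unplaced, key=str)
    return Layout(_ring_positions(order, canvas), "circle", canvas)


def _rescale(
    pos: dict[str, tuple[float, float]], canvas: Canvas
) -> dict[str, tuple[float, float]]:
    """Affinely map arbitrary coordinates into the canvas minus margins."""
    xs = np.array([p[0] for p in pos.values()])
    ys = np.array([p[1] for p in pos.values()])
    lo_x, hi_x = float(xs.min()), float(xs.max())
    lo_y, hi_y = float(ys.min()), float(ys.max())
    sx = (canvas.width - 2 * canvas.margin) / (hi_x - lo_x) if hi_x > lo_x else 0.0
    sy = (canvas.height - 2 * canvas.margin) / (hi_y - lo_y) if hi_y > lo_y else 0.0
    out = {}
    for v, (x, y) in pos.items():
        nx_ = canvas.margin + (x - lo_x) * sx if sx else canvas.width / 2.0
        ny_ = canvas.margin + (y - lo_y) * sy if sy else canvas.height / 2.0
        out[v] = (nx_, ny_)
    return out


def _spring_embedder(
    und: nx.Graph, seed: int, iterations: int
) -> dict[str, tuple[float, float]]:
    """Weighted spring embedder: edges pull their endpoints together in
    proportion to their weight, all node pairs repel, displacement is capped
    by a cooling schedule."""
    nodes = sorted(und.nodes, key=str)
    n = len(nodes)
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    if n == 1:
        return {nodes[0]: (0.5, 0.5)}
    idx = {v: i for i, v in enumerate(nodes)}
    k = 1.0 / math.sqrt(n)  # natural spring length
    edges = []
    for u, v, data in und.edges(data=True):
        if u != v:
            edges.append((idx[u], idx[v], float(data.get("weight", 1.0))))
    for it in range(iterations):
        temp = 0.1 * (1.0 - it / iterations)
        disp = np.zeros((n, 2))
        # pairwise repulsion
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.maximum(np.hypot(delta[..., 0], delta[..., 1]), 1e-9)
        rep = (k * k / dist**2)[:, :, None] * (delta / dist[:, :, None])
        np.einsum("iij->ij", rep)[...] = 0.0
        disp += rep.sum(axis=1) * 0.01
        # weighted attraction along edges
        for i, j, w in edges:
            d = pos[i] - pos[j]
            dd = max(math.hypot(*d), 1e-9)
            pull = w * dd / k * 0.01
            disp[i] -= d / dd * pull
            disp[j] += d / dd * pull
        length = np.maximum(np.hypot(disp[:, 0], disp[:, 1]), 1e-9)
        pos += disp / length[:, None] * np.minimum(length, temp)[:, None]
    return {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in idx.items()}


def _pack_components(
    und: nx.Graph, layout_one, canvas: Canvas
) -> dict[str, tuple[float, float]]:
    """Lay out each connected component separately and pack the results in
    equal-width horizontal slots."""
    comps = sorted(nx.connected_components(und), key=lambda c: min(map(str, c)))
    slot_w = (canvas.width - 2 * canvas.margin) / len(comps)
    out = {}
    for ci, comp in enumerate(comps):
        sub = und.subgraph(comp)
        sub_canvas = Canvas(width=slot_w, height=canvas.height, margin=min(canvas.margin, slot_w / 4))
        pos = _rescale(layout_one(sub), sub_canvas)
        for v, (x, y) in pos.items():
            out[v] = (canvas.margin + ci * slot_w + x * (slot_w / sub_canvas.width), y)
    return out


FORCE_METHODS = ("spring", "fruchterman_reingold", "kamada_kawai")


def layout_force(
    graph: nx.Graph,
    method: str = "fruchterman_reingold",
    canvas: Canvas = Canvas(),
    seed: int = 0,
    iterations: int = 50,
) -> Layout:
    """Force-directed layouts, deterministic for a fixed seed.

    "spring" pulls adjacent nodes together according to edge weights;
    "fruchterman_reingold" is the classic attract/repel scheme with a
    decreasing temperature; "kamada_kawai" minimizes spring energy over
    graph-theoretic distances (disconnected graphs are laid out per
    component and packed horizontally).
    """
    if method not in FORCE_METHODS:
        raise ValueError(f"unknown force method {method!r}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if graph.number_of_nodes() == 0:
        return Layout({}, method, canvas, seed=seed)
    und = nx.Graph(graph.to_undirected()) if graph.is_directed() else nx.Graph(graph)
    if und.number_of_nodes() == 1:
        v = next(iter(und.nodes))
        return Layout(
            {v: (canvas.width / 2.0, canvas.height / 2.0)}, method, canvas, seed=seed
        )
    if method == "spring":
        raw = _spring_embedder(und, seed, iterations)
        pos = _rescale(raw, canvas)
    elif method == "fruchterman_reingold":
        raw = nx.spring_layout(und, seed=seed, iterations=iterations)
        pos = _rescale({v: (float(p[0]), float(p[1])) for v, p in raw.items()}, canvas)
    else:  # kamada_kawai
        def one(sub: nx.Graph):
            if sub.number_of_nodes() == 1:
                v = next(iter(sub.nodes))
                return {v: (0.0, 0.0)}
            kk = nx.kamada_kawai_layout(sub)
            return {v: (float(p[0]), float(p[1])) for v, p in kk.items()}

        if nx.is_connected(und):
            pos = _rescale(one(und), canvas)
        else:
            pos = _pack_components(und, one, canvas)
    return Layout(pos, method, canvas, seed=seed)


def layout_isom(
    graph: nx.Graph,
    canvas: Canvas = Canvas(),
    seed: int = 0,
    epochs: int = 2000,
) -> Layout:
    """Inverted self-organizing-map layout.

    Each epoch picks a random point in the drawing area, finds the vertex
    closest to it and moves that vertex — and its graph neighbors up to the
    current radius in edge steps, with exponentially damped strength — toward
    the point.  Both the radius and the adaption factor decay over epochs,
    so placement anneals from global arrangement to local refinement.
    """
    nodes = sorted(graph.nodes, key=str)
    n = len(nodes)
    if n == 0:
        return Layout({}, "isom", canvas, seed=seed)
    rng = np.random.default_rng(seed)
    lo = np.array([canvas.margin, canvas.margin])
    hi = np.array([canvas.width - canvas.margin, canvas.height - canvas.margin])
    pos = lo + rng.random((n, 2)) * (hi - lo)
    if n == 1:
        return Layout({nodes[0]: (float(pos[0, 0]), float(pos[0, 1]))}, "isom", canvas, seed=seed)
    idx = {v: i for i, v in enumerate(nodes)}
    und = graph.to_undirected(as_view=False) if graph.is_directed() else graph
    adapt_0, adapt_end = 0.8, 0.05
    radius_0 = 3
    for e in range(epochs):
        frac = e / max(epochs - 1, 1)
        adapt = adapt_0 * (adapt_end / adapt_0) ** frac
        radius = max(int(round(radius_0 * (1.0 - frac))), 0)
        target = lo + rng.random(2) * (hi - lo)
        d2 = ((pos - target) ** 2).sum(axis=1)
        winner = nodes[int(np.argmin(d2))]
        hops = nx.single_source_shortest_path_length(und, winner, cutoff=radius)
        for v, h in hops.items():
            i = idx[v]
            factor = adapt * (2.0 ** (-h))
            pos[i] += factor * (target - pos[i])
    pos = np.clip(pos, lo, hi)
    return Layout(
        {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in idx.items()},
        "isom",
        canvas,
        seed=seed,
    )


def layout_temporal_circuit(
    graph: nx.Graph, traces: TraceSet | None, canvas: Canvas = Canvas()
) -> Layout:
    """Column placement by first appearance: species initially present sit in
    column 0 on the left; a species entering the system later is placed one
    column further right per distinct first-appearance time.

    The layout encodes simulation information, so it requires traces — the
    column of a species is the rank of its pooled tstart (minimum over
    replicas) among the sorted distinct tstart values.  Environment
    pseudo-nodes count as present from the start (column 0).  Within a
    column, nodes stack vertically in identifier order; every edge gets a
    ``source_column`` annotation, the maximum column of its reaction's
    source species.
    """
    if traces is None:
        raise ValueError(
            "temporal-circuit layout requires simulated traces: it encodes "
            "first-appearance times, which only a trace set provides"
        )
    tstart = traces.pooled_tstart()
    missing = [v for v in graph.nodes if v not in tstart and graph.nodes[v].get("kind") != ENV_KIND]
    if missing:
        raise ValueError(f"traces do not cover species: {sorted(missing)}")
    node_t = {
        v: (0.0 if graph.nodes[v].get("kind") == ENV_KIND else tstart[v])
        for v in graph.nodes
    }
    finite = sorted({t for t in node_t.values() if math.isfinite(t)})
    col_of_t = {t: i for i, t in enumerate(finite)}
    never = len(finite)  # species that never appear go to one extra column
    columns = {
        v: (col_of_t[t] if math.isfinite(t) else never) for v, t in node_t.items()
    }
    n_cols = max(columns.values()) + 1
    xs = (
        {0: canvas.width / 2.0}
        if n_cols == 1
        else {
            k: canvas.margin + k * (canvas.width - 2 * canvas.margin) / (n_cols - 1)
            for k in range(n_cols)
        }
    )
    positions = {}
    for k in range(n_cols):
        members = sorted((v for v, c in columns.items() if c == k), key=str)
        for j, v in enumerate(members):
            y = canvas.height * (j + 1) / (len(members) + 1)
            positions[v] = (xs[k], y)
    # a reaction's source column is the max column over all its source
    # species; edges without a reaction tag fall back to their own source
    if graph.is_multigraph():
        edge_iter = [((u, v, k), d) for u, v, k, d in graph.edges(keys=True, data=True)]
    else:
        edge_iter = [((u, v), d) for u, v, d in graph.edges(data=True)]
    reaction_col: dict[str, int] = {}
    for (edge, d) in edge_iter:
        rid = d.get("reaction")
        if rid is not None:
            u = edge[0]
            reaction_col[rid] = max(reaction_col.get(rid, 0), columns[u])
    edge_columns = {
        edge: reaction_col.get(d.get("reaction"), columns[edge[0]])
        for edge, d in edge_iter
    }
    return Layout(
        positions,
        "temporal_circuit",
        canvas,
        extras={"columns": columns, "edge_source_columns": edge_columns},
    )


# ------------------------------------------------------------------ colors

_GREEN_BAND = (90.0, 150.0)
_RED_BAND = (0.0, 40.0)


def _mitigate_hue(h: float, saturation: float) -> float:
    """Compress red-green confusion hues toward yellow/blue, proportionally
    to the distance from the band edge; hueless (gray) colors untouched."""
    if saturation == 0:
        return h
    lo, hi = _RED_BAND
    if lo <= h <= hi:  # reds: push toward yellow, most at the deep-red edge
        return h + (1.0 - (h - lo) / (hi - lo)) * 20.0
    lo, hi = _GREEN_BAND
    if lo <= h <= hi:  # greens: push toward blue, most at the deep-green edge
        return min(h + ((h - lo) / (hi - lo)) * 30.0, 359.999)
    return h


def colorblind_filter(
    palette: list[HslColor], background: HslColor, delta: float = 0.08
) -> list[HslColor]:
    """Remap a palette for protanopic/deuteranopic viewers.

    Lightness is replaced by a ladder that preserves the input's lightness
    ordering, separates every pair by at least `delta` and keeps every color
    at least ``2*delta`` away from the background lightness.  Hues in the
    red-green confusion bands are compressed toward yellow/blue.
    """
    if not palette:
        raise ValueError("palette must be non-empty")
    n = len(palette)
    # allowed lightness values: [0,1] minus the background exclusion zone
    zones = []
    lo_excl, hi_excl = background.lightness - 2 * delta, background.lightness + 2 * delta
    if lo_excl > 0:
        zones.append((0.0, min(lo_excl, 1.0)))
    if hi_excl < 1:
        zones.append((max(hi_excl, 0.0), 1.0))
    capacity = sum(int((b - a) / delta) + 1 for a, b in zones)
    if capacity < n:
        raise ValueError(
            f"palette of {n} colors does not fit the lightness ladder at "
            f"delta={delta}; use a smaller delta"
        )
    ladder: list[float] = []
    for a, b in zones:
        v = a
        while v <= b + 1e-12 and len(ladder) < n:
            ladder.append(min(v, b))
            v += delta
    while len(ladder) < n:  # pragma: no cover - capacity check precludes this
        ladder.append(ladder[-1] + delta)
    ladder = sorted(ladder)[:n]
    order = sorted(range(n), key=lambda i: (palette[i].lightness, i))
    out: list[HslColor | None] = [None] * n
    for slot, i in enumerate(order):
        c = palette[i]
        out[i] = HslColor(
            hue=_mitigate_hue(c.hue, c.saturation) % 360.0,
            saturation=c.saturation,
            lightness=ladder[slot],
        )
    return out  # type: ignore[return-value]
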