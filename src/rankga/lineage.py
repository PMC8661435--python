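"""Branching lineage construction from per-cluster orderings.

Each cluster is ordered independently by the GA; the resulting path has two
termination points.  The distance between two paths x (length m) and y
(length n) is the minimum cost of four candidate junctions built from the
quarter-length end segments of the two paths:

* ``x1`` — head quarter of y reversed, then head quarter of x
* ``x2`` — tail quarter of y, then head quarter of x
* ``x3`` — head quarter of x reversed, then head quarter of y
* ``x4`` — tail quarter of x, then head quarter of y

each evaluated with the rank-polynomial cost on ranks recomputed over the
union of the concatenated cells.  The winning junction identifies which
termination points the edge joins.  Paths are then connected by Kruskal's
minimum-spanning-tree rule on these distances (reject cycle-creating
edges); when several clusters attach to one termination point a branching
node is inserted at that point with zero-length edges.  Supplying a root
cell or cluster orients all edges away from the root and flips
within-cluster orderings so pseudotime increases along directed edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import ClusterAssignment, ExpressionMatrix
from .ga import GAConfig, evolve
from .rank_cost import MIN_CELLS, rank_transform, total_cost

__all__ = ["ClusterPath", "LineageTree", "order_all_clusters", "endpoint_distance", "build_tree", "root_tree"]

#: the four junction geometries: (label, endpoint of x used, endpoint of y used)
_GEOMETRIES = (
    ("x1", "start", "start"),
    ("x2", "start", "end"),
    ("x3", "start", "start"),
    ("x4", "end", "start"),
)


@dataclass
class ClusterPath:
    """A cluster's internal pseudotime path: global cell indices in order."""

    cluster_id: int
    cells: np.ndarray  # global cell indices, pseudotime order

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def endpoints(self) -> tuple[np.intp, np.intp]:
        return self.cells[0], self.cells[-1]

    def head_quarter(self) -> np.ndarray:
        return self.cells[: max(1, len(self.cells) // 4)]

    def tail_quarter(self) -> np.ndarray:
        return self.cells[(3 * len(self.cells)) // 4 :]

    def reversed(self) -> "ClusterPath":
        return ClusterPath(self.cluster_id, self.cells[::-1])


@dataclass
class LineageTree:
    """Undirected (optionally rooted) tree over cluster termination points.

    Nodes are ``(cluster_id, 'start'|'end')`` tuples plus inserted
    ``('branch', i)`` nodes; each cluster's two termination points are
    linked by a zero-weight intra-cluster edge representing the path.
    """

    graph: nx.Graph
    paths: dict[int, ClusterPath]
    root: tuple | None = None
    directed: nx.DiGraph | None = None
    distances: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.paths)

    def inter_cluster_edges(self) -> list[tuple]:
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d.get("kind") == "inter"
        ]


def order_all_clusters(
    expr: ExpressionMatrix,
    clusters: ClusterAssignment,
    config: GAConfig | None = None,
) -> list[ClusterPath]:
    """Run the GA independently within each cluster (ranks recomputed on the
    cluster's own cells).  Deterministic for a fixed config seed."""
    config = config or GAConfig()
    paths = []
    for c in range(clusters.k):
        idx = clusters.members(c)
        if len(idx) < MIN_CELLS:
            raise ValueError(
                f"cluster {c} has {len(idx)} cells; at least {MIN_CELLS} are required to fit the cost model"
            )
        ranks = rank_transform(expr.subset_cells(idx))
        rng = np.random.default_rng([config.seed, c])
        res = evolve(ranks, config, rng=rng)
        paths.append(ClusterPath(c, idx[res.ordering]))
    return paths


def _junction_sequences(path_x: ClusterPath, path_y: ClusterPath) -> list[np.ndarray]:
    xh, xt = path_x.head_quarter(), path_x.tail_quarter()
    yh, yt = path_y.head_quarter(), path_y.tail_quarter()
    return [
        np.concatenate([yh[::-1], xh]),  # x1
        np.concatenate([yt, xh]),        # x2
        np.concatenate([xh[::-1], yh]),  # x3
        np.concatenate([xt, yh]),        # x4
    ]


def endpoint_distance(
    path_x: ClusterPath,
    path_y: ClusterPath,
    expr: ExpressionMatrix,
    *,
    var_floor: float | None = None,
) -> tuple[float, tuple[str, str, str]]:
    """Distance between two paths: the minimum cost over the four junction
    geometries, with ranks recomputed on each concatenation's cells.

    Returns ``(distance, (label, x_side, y_side))`` identifying the winning
    junction.  Concatenations shorter than five cells fall back to a
    degree-1 fit.  Ties are resolved in geometry order (x1..x4).
    """
    if len(path_x) < 4 or len(path_y) < 4:
        raise ValueError("endpoint_distance requires paths of at least 4 cells")
    costs = []
    for seq in _junction_sequences(path_x, path_y):
        sub = expr.subset_cells(seq)
        ranks = rank_transform(sub)
        max_degree = 3 if len(seq) >= MIN_CELLS else 1
        costs.append(total_cost(ranks, np.arange(len(seq)), max_degree=max_degree, var_floor=var_floor).total)
    costs = np.asarray(costs)
    best = int(np.argmin(costs))
    if np.allclose(costs, costs[0]):
        warnings.warn(
            f"all four junction costs tie between clusters {path_x.cluster_id} and {path_y.cluster_id}"
        )
    return float(costs[best]), _GEOMETRIES[best]


def build_tree(
    paths: list[ClusterPath],
    expr: ExpressionMatrix,
    *,
    var_floor: float | None = None,
) -> LineageTree:
    """Join cluster paths into an undirected tree by Kruskal's rule on
    endpoint distances."""
    if not paths:
        raise ValueError("need at least one path")
    g = nx.Graph()
    for p in paths:
        g.add_node((p.cluster_id, "start"), cluster=p.cluster_id)
        g.add_node((p.cluster_id, "end"), cluster=p.cluster_id)
        g.add_edge((p.cluster_id, "start"), (p.cluster_id, "end"), weight=0.0, kind="path")

    distances: dict[tuple[int, int], float] = {}
    if len(paths) > 1:
        candidates = []
        for a in range(len(paths)):
            for b in range(a + 1, len(paths)):
                px, py = paths[a], paths[b]
                d, (_, x_side, y_side) = endpoint_distance(px, py, expr, var_floor=var_floor)
                distances[(px.cluster_id, py.cluster_id)] = d
                candidates.append(
                    (d, px.cluster_id, py.cluster_id, (px.cluster_id, x_side), (py.cluster_id, y_side))
                )
        # Kruskal with deterministic tie-break on (distance, cluster pair, sides)
        candidates.sort(key=lambda e: (e[0], e[1], e[2], e[3][1], e[4][1]))
        uf = {p.cluster_id: p.cluster_id for p in paths}

        def find(x):
            while uf[x] != x:
                uf[x] = uf[uf[x]]
                x = uf[x]
            return x

        added = 0
        for d, ca, cb, na, nb in candidates:
            ra, rb = find(ca), find(cb)
            if ra == rb:
                continue
            uf[ra] = rb
            g.add_edge(na, nb, weight=d, kind="inter")
            added += 1
            if added == len(paths) - 1:
                break

    # insert branching points where several clusters share a termination point
    branch_idx = 0
    for node in list(g.nodes):
        inter = [
            (u, v, d) for u, v, d in g.edges(node, data=True) if d.get("kind") == "inter"
        ]
        if len(inter) >= 2:
            bnode = ("branch", branch_idx)
            branch_idx += 1
            g.add_node(bnode, cluster=None)
            for u, v, d in inter:
                other = v if u == node else u
                g.remove_edge(u, v)
                g.add_edge(bnode, other, **d)
            g.add_edge(node, bnode, weight=0.0, kind="branchpoint")

    return LineageTree(graph=g, paths={p.cluster_id: p for p in paths}, distances=distances)


def _resolve_root(tree: LineageTree, root) -> tuple:
    """Map a root cluster id or global cell index to a termination node."""
    if isinstance(root, tuple) and root in tree.graph:
        return root
    if root in tree.paths:  # cluster id: root at its free (unattached) end
        def n_attached(side: str) -> int:
            return sum(
                1 for _, _, d in tree.graph.edges((root, side), data=True)
                if d.get("kind") != "path"
            )
        side = "start" if n_attached("start") <= n_attached("end") else "end"
        return (root, side)
    for cid, path in tree.paths.items():  # cell index
        pos = np.flatnonzero(path.cells == root)
        if pos.size:
            side = "start" if pos[0] < len(path) / 2 else "end"
            return (cid, side)
    raise ValueError(f"root {root!r} is neither a cluster id, a cell index, nor a tree node")


def root_tree(tree: LineageTree, root) -> LineageTree:
    """Orient the tree away from ``root`` (a cluster id, cell index, or
    node); within-cluster orderings are flipped so pseudotime increases
    along every directed edge.  Topology is unchanged."""
    root_node = _resolve_root(tree, root)
    directed = nx.bfs_tree(tree.graph, root_node)
    for u, v in directed.edges:
        directed[u][v].update(tree.graph[u][v])

    new_paths: dict[int, ClusterPath] = {}
    for cid, path in tree.paths.items():
        start, end = (cid, "start"), (cid, "end")
        # entry endpoint = the one closer to the root along the tree
        d_start = nx.shortest_path_length(tree.graph, root_node, start)
        d_end = nx.shortest_path_length(tree.graph, root_node, end)
        new_paths[cid] = path.reversed() if d_end < d_start else path
    return LineageTree(
        graph=tree.graph,
        paths=new_paths,
        root=root_node,
        directed=directed,
        distances=dict(tree.distances),
    )
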