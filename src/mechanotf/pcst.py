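"""Prize-Collecting Steiner Tree (PCST) solvers.

The unrooted Goemans-Williamson objective is minimized:

    objective(F) = sum of edge costs in the forest F
                 + beta * sum of prizes of nodes NOT spanned by F

with F restricted to at most ``num_components`` trees. Two solvers are
provided: an exhaustive exact solver (small graphs; the test oracle) and
a deterministic heuristic that strong-prunes shortest-path and
minimum-spanning candidate trees.

Tie-breaking is fully specified for reproducibility: among optimal
solutions the exact solver prefers fewer nodes, then the
lexicographically smallest node-id set; the heuristic's reconstruction
excludes zero-gain branches for the same reason.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

_TOL = 1e-12


@dataclass
class SolverParams:
    beta: float = 1.0
    num_components: int = 1
    mode: str = "heuristic"  # "heuristic" | "exact"
    seed: int = 0
    max_roots: int = 256  # heuristic: cap on shortest-path-tree roots

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.num_components < 1:
            raise ValueError("num_components must be >= 1")
        if self.mode not in ("heuristic", "exact"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PCSTSolution:
    """A forest: selected nodes, selected edges, the objective value and
    per-tree membership."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    objective: float
    components: tuple[tuple[str, ...], ...]

    @property
    def num_trees(self) -> int:
        return len(self.components)


def _norm_edge(u, v):
    return (u, v) if u <= v else (v, u)


def objective_value(g: nx.Graph, nodes, edges, beta: float) -> float:
    """Recompute the GW objective from the selected sets."""
    sel = set(nodes)
    cost = sum(g.edges[e]["cost"] for e in edges)
    missed = sum(g.nodes[n]["prize"] for n in g.nodes if n not in sel)
    return cost + beta * missed


def _components_of(nodes, edges) -> tuple[tuple[str, ...], ...]:
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(edges)
    comps = [tuple(sorted(c)) for c in nx.connected_components(sub)]
    return tuple(sorted(comps))


def _make_solution(g: nx.Graph, nodes, edges, beta: float) -> PCSTSolution:
    nodes = tuple(sorted(nodes))
    edges = tuple(sorted(_norm_edge(u, v) for u, v in edges))
    comps = _components_of(nodes, edges)
    if len(edges) != len(nodes) - len(comps):
        raise ValueError("selected edges do not form a spanning forest")
    return PCSTSolution(nodes, edges, objective_value(g, nodes, edges, beta), comps)


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.to_graph()


# ---------------------------------------------------------------------------
# exact solver


def _min_spanning_forest(g: nx.Graph, subset: tuple[str, ...], max_trees: int):
    """Cheapest forest spanning ``subset`` with at most ``max_trees``
    trees, or None if infeasible. Kruskal, stopped early: with
    non-negative costs the optimum uses as many trees as allowed."""
    sel = set(subset)
    target = min(max_trees, len(subset))
    parent = {n: n for n in subset}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    cand = sorted(
        (g.edges[u, v]["cost"], *_norm_edge(u, v))
        for u, v in g.edges
        if u in sel and v in sel
    )
    chosen = []
    n_comp = len(subset)
    for cost, u, v in cand:
        if n_comp <= target:
            break
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v))
            n_comp -= 1
    if n_comp > target:
        return None
    return chosen


def solve_exact(net, params: SolverParams) -> PCSTSolution:
    """Globally optimal PCST by subset enumeration (guarded to <= 15
    nodes). Subsets are scanned smallest-first in lexicographic order,
    so ties resolve toward fewer nodes, then the smallest node-id set."""
    g = _as_graph(net)
    if g.number_of_nodes() > 15:
        raise ValueError(
            f"solve_exact is limited to 15 nodes (got {g.number_of_nodes()}); "
            "use mode='heuristic'"
        )
    all_nodes = sorted(g.nodes)
    best: PCSTSolution | None = None
    for size in range(len(all_nodes) + 1):
        for subset in itertools.combinations(all_nodes, size):
            forest = _min_spanning_forest(g, subset, params.num_components)
            if forest is None:
                continue
            sol = _make_solution(g, subset, forest, params.beta)
            if best is None or sol.objective < best.objective - _TOL:
                best = sol
    assert best is not None  # the empty forest is always feasible
    return best


# ---------------------------------------------------------------------------
# heuristic solver


def _strong_prune(g: nx.Graph, tree: nx.Graph, beta: float):
    """Optimal subtree of a given tree (GW strong pruning).

    Roots the tree and computes, bottom-up, the best achievable net
    worth ``beta*prizes - costs`` of a subtree hanging from each node;
    zero-gain branches are excluded so ties resolve to fewer nodes.
    Returns (net_worth, nodes, edges) of the best subtree (possibly a
    single node).
    """
    best_nw, best_top = -1.0, None
    nw: dict[str, float] = {}
    keep: dict[str, list[str]] = {}
    for comp in nx.connected_components(tree):
        root = min(comp)
        order = list(nx.dfs_postorder_nodes(tree, root))
        parent = dict(nx.dfs_predecessors(tree, root))
        for v in order:
            value = beta * g.nodes[v]["prize"]
            keep[v] = []
            for u in sorted(tree.neighbors(v)):
                if parent.get(u) != v:
                    continue
                gain = nw[u] - tree.edges[v, u]["cost"]
                if gain > _TOL:
                    value += gain
                    keep[v].append(u)
            nw[v] = value
            if value > best_nw + _TOL or (
                value > best_nw - _TOL and (best_top is None or v < best_top)
            ):
                best_nw, best_top = value, v
    # reconstruct downward from the best top node
    nodes, edges = [best_top], []
    stack = [best_top]
    while stack:
        v = stack.pop()
        for u in keep[v]:
            nodes.append(u)
            edges.append((v, u))
            stack.append(u)
    return best_nw, nodes, edges


def _candidate_trees(g: nx.Graph, params: SolverParams):
    """Shortest-path trees from a deterministic root set, plus the
    minimum spanning forest."""
    nodes = sorted(g.nodes)
    if len(nodes) > params.max_roots:
        roots = sorted(nodes, key=lambda n: (-g.nodes[n]["prize"], n))[: params.max_roots]
    else:
        roots = nodes
    for root in roots:
        paths = nx.single_source_dijkstra_path(g, root, weight="cost")
        t = nx.Graph()
        t.add_node(root)
        for node, path in paths.items():
            for a, b in zip(path, path[1:]):
                t.add_edge(a, b, cost=g.edges[a, b]["cost"])
        yield t
    msf = nx.Graph()
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        mst = nx.minimum_spanning_tree(sub, weight="cost")
        msf.add_nodes_from(mst.nodes)
        msf.add_edges_from((u, v, {"cost": d["cost"]}) for u, v, d in mst.edges(data=True))
    yield msf


def _best_tree(g: nx.Graph, params: SolverParams):
    """Best strong-pruned candidate tree on g, by net worth; ties go to
    fewer nodes then smaller node set."""
    best = None
    for t in _candidate_trees(g, params):
        nw, nodes, edges = _strong_prune(g, t, params.beta)
        key = (-nw, len(nodes), tuple(sorted(nodes)))
        if best is None or key < best[0]:
            best = (key, nw, nodes, edges)
    if best is None:
        return 0.0, [], []
    return best[1], best[2], best[3]


def solve(net, params: SolverParams | None = None) -> PCSTSolution:
    """Solve the PCST. Heuristic mode strong-prunes shortest-path trees
    grown from every root (capped by ``max_roots``) and the minimum
    spanning forest, keeping the best net-worth subtree; for multiple
    allowed components, trees are extracted greedily. Deterministic for
    a given instance and parameter set."""
    params = params or SolverParams()
    g = _as_graph(net)
    if params.mode == "exact":
        return solve_exact(g, params)
    work = g.copy()
    sel_nodes: list[str] = []
    sel_edges: list[tuple[str, str]] = []
    for _ in range(params.num_components):
        if work.number_of_nodes() == 0:
            break
        nw, nodes, edges = _best_tree(work, params)
        if nw <= _TOL:  # nothing worth collecting
            break
        sel_nodes.extend(nodes)
        sel_edges.extend(edges)
        work.remove_nodes_from(nodes)
    sol = _make_solution(g, sel_nodes, sel_edges, params.beta)
    return prune_solution(sol, g, beta=params.beta)


def prune_solution(sol: PCSTSolution, net, beta: float = 1.0) -> PCSTSolution:
    """Iteratively drop leaves whose scaled prize does not pay for their
    attaching edge (``beta*prize < cost``). The objective never
    increases; a second application is a no-op."""
    g = _as_graph(net)
    sub = nx.Graph()
    sub.add_nodes_from(sol.nodes)
    sub.add_edges_from(sol.edges)
    changed = True
    while changed:
        changed = False
        for v in sorted(sub.nodes):
            if sub.degree(v) == 1:
                (u,) = sub.neighbors(v)
                if beta * g.nodes[v]["prize"] < g.edges[v, u]["cost"] - _TOL:
                    sub.remove_node(v)
                    changed = True
    return _make_solution(g, list(sub.nodes), list(sub.edges), beta)
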