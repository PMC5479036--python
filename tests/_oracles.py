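"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written against different primitives than
the implementation under test (explicit dynamic-programming tables,
networkx graph walks, brute-force enumeration) so that agreement is
evidence, not tautology.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# Smith-Waterman (Gotoh affine-gap) full-table oracle


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal local alignment score; first gap residue costs `gap_open`,
    each further residue `gap_extend` (matching the engine's convention)."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), -np.inf)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = blosum[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return float(best)


# ---------------------------------------------------------------------------
# Tree helpers on networkx (independent of skbio tree surgery)


def tree_to_graph(tree) -> tuple[nx.Graph, dict]:
    """Undirected weighted graph of a (skbio) tree; nodes are node ids."""
    g = nx.Graph()
    names = {}
    for node in tree.traverse(include_self=True):
        g.add_node(id(node))
        if node.is_tip():
            names[id(node)] = node.name
        if node.parent is not None:
            g.add_edge(id(node), id(node.parent), weight=float(node.length or 0.0))
    return g, names


def midpoint_optimum_oracle(tree) -> float:
    """Minimal achievable max root-to-leaf depth over all points on all edges."""
    g, names = tree_to_graph(tree)
    tips = [n for n, nm in names.items() if nm is not None]
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    best = np.inf
    for u, v, data in list(g.edges(data=True)):
        length = data["weight"]
        # removing edge (u, v) splits the tips into the u side and the v side
        g.remove_edge(u, v)
        comp_u = nx.node_connected_component(g, u)
        g.add_edge(u, v, weight=length)
        side_u = [t for t in tips if t in comp_u]
        side_v = [t for t in tips if t not in comp_u]
        if not side_u or not side_v:
            du = max(dist[u][t] for t in side_u) if side_u else 0.0
            best = min(best, du)
            continue
        du = max(dist[u][t] for t in side_u)
        dv = max(dist[v][t] for t in side_v)
        # root at x from u: f(x) = max(x + du, (length - x) + dv), x in [0, length]
        x = np.clip((length + dv - du) / 2.0, 0.0, length)
        best = min(best, max(x + du, (length - x) + dv))
    return float(best)


def max_root_depth(rooted_tree) -> float:
    return max(_depth(tip) for tip in rooted_tree.tips())


def _depth(tip) -> float:
    d = 0.0
    node = tip
    while node.parent is not None:
        d += node.length or 0.0
        node = node.parent
    return d


def rt_winner_oracle(tree, query: str, outgroup_species: str, species_of) -> str:
    """Exhaustive RT-rooting candidate enumeration on a networkx graph.

    For each outgroup leaf, orient the tree away from that leaf and find
    the largest query-containing subtree with no outgroup leaf; score by
    ingroup species count, break ties by query-candidate path length then
    by name. Returns the winning outgroup leaf name.
    """
    g, names = tree_to_graph(tree)
    tip_by_name = {nm: n for n, nm in names.items() if nm is not None}
    out_leaves = sorted(nm for nm in tip_by_name if species_of(nm) == outgroup_species)
    qnode = tip_by_name[query]
    dist = nx.single_source_dijkstra_path_length(g, qnode, weight="weight")
    scored = []
    for cand in out_leaves:
        cnode = tip_by_name[cand]
        # orientation: BFS tree from the candidate; the subtree "below" a node
        # (away from the candidate) is its descendant set in this orientation
        parents = dict(nx.bfs_predecessors(g, cnode))
        # climb from query toward candidate; stop before a subtree that
        # contains an outgroup leaf
        def subtree_tips(node):
            seen, stack, tips = {node}, [node], []
            while stack:
                cur = stack.pop()
                for nb in g.neighbors(cur):
                    if nb in seen or parents.get(cur) == nb:
                        continue
                    seen.add(nb)
                    stack.append(nb)
                if names.get(cur) is not None:
                    tips.append(names[cur])
            return tips

        best_node = qnode
        node = qnode
        while node in parents:
            nxt = parents[node]
            if nxt == cnode:
                break
            tips = subtree_tips(nxt)
            if any(species_of(t) == outgroup_species for t in tips):
                break
            best_node = nxt
            node = nxt
        species = {species_of(t) for t in subtree_tips(best_node)} - {outgroup_species}
        scored.append((-len(species), -dist[cnode], cand))
    scored.sort()
    return scored[0][2]


def prune_survivors_oracle(tree, query: str, cutoff: float) -> set[str]:
    """Leaves surviving iterated long-branch cutting, on a networkx graph.

    Mirrors the unrooted semantics: cut every edge above the cutoff, keep
    the query's component, splice out degree-2 junctions (edge lengths
    add) and dangling leafless stubs, and repeat until no edge exceeds the
    cutoff.
    """
    g, names = tree_to_graph(tree)
    leaf_nodes = {n for n, nm in names.items() if nm is not None}
    qnode = next(n for n, nm in names.items() if nm == query)
    while True:
        long_edges = [(u, v) for u, v, d in list(g.edges(data=True)) if d["weight"] > cutoff]
        if not long_edges:
            break
        g.remove_edges_from(long_edges)
        comp = nx.node_connected_component(g, qnode)
        g = g.subgraph(comp).copy()
        changed = True
        while changed:
            changed = False
            for u in list(g.nodes):
                if u in leaf_nodes:
                    continue
                deg = g.degree(u)
                if deg <= 1:
                    g.remove_node(u)
                    changed = True
                elif deg == 2:
                    (a, b) = list(g.neighbors(u))
                    w = g[u][a]["weight"] + g[u][b]["weight"]
                    g.remove_node(u)
                    g.add_edge(a, b, weight=w)
                    changed = True
    return {names[n] for n in g.nodes if n in leaf_nodes}


# ---------------------------------------------------------------------------
# Dense MCL reference


def mcl_oracle(weights: np.ndarray, ids, inflation: float = 1.2,
               expansion: int = 2, max_iter: int = 200, tol: float = 1e-6,
               prune: float = 1e-8) -> list[frozenset]:
    """Loop-based dense MCL; clusters from the nonzero pattern of the limit.

    Cluster extraction differs from the implementation: the limit matrix is
    turned into an undirected graph over its nonzero entries and connected
    components are read off with networkx.
    """
    m = np.array(weights, dtype=float)
    for j in range(m.shape[1]):
        s = m[:, j].sum()
        if s > 0:
            m[:, j] /= s
    for _ in range(max_iter):
        prev = m.copy()
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        for j in range(m.shape[1]):
            s = m[:, j].sum()
            if s > 0:
                m[:, j] /= s
        m[m < prune] = 0.0
        for j in range(m.shape[1]):
            s = m[:, j].sum()
            if s > 0:
                m[:, j] /= s
        if np.abs(m - prev).max() < tol:
            break
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    for i, j in zip(*np.nonzero(m)):
        g.add_edge(int(i), int(j))
    return [frozenset(ids[i] for i in comp) for comp in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# Recursive event-labeling / extraction oracle


def label_extract_oracle(shape, query_path: tuple[int, ...]) -> set[str]:
    """Orthologs of the leaf at `query_path` in a nested-tuple tree.

    `shape` is a leaf ``("leafname", "species")`` or a tuple of subtrees.
    Implemented recursively and independently: species sets bottom-up,
    species-overlap labels, explicit root-ward overwrite, then a root-down
    search for the last duplication above the query.
    """

    def species_and_events(node, path):
        if isinstance(node[0], str) and len(node) == 2 and isinstance(node[1], str):
            return {node[1]}, {}
        sets, events = [], {}
        for i, child in enumerate(node):
            s, e = species_and_events(child, path + (i,))
            sets.append(s)
            events.update(e)
        union = set().union(*sets)
        if len(union) == 1:
            events[path] = "single_species_gene"
        elif any(sets[i] & sets[j] for i in range(len(sets)) for j in range(i + 1, len(sets))):
            events[path] = "duplication"
        else:
            events[path] = "speciation"
        return union, events

    _, events = species_and_events(shape, ())
    # overwrite: a speciation with any duplication below it becomes a duplication
    for path, ev in sorted(events.items(), key=lambda kv: -len(kv[0])):
        if ev != "duplication":
            continue
        for k in range(len(path)):
            anc = path[:k]
            if events.get(anc) == "speciation":
                events[anc] = "duplication"

    # walk from the root down toward the query; remember the deepest
    # duplication strictly above the query leaf
    last_dup_depth = None
    for k in range(len(query_path)):
        if events.get(query_path[:k]) == "duplication":
            last_dup_depth = k
    if last_dup_depth is None:
        clade_path = ()
    else:
        clade_path = query_path[: last_dup_depth + 1]

    node = shape
    for i in clade_path:
        node = node[i]

    leaves: set[str] = set()

    def collect(nd):
        if isinstance(nd[0], str) and len(nd) == 2 and isinstance(nd[1], str):
            leaves.add(nd[0])
        else:
            for child in nd:
                collect(child)

    collect(node)
    return leaves


def enumerate_species_trees(n_leaves: int, species=("A", "B", "C")):
    """All rooted binary tree shapes with up to symmetry-distinct species
    labelings, as nested tuples of ``(leafname, species)`` leaves.

    Leaves get unique names on materialization; symmetric duplicates
    (identical up to child order) are generated once.
    """
    memo: dict[int, set] = {}

    def canon(t):
        if isinstance(t[0], str):
            return t
        return tuple(sorted((canon(c) for c in t), key=repr))

    def gen(n):
        if n in memo:
            return memo[n]
        if n == 1:
            out = {("L", sp) for sp in species}
        else:
            out = set()
            for a in range(1, n // 2 + 1):
                for left in gen(a):
                    for right in gen(n - a):
                        out.add(canon((left, right)))
        memo[n] = out
        return out

    counter = itertools.count()

    def materialize(t):
        if isinstance(t[0], str):
            sp = t[1]
            return (f"{sp}|x{next(counter)}", sp)
        return tuple(materialize(c) for c in t)

    for n in range(1, n_leaves + 1):
        for shape in sorted(gen(n), key=repr):
            yield materialize(shape)


def shape_to_newick(shape) -> str:
    def render(node):
        if isinstance(node[0], str):
            return f"{node[0]}:1.0"
        return "(" + ",".join(render(c) for c in node) + "):1.0"

    return render(shape).rsplit(":", 1)[0] + ";"


def leaf_paths(shape, path=()):
    """Yield (leafname, path) for every leaf of a nested-tuple tree."""
    if isinstance(shape[0], str):
        yield shape[0], path
    else:
        for i, child in enumerate(shape):
            yield from leaf_paths(child, path + (i,))
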