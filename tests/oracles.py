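"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths (and networkx algorithms)
they are checking: shortest paths by DFS enumeration, triangles by direct
counting, PageRank by solving its linear system, modularity by exhaustive
partition search, Faith's PD by unioning root paths.
"""

import itertools

import numpy as np


def cooccurrence_edges(sample_sets):
    """Edge weights by exhaustive pair enumeration over sample genus sets."""
    weights = {}
    for s in sample_sets:
        for a, b in itertools.combinations(sorted(s), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
    return weights


def _all_shortest_paths(adj, s, t):
    """All shortest s-t paths by breadth-limited DFS enumeration."""
    best, paths = None, []

    def dfs(node, path):
        nonlocal best
        if best is not None and len(path) - 1 > best:
            return
        if node == t:
            if best is None or len(path) - 1 < best:
                best = len(path) - 1
                paths.clear()
            if len(path) - 1 == best:
                paths.append(list(path))
            return
        for nb in adj[node]:
            if nb not in path:
                dfs(nb, path + [nb])

    dfs(s, [s])
    return paths


def betweenness_bruteforce(adj):
    """Unnormalized betweenness: for each unordered pair, the fraction of
    shortest paths through v, summed."""
    nodes = sorted(adj)
    bnc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bnc[v] += through / len(paths)
    return bnc


def clustering_bruteforce(adj):
    """Local clustering by direct triangle counting."""
    cc = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            cc[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a])
        cc[v] = 2.0 * links / (k * (k - 1))
    return cc


def pagerank_linear_solve(weights, nodes, damping=0.85):
    """Solve (I - d M^T) x = (1-d)/n, then normalize — the stationary point
    of the power iteration with teleport-only isolated nodes."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n))
    for (a, b), w in weights.items():
        W[idx[a], idx[b]] = w
        W[idx[b], idx[a]] = w
    s = W.sum(axis=1)
    M = np.divide(W, s[:, None], out=np.zeros_like(W), where=s[:, None] > 0)
    x = np.linalg.solve(np.eye(n) - damping * M.T, np.full(n, (1 - damping) / n))
    x /= x.sum()
    return {v: x[idx[v]] for v in nodes}


def _partitions(items):
    """All set partitions (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_value(weights, partition):
    """Newman's weighted Q computed from first principles."""
    m2 = 2.0 * sum(weights.values())
    if m2 == 0:
        return 0.0
    strength = {}
    for (a, b), w in weights.items():
        strength[a] = strength.get(a, 0.0) + w
        strength[b] = strength.get(b, 0.0) + w
    q = 0.0
    for block in partition:
        block = set(block)
        w_in = sum(w for (a, b), w in weights.items() if a in block and b in block)
        s_tot = sum(strength.get(v, 0.0) for v in block)
        q += w_in / (m2 / 2.0) - (s_tot / m2) ** 2
    return q


def best_partition_bruteforce(weights, nodes):
    """Exhaustive modularity maximization (feasible for <= 8 nodes)."""
    best_q, best_p = -np.inf, None
    for part in _partitions(sorted(nodes)):
        q = modularity_value(weights, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, [set(b) for b in best_p]


def faith_pd_bruteforce(tree, taxa):
    """PD as the size of the union of root-to-tip edge sets."""
    edges = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in taxa:
            node = leaf
            while node.parent_node is not None:
                edges.add(node)
                node = node.parent_node
    return sum(n.edge.length or 0.0 for n in edges)
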