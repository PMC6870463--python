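"""Independent straight-loop Markov clustering, used as an oracle.

Written directly from the textbook description of the algorithm with
plain Python lists — deliberately sharing no code with the package's
vectorised implementation. Only suitable for small graphs. Also hosts
the fixture-graph suite both implementations are compared on.
"""

from __future__ import annotations

import numpy as np


def _clique(names: list[str], w: float = 1.0) -> list[tuple[str, str, float]]:
    return [(a, b, w) for i, a in enumerate(names) for b in names[i + 1:]]


def fixture_graphs() -> list[tuple[list[str], list[tuple[str, str, float]]]]:
    """>= 20 small graphs: disjoint cliques, single cliques and planted
    partitions with weak bridges, at varied sizes and weights."""
    graphs = []
    rng = np.random.default_rng(0)
    for na, nb in [(3, 3), (4, 5), (5, 5), (6, 4), (7, 3)]:
        a = [f"a{i}" for i in range(na)]
        b = [f"b{i}" for i in range(nb)]
        graphs.append((a + b, _clique(a, 0.9) + _clique(b, 0.95)))
    for na, nb, bw in [(4, 4, 0.2), (5, 5, 0.3), (6, 6, 0.25), (5, 4, 0.15),
                       (4, 6, 0.35)]:
        a = [f"a{i}" for i in range(na)]
        b = [f"b{i}" for i in range(nb)]
        edges = _clique(a, 0.9) + _clique(b, 0.9) + [("a0", "b0", bw)]
        graphs.append((a + b, edges))
    for n in (3, 4, 5, 6, 7):  # single cliques
        names = [f"n{i}" for i in range(n)]
        graphs.append((names, _clique(names, 0.85)))
    for k in range(5):  # three modules with noisy within-module weights
        mods = [[f"m{j}_{i}" for i in range(3 + (j + k) % 3)] for j in range(3)]
        edges = []
        for mod in mods:
            edges += _clique(mod, round(0.8 + 0.15 * rng.random(), 3))
        edges.append((mods[0][0], mods[1][0], 0.2))
        graphs.append(([v for mod in mods for v in mod], edges))
    return graphs


def reference_mcl(
    nodes: list[str],
    weighted_edges: list[tuple[str, str, float]],
    inflation: float = 1.7,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[frozenset[str]]:
    """Cluster a small weighted graph; returns the partition as frozensets."""
    nodes = sorted(nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for u, v, w in weighted_edges:
        m[pos[u]][pos[v]] = w
        m[pos[v]][pos[u]] = w
    for j in range(n):
        col_max = max(m[i][j] for i in range(n))
        m[j][j] = col_max if col_max > 0 else 1.0

    def normalize(mat):
        out = [row[:] for row in mat]
        for j in range(n):
            s = sum(out[i][j] for i in range(n))
            if s > 0:
                for i in range(n):
                    out[i][j] /= s
        return out

    def matmul(a, b):
        out = [[0.0] * n for _ in range(n)]
        for i in range(n):
            for k in range(n):
                if a[i][k] == 0.0:
                    continue
                aik = a[i][k]
                for j in range(n):
                    out[i][j] += aik * b[k][j]
        return out

    m = normalize(m)
    for _ in range(max_iter):
        prev = m
        expanded = m
        for _ in range(expansion - 1):
            expanded = matmul(expanded, m)
        inflated = [[x ** inflation for x in row] for row in expanded]
        inflated = normalize(inflated)
        for j in range(n):
            col = [inflated[i][j] for i in range(n)]
            keep_i = max(range(n), key=lambda i: col[i])
            for i in range(n):
                if inflated[i][j] < prune_threshold and i != keep_i:
                    inflated[i][j] = 0.0
        m = normalize(inflated)
        delta = max(abs(m[i][j] - prev[i][j]) for i in range(n) for j in range(n))
        if delta < tol:
            break

    # connected components of the symmetrised support
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if m[i][j] > 0.0 and i != j:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    components: list[frozenset[str]] = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        components.append(frozenset(nodes[i] for i in comp))
    return components
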