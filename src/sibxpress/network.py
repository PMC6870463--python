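"""Co-expression network construction and Markov clustering.

The graph pipeline mirrors the standard co-expression workflow: a
Pearson correlation matrix (gene-to-gene or sample-to-sample), a
threshold graph keeping edges with r >= r_min, Markov clustering (MCL)
of the weighted graph, per-cluster mean expression profiles with an LPS
trend label, and hypergeometric gene-set enrichment with
Benjamini-Hochberg correction in place of a web annotation service.

MCL here is the canonical algorithm: build a column-stochastic matrix
from edge weights plus self-loops, then alternate expansion (matrix
power) and inflation (entrywise power + column renormalisation) with
pruning of tiny entries, until the matrix stops changing; clusters are
the connected components of the attractor support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix


def correlation_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    mode: str = "gene",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Full symmetric Pearson r matrix over genes or samples.

    Zero-variance vectors are excluded with a warning (their correlation
    is undefined). Requires >= 3 observations per vector.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    data = values if mode == "gene" else values.T
    if mode not in ("gene", "sample"):
        raise ValueError("mode must be 'gene' or 'sample'")
    if data.shape[1] < 3:
        raise ValueError("need >= 3 observations per vector for correlation")
    arr = data.to_numpy(dtype=float)
    if log_transform:
        arr = np.log2(arr + 1.0)
    sd = arr.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance vector(s)",
                      stacklevel=2)
    ids = data.index[keep]
    r = np.corrcoef(arr[keep])
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ids, columns=ids)


def threshold_graph(corr: pd.DataFrame, r_min: float) -> nx.Graph:
    """Undirected graph with an edge (i, j) iff r_ij >= r_min and i != j.

    All nodes are retained; isolated ones simply have no edges (they are
    reported as unclustered downstream).
    """
    if not np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    g = nx.Graph(r_min=r_min)
    g.add_nodes_from(corr.index)
    a = corr.to_numpy()
    ii, jj = np.where(np.triu(a >= r_min, k=1))
    g.add_weighted_edges_from(
        (corr.index[i], corr.index[j], float(a[i, j])) for i, j in zip(ii, jj)
    )
    return g


@dataclass
class ClusterSet:
    """MCL output: disjoint clusters numbered by decreasing size from 1."""

    clusters: list[list[str]]          # cluster k -> members (cluster ids are k+1)
    unclustered: list[str]
    inflation: float
    converged: bool
    n_iterations: int

    def membership(self) -> pd.Series:
        """node -> cluster number (1-based; 0 for unclustered)."""
        out = {n: 0 for n in self.unclustered}
        for k, members in enumerate(self.clusters, start=1):
            out.update({m: k for m in members})
        return pd.Series(out)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def _column_normalize(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0, keepdims=True)
    s[s == 0] = 1.0
    return m / s


def mcl(
    graph: nx.Graph,
    inflation: float = 1.7,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
    binarize: bool = False,
    min_cluster_size: int = 3,
) -> ClusterSet:
    """Markov clustering of a weighted correlation graph.

    Edge weights (Pearson r, or 1 with ``binarize``) feed the stochastic
    matrix; each node gets a self-loop equal to its maximum incident
    weight (1 for isolated nodes). Non-convergence within ``max_iter``
    returns the current clustering with ``converged`` False and a
    warning, never silently. Groups smaller than ``min_cluster_size``
    are reported as unclustered. Clusters are numbered by decreasing
    size, ties broken by the lexicographically smallest member.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("MCL on an empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = 1.0 if binarize else float(d.get("weight", 1.0))
        m[pos[u], pos[v]] = m[pos[v], pos[u]] = w
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m = _column_normalize(m)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = _column_normalize(np.power(m, inflation))
        keep = m >= prune_threshold
        keep[m.argmax(axis=0), np.arange(n)] = True  # never empty a column
        m = _column_normalize(np.where(keep, m, 0.0))
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations",
                      stacklevel=2)

    support = (m > 0) | (m > 0).T
    comp_graph = nx.from_numpy_array(support)
    groups = [[nodes[i] for i in comp] for comp in nx.connected_components(comp_graph)]

    isolated = {v for v in nodes if graph.degree(v) == 0}
    clusters, unclustered = [], list(isolated)
    for g in groups:
        members = sorted(set(g) - isolated)
        if len(members) >= min_cluster_size:
            clusters.append(members)
        else:
            unclustered.extend(members)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return ClusterSet(clusters, sorted(unclustered), inflation, converged, it)


# ---------------------------------------------------------------------------
# cluster profiles


@dataclass
class ClusterProfiles:
    profiles: pd.DataFrame   # clusters x samples, mean TPM over member genes
    trends: pd.Series        # cluster -> 'up with LPS' / 'down with LPS' / 'unchanged'
    fold: pd.Series          # paired LPS/control fold on the profile


def cluster_profiles(
    clusters: ClusterSet,
    matrix: ExpressionMatrix,
    fold_thresh: float = 2.0,
    pseudocount: float = 0.5,
) -> ClusterProfiles:
    """Per-cluster mean expression profiles with an LPS trend label.

    The profile is the arithmetic mean over member genes per sample; the
    trend compares the profile's mean over LPS samples with its mean over
    control samples ((+pc)/(+pc) fold; 'up with LPS' when > fold_thresh,
    'down with LPS' when < 1/fold_thresh, else 'unchanged'). Empty
    clusters are excluded.
    """
    rows, index = [], []
    for k, members in enumerate(clusters.clusters, start=1):
        present = [g for g in members if g in matrix.gene_ids]
        if not present:
            continue
        rows.append(matrix.values.loc[present].mean(axis=0))
        index.append(k)
    profiles = pd.DataFrame(rows, index=pd.Index(index, name="cluster"))

    is_lps = (matrix.samples["treatment"] == "LPS").to_numpy()
    if is_lps.any() and (~is_lps).any():
        fold = (profiles.loc[:, is_lps].mean(axis=1) + pseudocount) / (
            profiles.loc[:, ~is_lps].mean(axis=1) + pseudocount
        )
    else:
        fold = pd.Series(np.nan, index=profiles.index)
    trends = pd.Series(
        np.where(fold > fold_thresh, "up with LPS",
                 np.where(fold < 1.0 / fold_thresh, "down with LPS", "unchanged")),
        index=profiles.index,
    )
    return ClusterProfiles(profiles, trends, fold)


def cluster_table(
    clusters: ClusterSet, profiles: ClusterProfiles | None = None
) -> pd.DataFrame:
    """Summary table (cluster, size, trend, members) ordered by size."""
    rows = []
    for k, members in enumerate(clusters.clusters, start=1):
        trend = profiles.trends.get(k, "") if profiles is not None else ""
        rows.append({"cluster": k, "size": len(members), "trend": trend,
                     "members": ",".join(members)})
    return pd.DataFrame(rows, columns=["cluster", "size", "trend", "members"])


# ---------------------------------------------------------------------------
# gene-set enrichment


def gene_set_enrichment(
    cluster_genes: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation sets in a cluster.

    For each set, p is the upper-tail probability of observing at least
    the seen overlap when drawing ``len(cluster)`` genes from the
    universe without replacement; q is Benjamini-Hochberg adjusted across
    the tested sets. Cluster genes missing from the universe are dropped
    with a warning.
    """
    universe = set(universe)
    cluster = set(cluster_genes)
    missing = cluster - universe
    if missing:
        warnings.warn(
            f"dropping {len(missing)} cluster gene(s) not in the universe",
            stacklevel=2,
        )
        cluster &= universe
    n_univ, n_draw = len(universe), len(cluster)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        k = len(cluster & members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_draw))
        rows.append({"set": name, "set_size": len(members), "overlap": k,
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if len(table):
        from statsmodels.stats.multitest import multipletests

        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["q_value"] = []
    return table.sort_values(["p_value", "set"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# export


def write_edge_list(graph: nx.Graph, path: str) -> None:
    """Tab-separated edge list: node1, node2, r."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tr\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6g}\n")


def write_graphml(graph: nx.Graph, path: str) -> None:
    nx.write_graphml(graph, path)
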