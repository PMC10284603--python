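"""Gene-set subnetwork statistics with permutation nulls and hub tests.

Given a scored protein-association network (STRING-style combined scores on
a 0-1000 scale) and a gene set (e.g. differentially expressed genes), the
module builds the induced high-confidence subnetwork (score strictly above
700 by default), measures its size (edge count) and complexity (average
local clustering coefficient), and judges significance against random gene
sets of the same size drawn from an expressed-gene background.  Hub genes
are ranked by betweenness and stress centrality, and their connections are
tested for over-representation with one-sided Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneNetwork",
    "NetworkStats",
    "PermutationNull",
    "build_subnetwork",
    "network_stats",
    "permutation_test",
    "centrality_ranking",
    "hub_connection_test",
    "hub_connection_tests",
    "substrate_enrichment",
]

MIN_SCORE = 700   # "high confidence" cutoff; edges must score strictly above


class GeneNetwork:
    """Undirected scored gene-gene network.

    Edges are deduplicated symmetrically (the higher score wins) and
    self-loops dropped on load.
    """

    def __init__(self, edges: pd.DataFrame):
        required = {"gene_a", "gene_b", "combined_score"}
        if not required.issubset(edges.columns):
            raise ValueError(f"edge list needs columns {sorted(required)}")
        e = edges.copy()
        e = e[e["gene_a"] != e["gene_b"]]
        key = np.where(e["gene_a"] < e["gene_b"],
                       e["gene_a"] + "\x00" + e["gene_b"],
                       e["gene_b"] + "\x00" + e["gene_a"])
        e = e.assign(_key=key).sort_values("combined_score").drop_duplicates(
            "_key", keep="last").drop(columns="_key")
        self.edges = e.reset_index(drop=True)
        self.nodes = set(e["gene_a"]) | set(e["gene_b"])

    def graph(self, min_score: int = MIN_SCORE) -> nx.Graph:
        """Full network keeping edges with score strictly above min_score;
        all nodes of the universe are retained."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        strong = self.edges[self.edges["combined_score"] > min_score]
        g.add_edges_from(zip(strong["gene_a"], strong["gene_b"]))
        return g


def build_subnetwork(network: GeneNetwork, gene_set, min_score: int = MIN_SCORE) -> nx.Graph:
    """Induced subgraph on ``gene_set`` intersected with the node universe,
    edges with combined score > min_score (strict).  An empty intersection
    yields an empty graph."""
    members = set(gene_set) & network.nodes
    return network.graph(min_score).subgraph(members).copy()


@dataclass
class NetworkStats:
    n_edges: int
    avg_clustering: float


def network_stats(subgraph: nx.Graph) -> NetworkStats:
    """Edge count and mean local clustering coefficient over the subgraph's
    nodes (nodes of degree < 2 contribute 0)."""
    n = subgraph.number_of_nodes()
    if n == 0:
        return NetworkStats(0, 0.0)
    clus = nx.clustering(subgraph)
    return NetworkStats(subgraph.number_of_edges(), float(np.mean(list(clus.values()))))


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    n_perm: int
    seed: int
    observed: NetworkStats
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    exceedances: dict[str, int]
    p_value: dict[str, float]
    p_label: dict[str, str]
    conservative: bool = False


def _stats_from_adjacency(A: np.ndarray, idx: np.ndarray) -> tuple[int, float]:
    """Edge count and average local clustering on the induced boolean
    adjacency submatrix (triangle counting via matrix powers)."""
    S = A[np.ix_(idx, idx)]
    deg = S.sum(axis=1)
    edges = int(deg.sum() // 2)
    tri = np.diag(S.astype(np.int64) @ S @ S) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return edges, float(c.mean()) if len(c) else 0.0


def permutation_test(
    network: GeneNetwork,
    gene_set,
    background,
    n_perm: int = 100_000,
    seed: int = 0,
    min_score: int = MIN_SCORE,
    conservative: bool = False,
) -> PermutationNull:
    """Permutation significance of a gene set's subnetwork statistics.

    Each permutation draws ``len(gene_set)`` genes uniformly without
    replacement from the background (typically the expressed genes of the
    relevant condition) and recomputes edge count and average clustering.
    The empirical p is the proportion of permutations with a statistic at or
    above the observed value (``k / N``, labelled ``"< 1/N"`` when no
    permutation reaches it); ``conservative=True`` reports ``(k+1)/(N+1)``
    instead.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    gene_set = list(dict.fromkeys(gene_set))
    background = list(dict.fromkeys(background))
    if len(background) <= len(gene_set):
        raise ValueError("background must be larger than the gene set")
    rng = np.random.default_rng(seed)

    obs = network_stats(build_subnetwork(network, gene_set, min_score))

    universe = sorted(set(background) | set(gene_set))
    pos = {g: i for i, g in enumerate(universe)}
    A = np.zeros((len(universe), len(universe)), dtype=bool)
    strong = network.edges[network.edges["combined_score"] > min_score]
    for ga, gb in zip(strong["gene_a"], strong["gene_b"]):
        ia, ib = pos.get(ga), pos.get(gb)
        if ia is not None and ib is not None:
            A[ia, ib] = A[ib, ia] = True
    bg_idx = np.array([pos[g] for g in background])

    m = len(gene_set)
    null_edges = np.empty(n_perm)
    null_clus = np.empty(n_perm)
    for k in range(n_perm):
        draw = rng.choice(bg_idx, size=m, replace=False)
        null_edges[k], null_clus[k] = _stats_from_adjacency(A, draw)

    out_mean, out_sd, out_k, out_p, out_label = {}, {}, {}, {}, {}
    for name, null, ob in (("edges", null_edges, obs.n_edges),
                           ("clustering", null_clus, obs.avg_clustering)):
        k = int((null >= ob - 1e-12).sum())
        p = (k + 1) / (n_perm + 1) if conservative else k / n_perm
        out_mean[name] = float(null.mean())
        out_sd[name] = float(null.std(ddof=1)) if n_perm > 1 else 0.0
        out_k[name] = k
        out_p[name] = float(p)
        out_label[name] = f"< {1 / n_perm:g}" if (k == 0 and not conservative) else f"{p:g}"
    return PermutationNull(n_perm, int(seed), obs, out_mean, out_sd, out_k,
                           out_p, out_label, conservative)


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

def _bfs_counts(adj: list[np.ndarray], s: int, n: int):
    """Unweighted single-source distances and shortest-path counts."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[s] = 0
    sigma[s] = 1.0
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if dist[v] == -1:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        frontier = nxt
    return dist, sigma


def stress_centrality(graph: nx.Graph) -> dict:
    """Raw shortest-path count through each node.

    ``stress(v) = sum over unordered pairs {s, t} (s, t != v) of the number
    of shortest s-t paths passing through v``.  Disconnected pairs
    contribute nothing, so components are handled independently.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    index = {u: i for i, u in enumerate(nodes)}
    adj = [np.array([index[v] for v in graph.neighbors(u)], dtype=np.int64)
           for u in nodes]
    D = np.full((n, n), -1, dtype=np.int64)
    S = np.zeros((n, n))
    for i in range(n):
        D[i], S[i] = _bfs_counts(adj, i, n)
    stress = {}
    reach = D >= 0
    for vi, v in enumerate(nodes):
        through = (D[:, vi][:, None] + D[vi, None, :] == D) \
            & reach[:, vi][:, None] & reach[vi, None, :] & reach
        paths = np.where(through, S[:, vi][:, None] * S[vi, None, :], 0.0)
        paths[vi, :] = 0.0
        paths[:, vi] = 0.0
        np.fill_diagonal(paths, 0.0)
        stress[v] = int(round(paths.sum() / 2.0))
    return stress


def centrality_ranking(subgraph: nx.Graph) -> pd.DataFrame:
    """Betweenness (fraction-weighted) and stress (raw-count) centrality per
    node, sorted by descending betweenness then stress, ties broken by node
    label."""
    bet = nx.betweenness_centrality(subgraph)
    stress = stress_centrality(subgraph)
    df = pd.DataFrame({
        "gene": list(subgraph.nodes),
        "betweenness": [bet[v] for v in subgraph.nodes],
        "stress": [stress[v] for v in subgraph.nodes],
    })
    return df.sort_values(["betweenness", "stress", "gene"],
                          ascending=[False, False, True],
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------

def _fisher_greater(table: np.ndarray) -> tuple[float, bool]:
    """One-sided (enrichment) Fisher exact p; degenerate margins give p = 1
    with a flag."""
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0, True
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p), False


def hub_connection_test(network: GeneNetwork, gene_set, hub: str, universe,
                        min_score: int = MIN_SCORE) -> dict:
    """Are the hub's network connections over-represented in the gene set?

    The 2x2 table classifies every gene of the universe (hub excluded) by
    gene-set membership and by connection to the hub in the full
    high-confidence network; the one-sided Fisher exact test asks whether
    set members are connected to the hub more often than chance.
    """
    universe = set(universe)
    if hub not in universe:
        raise ValueError(f"hub {hub!r} not in the universe")
    universe = universe - {hub}
    members = set(gene_set) & universe
    g = network.graph(min_score)
    connected = (set(g.neighbors(hub)) if hub in g else set()) & universe
    a = len(members & connected)
    b = len(members - connected)
    c = len(connected - members)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p, degenerate = _fisher_greater(table)
    return {"hub": hub, "table": table, "p_value": p, "degenerate": degenerate}


def hub_connection_tests(network: GeneNetwork, gene_set, hubs, universe,
                         min_score: int = MIN_SCORE) -> pd.DataFrame:
    """Fisher test per hub with Benjamini-Hochberg adjustment across hubs."""
    res = [hub_connection_test(network, gene_set, h, universe, min_score) for h in hubs]
    df = pd.DataFrame({"hub": [r["hub"] for r in res],
                       "p_value": [r["p_value"] for r in res],
                       "degenerate": [r["degenerate"] for r in res]})
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def substrate_enrichment(connections, substrates, universe) -> dict:
    """Over-representation of a kinase's known/predicted substrates among its
    network connections (one-sided Fisher exact)."""
    universe = set(universe)
    conn = set(connections) & universe
    subs = set(substrates) & universe
    if not conn:
        return {"table": np.zeros((2, 2), dtype=int), "p_value": 1.0, "degenerate": True}
    a = len(conn & subs)
    b = len(conn - subs)
    c = len(subs - conn)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p, degenerate = _fisher_greater(table)
    return {"table": table, "p_value": p, "degenerate": degenerate}
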