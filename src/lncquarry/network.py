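"""lncRNA–mRNA interaction network, cohesive-module detection, empirical
module significance, and hypergeometric gene-set enrichment.

Module detection re-implements the ClusterONE objective: greedy growth of
a seed node set V maximizing the cohesiveness
``f(V) = w_in / (w_in + w_bound + p * |V|)`` (w_in: total edge weight
inside V, w_bound: weight crossing the boundary, p: per-node penalty),
followed by a size filter and merging of heavily overlapping groups.
Significance is assessed against a degree-preserving edge-rewiring null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import TargetAssignment
from .models import GeneSet

logger = logging.getLogger(__name__)

KIND_LNCRNA = "lncRNA"
KIND_MRNA = "mRNA"


def build_network(ppi_edges: list[tuple[str, str, float]],
                  target_assignments: list[TargetAssignment],
                  ) -> nx.Graph:
    """Union graph of mRNA–mRNA PPI edges and lncRNA–mRNA target edges.

    Duplicate edges collapse keeping the maximum weight; self-loops are
    dropped with a warning.  Node kinds are inferred: assignment lncRNA
    ids are ``lncRNA``, everything else ``mRNA``.
    """
    g = nx.Graph()

    def add_edge(a: str, b: str, w: float) -> None:
        if a == b:
            logger.warning("self-loop on %s dropped", a)
            return
        if w <= 0:
            raise ValueError(f"edge {a}-{b} has non-positive weight {w}")
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)

    for a, b, w in ppi_edges:
        add_edge(a, b, w)
    for t in target_assignments:
        add_edge(t.lnc_id, t.gene_id, 1.0)
    lnc_ids = {t.lnc_id for t in target_assignments}
    for node in g.nodes:
        g.nodes[node]["kind"] = KIND_LNCRNA if node in lnc_ids else KIND_MRNA
    return g


def cohesiveness(graph: nx.Graph, node_set, penalty: float = 2.0) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty * |V|); 0 for an isolated
    set with zero penalty."""
    nodes = set(node_set)
    if not nodes:
        raise ValueError("node set must be non-empty")
    missing = nodes - set(graph.nodes)
    if missing:
        raise ValueError(f"nodes not in network: {sorted(missing)}")
    w_in = 0.0
    w_bound = 0.0
    for u in nodes:
        for v, data in graph[u].items():
            if v in nodes:
                if u < v:
                    w_in += data["weight"]
            else:
                w_bound += data["weight"]
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


@dataclass
class Module:
    nodes: frozenset[str]
    cohesiveness: float
    p_value: float | None = None


def _grow_from_seed(graph: nx.Graph, seed: str, penalty: float,
                    tol: float = 1e-12) -> set[str]:
    current = {seed}
    f = cohesiveness(graph, current, penalty)
    while True:
        candidates = []
        boundary = {v for u in current for v in graph[u] if v not in current}
        for v in sorted(boundary):
            candidates.append(("add", v))
        if len(current) > 1:
            for v in sorted(current):
                candidates.append(("remove", v))
        # best improving single step: highest f, then add before remove,
        # then lexicographically smallest node
        best = None   # (f, action_rank, node, action)
        for action, v in candidates:
            trial = current | {v} if action == "add" else current - {v}
            ft = cohesiveness(graph, trial, penalty)
            if ft <= f + tol:
                continue
            key = (-ft, 0 if action == "add" else 1, v)
            if best is None or key < best[0]:
                best = (key, v, action, ft)
        if best is None:
            return current
        _, v, action, ft = best
        current = current | {v} if action == "add" else current - {v}
        f = ft


def overlap_score(a: frozenset, b: frozenset) -> float:
    """ClusterONE overlap score omega(A,B) = |A n B|^2 / (|A| * |B|)."""
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def detect_modules(graph: nx.Graph, min_size: int = 5, penalty: float = 2.0,
                   overlap_merge: float = 0.8) -> list[Module]:
    """Greedy cohesiveness growth from unvisited highest-degree seeds,
    size-filtered, with omega >= ``overlap_merge`` merging.

    Deterministic: ties (seed order, growth steps) break on
    lexicographic node id.
    """
    if graph.number_of_nodes() == 0:
        return []
    visited: set[str] = set()
    raw: list[frozenset[str]] = []
    seeds = sorted(graph.nodes, key=lambda n: (-graph.degree(n, weight="weight"), n))
    for seed in seeds:
        if seed in visited:
            continue
        grown = _grow_from_seed(graph, seed, penalty)
        visited |= grown
        if len(grown) >= min_size:
            fs = frozenset(grown)
            if fs not in raw:
                raw.append(fs)
    # merge heavily overlapping groups (union–find on omega >= cutoff)
    merged = True
    groups = list(raw)
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if overlap_score(groups[i], groups[j]) >= overlap_merge:
                    union = groups[i] | groups[j]
                    groups = [g for k, g in enumerate(groups)
                              if k not in (i, j)] + [union]
                    merged = True
                    break
            if merged:
                break
    modules = [Module(g, cohesiveness(graph, g, penalty)) for g in groups]
    modules.sort(key=lambda m: (-m.cohesiveness, sorted(m.nodes)))
    return modules


def _rewired_adjacency(edges: list[tuple[str, str]], weights: np.ndarray,
                       rng: np.random.Generator,
                       n_swaps: int) -> dict[str, dict[str, float]]:
    """Degree-preserving double-edge swaps on an edge list; weights are
    randomly permuted over the rewired edges."""
    edges = [list(e) for e in edges]
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    done = 0
    tries = 0
    max_tries = 100 * n_swaps + 100
    while done < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if rng.integers(0, 2):
            c, d = d, c
        # propose a-d, c-b
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset(edges[j]))
        edges[i] = [a, d]
        edges[j] = [c, b]
        edge_set.add(e1)
        edge_set.add(e2)
        done += 1
    perm = rng.permutation(m)
    adj: dict[str, dict[str, float]] = {}
    for idx, (u, v) in enumerate(edges):
        w = float(weights[perm[idx]])
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    return adj


def _cohesiveness_adj(adj: dict[str, dict[str, float]], nodes: set[str],
                      penalty: float) -> float:
    w_in = 0.0
    w_bound = 0.0
    for u in nodes:
        for v, w in adj.get(u, {}).items():
            if v in nodes:
                if u < v:
                    w_in += w
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def module_significance(graph: nx.Graph, module_nodes, n_null: int = 1000,
                        seed: int | None = None,
                        penalty: float = 2.0) -> float:
    """Empirical p-value of a module's cohesiveness under a
    degree-preserving rewiring null: p = (1 + #{f_null >= f_obs}) /
    (n_null + 1)."""
    nodes = set(module_nodes)
    missing = nodes - set(graph.nodes)
    if missing:
        raise ValueError(f"module nodes not in network: {sorted(missing)}")
    f_obs = cohesiveness(graph, nodes, penalty)
    edges = [(u, v) for u, v in graph.edges]
    weights = np.array([graph[u][v]["weight"] for u, v in edges])
    rng = np.random.default_rng(seed)
    n_swaps = 10 * len(edges)
    exceed = 0
    for _ in range(n_null):
        adj = _rewired_adjacency(edges, weights, rng, n_swaps)
        if _cohesiveness_adj(adj, nodes, penalty) >= f_obs:
            exceed += 1
    return (1 + exceed) / (n_null + 1)


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    q_value: float
    significant: bool


def enrich(query_genes, gene_sets: list[GeneSet], background,
           q_threshold: float = 0.1) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail enrichment of ``query_genes``
    in each set, BH-adjusted; significant at q < ``q_threshold``.

    Gene sets are intersected with the background; the query must be a
    subset of the background.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    query = set(query_genes)
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)}")
    n_bg = len(background)
    n_query = len(query)
    rows = []
    for gs in gene_sets:
        members = gs.members & background
        k = len(query & members)
        big_k = len(members)
        # P(X >= k) under Hypergeom(N, K, n); sf(k-1) is the upper tail
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_query))
        rows.append({"set_id": gs.set_id, "description": gs.description,
                     "overlap": k, "set_size": big_k,
                     "query_size": n_query, "background_size": n_bg,
                     "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        df["q_value"] = []
        df["significant"] = []
        return df
    _rej, q, _, _ = multipletests(df["p_value"].values, method="fdr_bh")
    df["q_value"] = q
    df["significant"] = q < q_threshold
    return df.sort_values(["q_value", "p_value", "set_id"],
                          ignore_index=True)
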