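"""Co-occurrence network construction and module detection.

Edges are pairwise Spearman correlations between taxa across samples,
retained when |rho| >= rho_min (default 0.8) AND the BH-adjusted two-sided
p-value <= p_max (default 0.01).  Modules (ecological clusters) are found by
running greedy modularity agglomeration, Louvain, and fast label propagation
on the unweighted, sign-agnostic edge skeleton and keeping the partition
with the highest Newman-Girvan modularity Q; module IDs are relabeled
0, 1, 2, ... by decreasing module size.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community_stats import bh_adjust
from .tables_io import AbundanceTable, TableError

ALGORITHMS = ("greedy", "louvain", "label_propagation")


@dataclass
class CooccurrenceNetwork:
    """Undirected signed-correlation graph of taxa with a module partition.

    ``graph`` nodes carry ``domain`` and ``excluded`` (constant-taxon)
    attributes; edges carry ``rho``, ``p_raw``, ``p_adj`` and ``sign``.
    ``partition`` maps every node to a module id once modules are detected.
    """

    graph: nx.Graph
    partition: dict | None = None
    modularity: float | None = None
    algorithm_q: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def module_members(self) -> dict:
        if self.partition is None:
            raise TableError("partition not computed; run detect_modules")
        out: dict = {}
        for node, mod in self.partition.items():
            out.setdefault(mod, []).append(node)
        return out


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    avg_clustering: float
    density: float
    modularity: float
    n_large_modules: int
    frac_nodes_in_large_modules: float


def _spearman_matrix(X: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    return rho


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t-distribution approximation (n-2 df)."""
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


def _exact_perm_p(xr: np.ndarray, yr: np.ndarray) -> float:
    """Exact permutation p for Spearman rho on ranked vectors (small n)."""
    n = xr.size
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 1.0
    r_obs = abs(float(xc @ yc) / denom)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(float(xc @ yc[list(perm)]) / denom)
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


def build_network(t: AbundanceTable, rho_min: float = 0.8,
                  p_max: float = 0.01, fdr: str = "bh",
                  method: str = "spearman", seed: int = 0) -> CooccurrenceNetwork:
    """Correlation network over the taxa of an (already filtered) table.

    Constant (zero-variance) taxa are excluded from testing with a warning
    and can never be an edge endpoint; they remain in the node set flagged
    ``excluded``.  Spearman p-values use the t approximation for n >= 10
    samples and exact permutation enumeration below that.  BH adjustment is
    applied once over all tested pairs (``fdr='none'`` uses raw p).
    """
    if t.n_samples < 4:
        raise TableError("need at least 4 samples to test correlations")
    ra = t.relative_abundance()
    X = ra.to_numpy()
    taxa = t.taxa_ids
    n = t.n_samples

    variable = ~np.all(X == X[:, :1], axis=1)  # exact constant rows
    if not variable.all():
        warnings.warn(
            f"{int((~variable).sum())} constant taxa excluded from "
            "correlation testing"
        )
    idx = np.flatnonzero(variable)

    G = nx.Graph()
    for i, taxon in enumerate(taxa):
        G.add_node(taxon, domain=str(t.domain_of.iloc[i]),
                   excluded=bool(not variable[i]))

    if idx.size >= 2:
        Xv = X[idx]
        if method == "spearman":
            ranks = np.apply_along_axis(stats.rankdata, 1, Xv)
        elif method == "pearson":
            ranks = Xv
        else:
            raise ValueError(f"unknown method {method!r}")
        rho = np.corrcoef(ranks)
        iu = np.triu_indices(idx.size, k=1)
        rho_flat = rho[iu]
        if n >= 10 or method == "pearson":
            p_flat = _t_approx_p(rho_flat, n)
        else:
            p_flat = np.array([
                _exact_perm_p(ranks[a], ranks[b])
                for a, b in zip(*iu)
            ])
        if fdr == "bh":
            p_adj = bh_adjust(p_flat)
        elif fdr == "none":
            p_adj = p_flat.copy()
        else:
            raise ValueError(f"unknown fdr mode {fdr!r}")
        keep = (np.abs(rho_flat) >= rho_min) & (p_adj <= p_max)
        for k in np.flatnonzero(keep):
            a, b = iu[0][k], iu[1][k]
            G.add_edge(taxa[idx[a]], taxa[idx[b]],
                       rho=float(rho_flat[k]), p_raw=float(p_flat[k]),
                       p_adj=float(p_adj[k]),
                       sign=1 if rho_flat[k] > 0 else -1)

    return CooccurrenceNetwork(
        graph=G,
        params={"rho_min": rho_min, "p_max": p_max, "fdr": fdr,
                "method": method, "seed": seed},
    )


def detect_modules(net: CooccurrenceNetwork,
                   algorithms=ALGORITHMS, seed: int = 0,
                   weighted: bool = False) -> CooccurrenceNetwork:
    """Fill ``net.partition`` with the best-of-several-algorithms modules.

    Runs each requested algorithm on the (by default) unweighted skeleton,
    scores each partition by Newman-Girvan modularity, and keeps the one with
    the highest Q (ties broken in fixed algorithm order).  An edgeless
    network gets singleton modules and Q = 0.  ``weighted=True`` uses |rho|
    as edge weight for both detection and Q.
    """
    G = net.graph
    weight = None
    if weighted:
        G = G.copy()
        for u, v, d in G.edges(data=True):
            d["absrho"] = abs(d.get("rho", 1.0))
        weight = "absrho"

    if G.number_of_edges() == 0:
        net.partition = {node: i for i, node in enumerate(G.nodes)}
        net.modularity = 0.0
        net.algorithm_q = {}
        return net

    candidates: list[tuple[str, list, float]] = []
    for algo in algorithms:
        if algo == "greedy":
            comms = nx.community.greedy_modularity_communities(G, weight=weight)
        elif algo == "louvain":
            comms = nx.community.louvain_communities(G, weight=weight, seed=seed)
        elif algo == "label_propagation":
            comms = nx.community.fast_label_propagation_communities(
                G, weight=weight, seed=seed)
        else:
            raise ValueError(f"unknown algorithm {algo!r}")
        comms = [set(c) for c in comms]
        q = nx.community.modularity(G, comms, weight=weight)
        candidates.append((algo, comms, q))

    best_algo, best_comms, best_q = max(
        candidates, key=lambda x: (x[2], -list(algorithms).index(x[0])))
    # relabel modules by decreasing size (module 0 = largest)
    order = sorted(range(len(best_comms)),
                   key=lambda i: (-len(best_comms[i]), sorted(map(str, best_comms[i]))))
    partition = {}
    for new_id, old_id in enumerate(order):
        for node in best_comms[old_id]:
            partition[node] = new_id
    net.partition = partition
    net.modularity = float(best_q)
    net.algorithm_q = {algo: float(q) for algo, _, q in candidates}
    net.params["module_algorithm"] = best_algo
    return net


def summarize_network(net: CooccurrenceNetwork) -> NetworkSummary:
    """Topology summary; requires a partition for the module statistics."""
    if net.partition is None:
        raise TableError("partition not computed; run detect_modules")
    G = net.graph
    n = G.number_of_nodes()
    e = G.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in G.edges(data=True)]
    sizes = pd.Series(list(net.partition.values())).value_counts()
    large = sizes[sizes >= 5]
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        n_positive=int(sum(s > 0 for s in signs)),
        n_negative=int(sum(s < 0 for s in signs)),
        avg_clustering=float(nx.average_clustering(G)) if n else 0.0,
        density=float(nx.density(G)) if n > 1 else 0.0,
        modularity=float(net.modularity),
        n_large_modules=int(len(large)),
        frac_nodes_in_large_modules=float(large.sum() / n) if n else 0.0,
    )


# -- serialization ---------------------------------------------------------


def edge_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Gephi-compatible edge list (source, target, sign, rho, p_adj)."""
    rows = [
        {"source": u, "target": v, "sign": d.get("sign", 1),
         "rho": d.get("rho", np.nan), "p_adj": d.get("p_adj", np.nan)}
        for u, v, d in net.graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "sign", "rho", "p_adj"])


def write_network(net: CooccurrenceNetwork, path) -> None:
    """GraphML (node/edge attributes included) plus an edge-list TSV."""
    path = Path(path)
    G = net.graph.copy()
    if net.partition is not None:
        nx.set_node_attributes(G, net.partition, "module")
        deg = dict(G.degree())
        nx.set_node_attributes(G, deg, "degree")
    nx.write_graphml(G, path.with_suffix(".graphml"))
    edge_table(net).to_csv(path.with_suffix(".edges.tsv"), sep="\t", index=False)
    meta = {"modularity": net.modularity, "algorithm_q": net.algorithm_q,
            "params": net.params}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
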