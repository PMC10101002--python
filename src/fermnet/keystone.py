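"""Topological node roles: within/among-module connectivity (Zi / Pi).

Following the Guimera-Amaral convention, Zi is the z-score of a node's
within-module degree relative to its module's within-degree distribution
(population standard deviation), and Pi is the participation coefficient
1 - sum_s (k_is / k_i)^2 over modules s.  Roles:

    network hub   Zi >= 2.5 and Pi >= 0.62
    module hub    Zi >= 2.5 and Pi <  0.62
    connector     Zi <  2.5 and Pi >= 0.62
    peripheral    otherwise

Network hubs, module hubs and connectors together constitute the keystone
taxa.  Both boundaries are inclusive.  Degenerate modules (size 1 or zero
within-degree variance) give Zi = 0 so that every node is classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import CooccurrenceNetwork
from .tables_io import TableError

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLES = ("network_hub", "module_hub", "connector", "peripheral")


def _role(zi: float, pi: float) -> str:
    if zi >= ZI_THRESHOLD and pi >= PI_THRESHOLD:
        return "network_hub"
    if zi >= ZI_THRESHOLD:
        return "module_hub"
    if pi >= PI_THRESHOLD:
        return "connector"
    return "peripheral"


def zi_pi(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Per-node Zi, Pi, role, degree and closeness centrality.

    Degree counts both positive and negative edges.  Pi is 0 for isolated
    nodes.  Every node must appear in the partition.
    """
    if net.partition is None:
        raise TableError("partition not computed; run detect_modules")
    G = net.graph
    missing = [v for v in G.nodes if v not in net.partition]
    if missing:
        raise TableError(f"nodes absent from partition: {missing[:5]}")

    part = net.partition
    # within-module degree per node
    within = {}
    k_per_module = {}
    for v in G.nodes:
        counts: dict = {}
        for u in G.neighbors(v):
            counts[part[u]] = counts.get(part[u], 0) + 1
        k_per_module[v] = counts
        within[v] = counts.get(part[v], 0)
        assert sum(counts.values()) == G.degree(v)

    # module-wise mean / population sd of within-degree
    module_nodes: dict = {}
    for v, m in part.items():
        module_nodes.setdefault(m, []).append(v)
    mod_stats = {}
    for m, nodes in module_nodes.items():
        w = np.array([within[v] for v in nodes], dtype=float)
        mod_stats[m] = (w.mean(), w.std())  # population denominator

    closeness = nx.closeness_centrality(G)
    rows = []
    for v in G.nodes:
        k = G.degree(v)
        mu, sd = mod_stats[part[v]]
        zi = 0.0 if (sd == 0 or len(module_nodes[part[v]]) == 1) \
            else (within[v] - mu) / sd
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((ks / k) ** 2 for ks in k_per_module[v].values())
        rows.append({
            "taxon_id": v,
            "domain": G.nodes[v].get("domain", ""),
            "module": part[v],
            "degree": k,
            "zi": float(zi),
            "pi": float(pi),
            "role": _role(zi, pi),
            "closeness": float(closeness[v]),
        })
    return pd.DataFrame(rows).set_index("taxon_id")


@dataclass
class KeystoneSet:
    taxa: list
    connectors: list
    role_counts: dict


def keystone_set(roles: pd.DataFrame) -> KeystoneSet:
    """Keystone taxa = union of network hubs, module hubs and connectors."""
    counts = {r: int((roles["role"] == r).sum()) for r in ROLES}
    keystone = roles.index[roles["role"].isin(
        ("network_hub", "module_hub", "connector"))].tolist()
    connectors = roles.index[roles["role"] == "connector"].tolist()
    return KeystoneSet(taxa=keystone, connectors=connectors,
                       role_counts=counts)


def node_role_table(net: CooccurrenceNetwork,
                    mean_ra: pd.Series | None = None) -> pd.DataFrame:
    """Role table with optional mean relative abundance column for export."""
    roles = zi_pi(net)
    if mean_ra is not None:
        roles["mean_ra"] = mean_ra.reindex(roles.index)
    return roles
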