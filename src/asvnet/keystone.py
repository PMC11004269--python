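"""Module detection, Zi-Pi node cartography and keystone-taxon summaries.

Nodes are classified by their within-module degree z-score (Zi) and
participation coefficient (Pi) against the thresholds (2.5, 0.62):
module hubs (Zi > 2.5), connectors (Pi > 0.62), network hubs (both) and
peripherals (neither).  Non-peripheral taxa are treated as keystone
candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm

logger = logging.getLogger("asvnet")

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class ModuleAssignment:
    membership: dict  # node -> module id (int)
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))


def detect_modules(net: nx.Graph, method: str = "greedy", seed: int | None = 0) -> ModuleAssignment:
    """Partition the network into modules by modularity maximization.

    ``greedy`` (default) is the deterministic agglomerative CNM heuristic
    with lexicographic node order; ``louvain`` is the seeded Louvain
    algorithm.  Module ids are renumbered by each module's lexicographically
    smallest member so ids are stable across runs.
    """
    if net.number_of_edges() == 0:
        raise ValueError("module detection needs at least one edge")
    h = nx.Graph()
    h.add_nodes_from(sorted(net.nodes))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in net.edges))
    if method == "greedy":
        comms = nx_comm.greedy_modularity_communities(h)
    elif method == "louvain":
        comms = nx_comm.louvain_communities(h, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}; use 'greedy' or 'louvain'")
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    membership = {node: k for k, comm in enumerate(comms) for node in comm}
    q = nx_comm.modularity(h, [set(c) for c in comms])
    logger.info("detect_modules(%s): %d modules, Q=%.4f", method, len(comms), q)
    return ModuleAssignment(membership, float(q))


def zi_pi(net: nx.Graph, modules: ModuleAssignment) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's link count into its own module over that
    module's members (0 when the module has < 2 members or zero spread);
    Pi = 1 - sum_m (k_im / k_i)^2 over modules m, with Pi = 0 for isolated
    nodes.  Edge signs are ignored.
    """
    mem = modules.membership
    missing = [n for n in net.nodes if n not in mem]
    if missing:
        raise ValueError(f"module assignment does not cover nodes: {missing[:5]}")
    nodes = list(net.nodes)
    mod_ids = sorted(set(mem.values()))
    mod_index = {m: j for j, m in enumerate(mod_ids)}

    # k_im: links of node i into module m
    k_im = {n: np.zeros(len(mod_ids)) for n in nodes}
    for u, v in net.edges:
        k_im[u][mod_index[mem[v]]] += 1
        k_im[v][mod_index[mem[u]]] += 1

    within = {n: k_im[n][mod_index[mem[n]]] for n in nodes}
    zi = {}
    for m in mod_ids:
        members = [n for n in nodes if mem[n] == m]
        w = np.array([within[n] for n in members])
        sd = w.std()
        if len(members) < 2 or sd == 0:
            for n in members:
                zi[n] = 0.0
        else:
            mu = w.mean()
            for n, wi in zip(members, w):
                zi[n] = float((wi - mu) / sd)

    pi = {}
    for n in nodes:
        k = k_im[n].sum()
        if k == 0:
            logger.warning("zi_pi: node %r has degree 0; Pi set to 0", n)
            pi[n] = 0.0
        else:
            pi[n] = float(1.0 - np.sum((k_im[n] / k) ** 2))

    out = pd.DataFrame(
        {
            "module": [mem[n] for n in nodes],
            "degree": [int(k_im[n].sum()) for n in nodes],
            "zi": [zi[n] for n in nodes],
            "pi": [pi[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return out


def classify_nodes(
    roles: pd.DataFrame,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Assign each node a cartographic role from its (Zi, Pi).

    network_hub: Zi > threshold and Pi > threshold; module_hub: only Zi;
    connector: only Pi; peripheral otherwise.  Thresholds are strict, so
    boundary values fall to peripheral.
    """
    out = roles.copy()
    hi_z = out["zi"] > zi_threshold
    hi_p = out["pi"] > pi_threshold
    role = np.where(
        hi_z & hi_p,
        "network_hub",
        np.where(hi_z, "module_hub", np.where(hi_p, "connector", "peripheral")),
    )
    out["role"] = role
    return out


def keystone_abundance(
    roles: pd.DataFrame,
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    rank: str = "phylum",
    keystone_roles: tuple = ("module_hub", "network_hub", "connector"),
) -> pd.DataFrame:
    """Per-treatment relative abundance of keystone taxa grouped at a rank.

    Keystone = nodes whose role is in ``keystone_roles`` (all non-peripheral
    roles by default; pass ("module_hub", "network_hub") to restrict to
    hubs).  Denominator is each treatment's total reads over all taxa, so the
    column sums equal the treatment's total keystone proportion.
    """
    if "role" not in roles.columns:
        raise ValueError("call classify_nodes first (no 'role' column)")
    keys = roles.index[roles["role"].isin(keystone_roles)]
    missing = [t for t in keys if t not in taxonomy.index]
    if missing:
        raise ValueError(f"keystone taxa missing from taxonomy: {missing[:5]}")
    treatments = metadata.loc[table.columns, "treatment"]
    out = {}
    for treat in pd.unique(treatments):
        cols = table.columns[treatments == treat]
        total = float(table[cols].to_numpy().sum())
        sub = table.loc[table.index.isin(keys), cols]
        if sub.empty:
            out[treat] = pd.Series(dtype=float)
        else:
            grouped = sub.sum(axis=1).groupby(taxonomy.loc[sub.index, rank]).sum()
            out[treat] = grouped / total
    result = pd.DataFrame(out).fillna(0.0)
    result.index.name = rank
    return result


def node_role_table(
    net: nx.Graph,
    roles: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Node attribute table (domain, module, zi, pi, role) for export."""
    out = roles.copy()
    if taxonomy is not None:
        out.insert(0, "domain", taxonomy.loc[out.index, "domain"].to_numpy())
    else:
        domains = nx.get_node_attributes(net, "domain")
        out.insert(0, "domain", [domains.get(n, "") for n in out.index])
    return out


def annotate_network(net: nx.Graph, roles: pd.DataFrame) -> nx.Graph:
    """Attach module/zi/pi/role node attributes (for GraphML re-export)."""
    g = net.copy()
    for col in ("module", "zi", "pi", "role"):
        if col in roles.columns:
            nx.set_node_attributes(g, roles[col].to_dict(), col)
    return g
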