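"""Network topology panel and spectral stability measures.

The topology panel mirrors the standard co-occurrence-network report: edge
and node counts split by sign and domain, edge density, average degree,
average shortest-path length, and Freeman centralizations.  Stability is
quantified by natural connectivity — ln of the average of e^lambda over the
adjacency eigenvalues, a measure of closed-walk redundancy — and by
robustness, the ratio of natural connectivity after random removal of a
fixed fraction of nodes to that of the intact network.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx
import numpy as np
from scipy.linalg import eigvalsh
from scipy.special import logsumexp


@dataclass
class TopologyMetrics:
    edges: int
    num_pos_edges: int
    num_neg_edges: int
    positive_pct: float
    nodes: int
    bacteria_nodes: int
    fungus_nodes: int
    edge_density: float
    average_degree: float
    average_path_length: float
    degree_centralization: float
    betweenness_centralization: float
    closeness_centralization: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class StabilityResult:
    natural_connectivity_full: float
    robustness_mean: float
    robustness_se: float
    n_reps: int
    decay_curve: list[tuple[int, float]]


def topology_identities(edges: int, nodes: int, pos_edges: int) -> dict:
    """Arithmetic identities tying a network's raw counts to its ratio
    metrics: average degree 2E/N, edge density 2E/(N(N-1)), and the positive
    share 100*pos/E."""
    if nodes < 2 or edges < 0:
        raise ValueError("need nodes >= 2 and edges >= 0")
    return {
        "average_degree": 2.0 * edges / nodes,
        "edge_density": 2.0 * edges / (nodes * (nodes - 1)),
        "positive_pct": 100.0 * pos_edges / edges if edges else 0.0,
    }


def _average_path_length(g: nx.Graph) -> float:
    """Mean shortest-path length over connected pairs (components weighted by
    their pair counts); 0 when no connected pair exists."""
    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        c = len(comp)
        if c < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += c * (c - 1)
    return total / pairs if pairs else 0.0


def _closeness(g: nx.Graph) -> dict:
    """Per-node closeness within its own component: (c-1)/sum(d); 0 for
    isolated nodes."""
    out: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for n in comp:
            if len(comp) < 2:
                out[n] = 0.0
            else:
                out[n] = (len(comp) - 1) / sum(
                    nx.single_source_shortest_path_length(sub, n).values()
                )
    return out


def topology_summary(net: nx.Graph) -> TopologyMetrics:
    """Compute the full topology panel for one signed network.

    Edge signs default to '+' when absent; nodes without a ``domain``
    attribute are counted as bacteria.  Centralizations use Freeman's
    formulas with the undirected-graph maxima (see docs/methods.md).
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = net.number_of_edges()
    pos = sum(1 for *_, d in net.edges(data=True) if d.get("sign", "+") == "+")
    neg = e - pos
    domains = nx.get_node_attributes(net, "domain")
    fungi = sum(1 for v in net.nodes if domains.get(v, "bacteria") == "fungi")

    degrees = np.array([d for _, d in net.degree()], dtype=float)
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0

    if n > 2:
        deg_cent = float(np.sum(degrees.max() - degrees)) / ((n - 1) * (n - 2))
        btw = np.array(list(nx.betweenness_centrality(net, normalized=False).values()))
        btw_cent = float(np.sum(btw.max() - btw)) / ((n - 1) ** 2 * (n - 2) / 2.0)
        clo = np.array(list(_closeness(net).values()))
        clo_cent = float(np.sum(clo.max() - clo)) / ((n - 1) * (n - 2) / (2.0 * n - 3.0))
    else:
        deg_cent = btw_cent = clo_cent = 0.0

    return TopologyMetrics(
        edges=e,
        num_pos_edges=pos,
        num_neg_edges=neg,
        positive_pct=100.0 * pos / e if e else 0.0,
        nodes=n,
        bacteria_nodes=n - fungi,
        fungus_nodes=fungi,
        edge_density=density,
        average_degree=2.0 * e / n,
        average_path_length=_average_path_length(net),
        degree_centralization=deg_cent,
        betweenness_centralization=btw_cent,
        closeness_centralization=clo_cent,
    )


def natural_connectivity(net: nx.Graph) -> float:
    """ln((1/N) sum_i e^{lambda_i}) over eigenvalues of the unsigned,
    unweighted adjacency matrix; 0 for an edgeless graph."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for an empty graph")
    if net.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(net, weight=None)
    lam = eigvalsh(a)
    return float(logsumexp(lam) - np.log(n))


def robustness(
    net: nx.Graph,
    fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = None,
) -> StabilityResult:
    """Stability under random node removal.

    Each replicate removes ``floor(fraction * N)`` uniformly chosen nodes and
    records the ratio of the induced subgraph's natural connectivity to the
    intact network's; the mean and standard error over replicates are
    returned.  ``fraction=0`` is the degenerate no-removal mode (ratio 1).
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    nodes = list(net.nodes)
    n = len(nodes)
    k = int(np.floor(fraction * n))
    if n - k < 1:
        raise ValueError("removal would leave no nodes")
    full = natural_connectivity(net)
    if full == 0.0:
        raise ValueError("natural connectivity of the intact network is 0; ratio undefined")
    if k == 0:
        return StabilityResult(full, 1.0, 0.0, n_reps, [(0, full)])
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_reps)
    for r in range(n_reps):
        removed = set(rng.choice(n, size=k, replace=False).tolist())
        keep = [nodes[i] for i in range(n) if i not in removed]
        ratios[r] = natural_connectivity(net.subgraph(keep)) / full
    se = float(ratios.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
    return StabilityResult(full, float(ratios.mean()), se, n_reps, [(0, full)])


def connectivity_decay_curve(
    net: nx.Graph,
    step: int = 10,
    n_reps: int = 30,
    seed: int | None = None,
    max_removed: int | None = None,
) -> list[tuple[int, float]]:
    """Mean natural connectivity after removing 0, step, 2*step, ... nodes in
    random order (n_reps independent orders); the first point is the intact
    value."""
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    nodes = list(net.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    limit = n - 1 if max_removed is None else min(max_removed, n - 1)
    removal_counts = list(range(0, limit + 1, step))
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(removal_counts))
    for _ in range(n_reps):
        order = rng.permutation(n)
        for j, r in enumerate(removal_counts):
            keep = [nodes[i] for i in order[r:]]
            acc[j] += natural_connectivity(net.subgraph(keep)) if keep else 0.0
    acc /= n_reps
    return list(zip(removal_counts, acc.tolist()))
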