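"""Co-occurrence network construction: abundance/prevalence filtering,
Spearman edge inference with an |rho|^2 threshold, and the signed graph.

The screen keeps taxa whose overall relative abundance exceeds 0.1 % of all
reads and which occur in more than 60 % of samples; edges join taxa whose
Spearman rank correlation across samples satisfies rho^2 > 0.9 at p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignError

logger = logging.getLogger("asvnet")


@dataclass
class FilterConfig:
    """Abundance/prevalence screen ahead of network inference.

    ``total-proportion`` mode retains taxa whose grand-total relative
    abundance exceeds ``abundance_threshold`` (default 0.1 % of all reads);
    ``top-fraction`` mode instead keeps the top ``ceil(fraction * T)`` taxa
    ranked by total reads.  Both then require presence (count > 0) in strictly
    more than ``prevalence_threshold`` of samples.
    """

    abundance_threshold: float = 0.001
    prevalence_threshold: float = 0.60
    abundance_mode: str = "total-proportion"

    def validate(self) -> None:
        for name in ("abundance_threshold", "prevalence_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DesignError(f"{name} must be in (0, 1), got {v}")
        if self.abundance_mode not in ("total-proportion", "top-fraction"):
            raise DesignError(
                f"abundance_mode must be 'total-proportion' or 'top-fraction', "
                f"got {self.abundance_mode!r}"
            )


@dataclass
class EdgeRecord:
    """One retained co-occurrence edge."""

    taxon_a: str
    taxon_b: str
    rho: float
    p: float
    sign: str = field(init=False)

    def __post_init__(self):
        self.sign = "+" if self.rho >= 0 else "-"


def filter_taxa(table: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the abundance + prevalence screen; original row order is kept."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    if table.empty:
        raise ValueError("empty count table")
    totals = table.sum(axis=1)
    grand = totals.sum()
    if cfg.abundance_mode == "total-proportion":
        abundant = (totals / grand) > cfg.abundance_threshold
    else:
        k = int(np.ceil(cfg.abundance_threshold * len(table)))
        top = totals.sort_values(ascending=False, kind="stable").index[:k]
        abundant = table.index.isin(top)
    prevalence = (table > 0).mean(axis=1)
    keep = abundant & (prevalence > cfg.prevalence_threshold)
    out = table.loc[keep]
    logger.info("filter_taxa: retained %d of %d taxa", len(out), len(table))
    return out


def spearman_edges(
    table: pd.DataFrame,
    rho2_threshold: float = 0.9,
    alpha: float = 0.05,
    correction: str = "none",
    min_samples: int = 5,
) -> list[EdgeRecord]:
    """Test all unordered taxon pairs for Spearman association.

    An edge is retained iff rho^2 > ``rho2_threshold`` and its (optionally
    Benjamini-Hochberg-corrected) two-sided p-value from the t-distribution
    approximation is < ``alpha``.  Taxa constant across samples are excluded
    with a warning (rho undefined).
    """
    if correction not in ("none", "BH"):
        raise ValueError(f"correction must be 'none' or 'BH', got {correction!r}")
    n = table.shape[1]
    if n < min_samples:
        raise ValueError(
            f"Spearman p-values are unreliable below {min_samples} samples; got {n}"
        )
    x = table.to_numpy(dtype=float)
    const = x.std(axis=1) == 0
    if const.any():
        logger.warning(
            "spearman_edges: excluding %d constant taxa (rho undefined): %s",
            const.sum(),
            list(table.index[const][:5]),
        )
    sub = table.loc[~const]
    t_ids = list(sub.index)
    m = len(t_ids)
    if m < 2:
        return []
    rho, _ = stats.spearmanr(sub.to_numpy(dtype=float), axis=1)
    if m == 2:  # scipy returns a scalar for exactly two variables
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    # two-sided p via the t-approximation on n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.clip(rho, -1.0, 1.0)
        t = rr * np.sqrt((n - 2) / np.clip(1.0 - rr * rr, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rr) == 1.0] = 0.0

    iu = np.triu_indices(m, k=1)
    rhos, ps = rho[iu], p[iu]
    logger.info("spearman_edges: tested %d taxon pairs", len(rhos))
    if correction == "BH":
        ps = stats.false_discovery_control(ps, method="bh")
    keep = (rhos * rhos > rho2_threshold) & (ps < alpha)
    return [
        EdgeRecord(t_ids[i], t_ids[j], float(r), float(pv))
        for i, j, r, pv in zip(iu[0][keep], iu[1][keep], rhos[keep], ps[keep])
    ]


def build_network(
    edges: list[EdgeRecord],
    taxonomy: pd.DataFrame,
    include_isolated: bool = False,
    retained_taxa=None,
) -> nx.Graph:
    """Assemble the signed undirected network; every node gets its domain
    label from the taxonomy.  ``include_isolated`` adds edge-less retained
    taxa (``retained_taxa`` must then list them)."""
    g = nx.Graph()
    if include_isolated:
        if retained_taxa is None:
            raise ValueError("include_isolated=True requires retained_taxa")
        g.add_nodes_from(retained_taxa)
    for e in edges:
        if e.taxon_a == e.taxon_b:
            raise ValueError(f"self-loop edge on {e.taxon_a!r}")
        g.add_edge(e.taxon_a, e.taxon_b, rho=e.rho, p=e.p, sign=e.sign)
    missing = [t for t in g.nodes if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa without taxonomy entry: {missing[:5]}")
    nx.set_node_attributes(g, {t: taxonomy.loc[t, "domain"] for t in g.nodes}, "domain")
    return g


def infer_network(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    treatment: str | None = None,
    cfg: FilterConfig | None = None,
    rho2_threshold: float = 0.9,
    alpha: float = 0.05,
    correction: str = "none",
    samples: str = "all",
) -> nx.Graph:
    """Filter -> Spearman -> graph, optionally restricted to one treatment.

    ``samples='treatment'`` computes correlations only within the treatment's
    samples; ``'all'`` uses every sample (filtering is always on the selected
    sample set).
    """
    if treatment is not None and samples == "treatment":
        if metadata is None:
            raise ValueError("treatment subsetting requires metadata")
        cols = metadata.index[metadata["treatment"] == treatment]
        cols = [c for c in table.columns if c in set(cols)]
        if not cols:
            raise ValueError(f"no samples with treatment {treatment!r}")
        table = table[cols]
    retained = filter_taxa(table, cfg)
    edges = spearman_edges(retained, rho2_threshold, alpha, correction)
    return build_network(edges, taxonomy)
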