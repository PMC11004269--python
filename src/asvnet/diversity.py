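"""Alpha/beta diversity: ACE and Gini-Simpson indices, analytic rarefaction
curves, Bray-Curtis dissimilarity and the ANOSIM permutation test."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import rankdata


def _clean_counts(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D abundance vector")
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if v.sum() == 0:
        raise ValueError("all-zero abundance vector: diversity undefined")
    return v[v > 0]


def ace_index(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of species richness (Chao & Lee).

    Taxa with <= ``rare_cutoff`` reads form the rare group used to estimate
    sample coverage ``C = 1 - F1/N_rare``; the estimate is

        S_ACE = S_abund + S_rare/C + (F1/C) * gamma^2,

    with gamma^2 the rare-group coefficient of variation (floored at 0).
    When every rare taxon is a singleton the coverage is 0 and the Chao1
    estimator ``S_obs + F1(F1-1)/(2(F2+1))`` is returned instead.
    """
    v = _clean_counts(counts).astype(int)
    rare = v[v <= rare_cutoff]
    s_abund = int((v > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f = np.bincount(rare, minlength=rare_cutoff + 1)
    f1 = int(f[1])
    if f1 == n_rare:  # coverage 0: every rare taxon seen exactly once
        f2 = int(f[2]) if len(f) > 2 else 0
        return float(len(v) + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    c_ace = 1.0 - f1 / n_rare
    i = np.arange(1, rare_cutoff + 1)
    sum_ii = float(np.sum(i * (i - 1) * f[1:]))
    gamma2 = max(
        (s_rare / c_ace) * sum_ii / (n_rare * (n_rare - 1.0)) - 1.0, 0.0
    )
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def simpson_index(counts) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2): probability two random reads
    belong to different taxa. 0 for one taxon, 1 - 1/S for S even taxa."""
    v = _clean_counts(counts)
    p = v / v.sum()
    return float(1.0 - np.sum(p * p))


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness at each subsampling depth (dilution curve).

    Uses the exact hypergeometric expectation
    ``E[S_m] = sum_i (1 - C(N - N_i, m) / C(N, m))`` computed in log space.
    """
    v = _clean_counts(counts)
    n = v.sum()
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths < 0).any() or (depths > n).any():
        raise ValueError(f"depths must lie in [0, {int(n)}]")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths), dtype=float)
    for j, m in enumerate(depths):
        rem = n - v  # reads not belonging to taxon i
        keep = rem >= m
        p_absent = np.zeros(len(v))
        if keep.any():
            p_absent[keep] = np.exp(log_choose(rem[keep], m) - log_choose(n, m))
        out[j] = np.sum(1.0 - p_absent)
    return out


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (columns) of a count table:
    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"samples with zero total counts: {empty}")
    d = squareform(pdist(table.to_numpy(dtype=float).T, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


def anosim(
    dissim: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM: are between-group dissimilarities larger than within-group?

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks taken over all n(n-1)/2 dissimilarities with average ties.  The
    p-value is the add-one permutation estimate
    ``(1 + #{R_perm >= R_obs}) / (1 + n_perm)`` under random relabelling.
    """
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    labels = np.asarray(
        [groups[s] for s in dissim.index] if isinstance(groups, dict) else groups
    )
    if len(labels) != n:
        raise ValueError("group labels must match the matrix dimension")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 are not allowed: {small}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # average ranks for ties
    denom = n * (n - 1) / 4.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return float(r_obs), float(p)


def alpha_diversity_table(table: pd.DataFrame, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample ACE and Gini-Simpson summary of a count table."""
    rows = {
        s: {
            "ACE": ace_index(table[s], rare_cutoff=rare_cutoff),
            "Simpson": simpson_index(table[s]),
        }
        for s in table.columns
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
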