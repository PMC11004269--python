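"""Treatment-effect statistics: percent change vs control, one-way ANOVA with
Fisher-LSD compact letter displays, Pearson correlation panels, and LMG
relative-importance decomposition of regression R^2."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimal places (spreadsheet convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_change(treated_mean: float, control_mean: float) -> float:
    """100 * (treated - control) / control, half-up rounded to 2 d.p."""
    if control_mean == 0:
        raise ValueError("percent change undefined for a zero control mean")
    return _round2(100.0 * (treated_mean - control_mean) / control_mean)


# ---------------------------------------------------------------------------
# ANOVA + LSD letters


@dataclass
class TreatmentSummary:
    variable: str
    table: pd.DataFrame  # per-group: mean, se, n, letters, pct_change
    f_stat: float
    p_value: float


def _lsd_p_matrix(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise p-values of Fisher's LSD t-tests with the pooled ANOVA MSE."""
    names = list(groups)
    ns = {g: len(groups[g]) for g in names}
    means = {g: groups[g].mean() for g in names}
    df_err = sum(ns.values()) - len(names)
    sse = sum(((groups[g] - means[g]) ** 2).sum() for g in names)
    mse = sse / df_err
    p = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        if mse == 0:
            pv = 1.0 if means[a] == means[b] else 0.0
        else:
            t = abs(means[a] - means[b]) / np.sqrt(mse * (1 / ns[a] + 1 / ns[b]))
            pv = 2.0 * stats.t.sf(t, df_err)
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def _letter_display(means: dict[str, float], pmat: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact letter display via maximal cliques of the 'not significantly
    different' graph, lettered in order of descending best member mean.

    Guarantees: two groups share a letter iff their pairwise p >= alpha."""
    g = nx.Graph()
    g.add_nodes_from(means)
    for a, b in combinations(means, 2):
        if pmat.loc[a, b] >= alpha:
            g.add_edge(a, b)
    cliques = sorted(
        (sorted(c, key=lambda x: -means[x]) for c in nx.find_cliques(g)),
        key=lambda c: -means[c[0]],
    )
    letters: dict[str, list[str]] = {name: [] for name in means}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for name in clique:
            letters[name].append(ch)
    return {name: "".join(sorted(v)) for name, v in letters.items()}


def anova_lsd(
    values,
    groups,
    alpha: float = 0.05,
    control: str | None = None,
    variable: str = "",
) -> TreatmentSummary:
    """One-way ANOVA with LSD multiple comparisons and letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    ``control`` (default: the first group label in input order) anchors the
    percent-change column.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: values[labels == g] for g in names}
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    if all(np.ptp(v) == 0 for v in data.values()) and len({v[0] for v in data.values()}) == 1:
        f_stat, p_value = 0.0, 1.0  # all observations identical
    else:
        f_stat, p_value = stats.f_oneway(*data.values())
    pmat = _lsd_p_matrix(data)
    means = {g: float(v.mean()) for g, v in data.items()}
    letters = _letter_display(means, pmat, alpha)
    control = control if control is not None else names[0]
    tab = pd.DataFrame(
        {
            "mean": [means[g] for g in names],
            "se": [float(v.std(ddof=1) / np.sqrt(len(v))) for v in data.values()],
            "n": [len(data[g]) for g in names],
            "letters": [letters[g] for g in names],
            "pct_change": [percent_change(means[g], means[control]) for g in names],
        },
        index=pd.Index(names, name="group"),
    )
    return TreatmentSummary(variable, tab, float(f_stat), float(p_value))


def treatment_summaries(
    metadata: pd.DataFrame, variables, alpha: float = 0.05, control: str | None = None
) -> dict[str, TreatmentSummary]:
    """anova_lsd over several metadata columns, keyed by variable."""
    return {
        v: anova_lsd(metadata[v], metadata["treatment"], alpha, control, variable=v)
        for v in variables
    }


# ---------------------------------------------------------------------------
# Pearson panel


def pearson_matrix(
    x: pd.DataFrame, y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r, two-sided p and significance stars between the
    columns of ``x`` (e.g. soil covariates) and ``y`` (e.g. topology
    metrics).  Stars: * p<0.05, ** p<0.01; zero-variance columns yield NaN."""
    if len(x) != len(y):
        raise ValueError("x and y must have matching rows")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    r = pd.DataFrame(np.nan, index=x.columns, columns=y.columns)
    p = r.copy()
    for cx in x.columns:
        for cy in y.columns:
            a, b = x[cx].to_numpy(float), y[cy].to_numpy(float)
            if a.std() == 0 or b.std() == 0:
                continue  # r undefined; left NaN
            rr, pp = stats.pearsonr(a, b)
            r.loc[cx, cy], p.loc[cx, cy] = rr, pp
    stars = p.map(lambda v: "**" if v < 0.01 else "*" if v < 0.05 else "")
    return r, p, stars


# ---------------------------------------------------------------------------
# LMG relative importance


def _r2(y: np.ndarray, x: np.ndarray | None) -> float:
    """R^2 of OLS with intercept; 0 for the empty predictor set."""
    n = len(y)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if x is None or x.shape[1] == 0:
        return 0.0
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return 1.0 - float(resid @ resid) / sst


def lmg_importance(response, predictors: pd.DataFrame) -> pd.Series:
    """LMG decomposition of regression R^2 into per-predictor shares.

    Each predictor's share is its incremental R^2 averaged over all p!
    orderings of entry into the model (computed over subsets with the
    standard combinatorial weights).  Shares are non-negative and sum to the
    full-model R^2; the result is invariant to predictor input order.
    """
    y = np.asarray(response, dtype=float)
    xcols = list(predictors.columns)
    p = len(xcols)
    if p > 8:
        raise ValueError(
            f"{p} predictors: exact LMG enumerates 2^p subsets; "
            "restrict to at most 8 predictors"
        )
    if len(y) <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={len(y)}, p={p})")
    xm = predictors.to_numpy(dtype=float)
    full_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), xm]))
    if full_rank < p + 1:
        raise ValueError("predictor matrix is singular (collinear predictors)")

    r2_cache = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            r2_cache[frozenset(subset)] = _r2(y, xm[:, list(subset)])

    shares = np.zeros(p)
    for j in range(p):
        rest = [i for i in range(p) if i != j]
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for subset in combinations(rest, size):
                s = frozenset(subset)
                shares[j] += w * (r2_cache[s | {j}] - r2_cache[s])
    return pd.Series(shares, index=xcols, name="lmg_share")
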