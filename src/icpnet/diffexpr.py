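"""Empirical-Bayes moderated-t differential expression on the pooled design.

The model is a one-way group-means fit per gene (three groups, two pooled
arrays each, residual df = N − G = 3), with per-gene variances shrunk
toward a scaled inverse-chi-square prior whose hyperparameters (d0, s0²)
are estimated by moment matching on log s² (trigamma inversion).  The
moderated t for a contrast numerator − denominator is

    t_g = log2FC_g / sqrt(s̃²_g · (1/n₁ + 1/n₂)),   df = d0 + dg,

with the posterior variance s̃²_g = (d0·s0² + dg·s²_g) / (d0 + dg).
P-values are two-sided; multiplicity is handled by Benjamini–Hochberg
step-up, and genes are called differentially expressed when the linear
fold change is at least 1.5 (inclusive) AND p < 0.05 AND FDR < 0.05
(both strict), matching the published gates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.special import digamma, polygamma

from .io_formats import ExpressionMatrix

DEFAULT_CONTRASTS = {
    "mild_vs_healthy": ("mild", "healthy"),
    "severe_vs_healthy": ("severe", "healthy"),
}


# ---------------------------------------------------------------------------
# Linear fit
# ---------------------------------------------------------------------------


@dataclass
class GroupFit:
    """Per-gene group means with pooled within-group variance."""

    means: pd.DataFrame  # genes x groups
    s2: pd.Series  # pooled residual variance per gene
    dg: int  # residual degrees of freedom (N - G)
    n_per_group: dict[str, int]


def fit_group_means(matrix: ExpressionMatrix) -> GroupFit:
    """One-way group-means fit: means per group, pooled residual variance.

    Every group needs at least 2 arrays for the within-group variance to
    be defined.
    """
    groups = matrix.groups()
    for group, arrays in groups.items():
        if len(arrays) < 2:
            raise ValueError(f"group {group!r} has {len(arrays)} array(s); need >= 2")
    values = matrix.values
    n_total = sum(len(a) for a in groups.values())
    dg = n_total - len(groups)
    means = {}
    ss = np.zeros(matrix.n_genes)
    for group, arrays in groups.items():
        sub = values[arrays].to_numpy()
        mu = sub.mean(axis=1)
        means[group] = mu
        ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    return GroupFit(
        means=pd.DataFrame(means, index=values.index),
        s2=pd.Series(ss / dg, index=values.index),
        dg=dg,
        n_per_group={g: len(a) for g, a in groups.items()},
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


@dataclass
class EBayesParams:
    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    dg: int  # residual df per gene


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def ebayes_moderate(
    s2: pd.Series,
    dg: int,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> tuple[EBayesParams, pd.Series]:
    """Estimate (d0, s0²) and return posterior variances s̃²_g.

    Hyperparameters are estimated by matching the first two moments of
    log s²_g to the scaled-F sampling distribution implied by the
    inverse-chi-square prior:

        e_g = log s²_g − ψ(dg/2) + log(dg/2)
        ψ'(d0/2) = var(e) − ψ'(dg/2)        (solved by trigamma inversion)
        log s0² = mean(e) + ψ(d0/2) − log(d0/2)

    A non-positive variance excess yields d0 = ∞ (complete shrinkage to
    s0²).  Either hyperparameter may be forced; d0 = 0 reproduces the
    ordinary per-gene t and d0 = ∞ gives s̃² = s0² everywhere.
    """
    s2_arr = s2.to_numpy(dtype=float)
    if (s2_arr < 0).any():
        raise ValueError("negative sample variances")
    positive = s2_arr[s2_arr > 0]
    if positive.size == 0:
        raise ValueError(
            "all per-gene variances are zero; the data are degenerate "
            "(add noise or check the input)"
        )
    if d0 is None or s0_sq is None:
        if positive.size < 10:
            raise ValueError("need >= 10 genes with positive variance to estimate the prior")
        e = np.log(positive) - digamma(dg / 2.0) + math.log(dg / 2.0)
        e_mean = float(e.mean())
        e_var = float(e.var(ddof=1))
        excess = e_var - float(polygamma(1, dg / 2.0))
        if d0 is None:
            d0 = 2.0 * _trigamma_inverse(excess) if excess > 0 else math.inf
        if s0_sq is None:
            if math.isinf(d0):
                s0_sq = float(math.exp(e_mean))
            else:
                s0_sq = float(
                    math.exp(e_mean + digamma(d0 / 2.0) - math.log(d0 / 2.0))
                )
    params = EBayesParams(d0=float(d0), s0_sq=float(s0_sq), dg=dg)
    if math.isinf(params.d0):
        post = np.full_like(s2_arr, params.s0_sq)
    elif params.d0 == 0:
        post = s2_arr.copy()
    else:
        post = (params.d0 * params.s0_sq + dg * s2_arr) / (params.d0 + dg)
    return params, pd.Series(post, index=s2.index)


# ---------------------------------------------------------------------------
# Moderated t, BH, calling
# ---------------------------------------------------------------------------


def moderated_t_table(
    fit: GroupFit,
    params: EBayesParams,
    posterior_var: pd.Series,
    contrast: str,
    numerator: str,
    denominator: str,
) -> pd.DataFrame:
    """Per-gene log2FC, moderated t and two-sided p for one contrast."""
    lfc = fit.means[numerator] - fit.means[denominator]
    c = 1.0 / fit.n_per_group[numerator] + 1.0 / fit.n_per_group[denominator]
    se = np.sqrt(posterior_var.to_numpy() * c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc.to_numpy() / se
    t = np.where(se == 0, np.where(lfc.to_numpy() == 0, 0.0, np.inf * np.sign(lfc)), t)
    df_total = params.d0 + params.dg
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame(
        {
            "gene": fit.means.index,
            "contrast": contrast,
            "log2fc": lfc.to_numpy(),
            "moderated_t": t,
            "p": np.clip(p, 0.0, 1.0),
        }
    ).reset_index(drop=True)


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up: q(i) = min_{j>=i} m·p(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_de(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Add BH ``fdr`` and a ``call`` column (up / down / ns).

    The fold-change gate is inclusive on the linear scale
    (|FC| >= fc_threshold); the p and FDR gates are strict (<).
    """
    if min(fc_threshold, p_threshold, fdr_threshold) < 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    out["fdr"] = adjust_bh(out["p"].to_numpy())
    lfc_gate = math.log2(fc_threshold)
    passed = (
        (np.abs(out["log2fc"]) >= lfc_gate - 1e-12)
        & (out["p"] < p_threshold)
        & (out["fdr"] < fdr_threshold)
    )
    out["call"] = np.where(
        passed & (out["log2fc"] > 0), "up", np.where(passed, "down", "ns")
    )
    return out


def de_analysis(
    matrix: ExpressionMatrix,
    contrasts: dict[str, tuple[str, str]] | None = None,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Full moderated-t pipeline: fit → moderate → test → BH → call."""
    contrasts = contrasts or DEFAULT_CONTRASTS
    fit = fit_group_means(matrix)
    params, post = ebayes_moderate(fit.s2, fit.dg, d0=d0, s0_sq=s0_sq)
    out = {}
    for name, (num, den) in contrasts.items():
        table = moderated_t_table(fit, params, post, name, num, den)
        out[name] = select_de(table, fc_threshold, p_threshold, fdr_threshold)
    return out


def called_genes(table: pd.DataFrame) -> dict[str, str]:
    """Map gene → direction for the called rows of a DE table."""
    called = table[table["call"] != "ns"]
    return dict(zip(called["gene"], called["call"]))


def de_set_algebra(
    mild: dict[str, str], severe: dict[str, str]
) -> dict[str, dict[str, tuple[str, ...]]]:
    """Partition the union of called genes into intersection / mild-only /
    severe-only, keeping each contrast's own direction.

    A gene called in opposite directions lands in the intersection with
    both directions recorded.
    """
    inter = {g: (mild[g], severe[g]) for g in sorted(set(mild) & set(severe))}
    mild_only = {g: (mild[g],) for g in sorted(set(mild) - set(severe))}
    severe_only = {g: (severe[g],) for g in sorted(set(severe) - set(mild))}
    return {"intersection": inter, "mild_only": mild_only, "severe_only": severe_only}


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    gene_linkage: np.ndarray
    array_linkage: np.ndarray
    gene_newick: str
    array_newick: str
    ordered: pd.DataFrame  # heatmap matrix reordered by both dendrograms


def correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 − Pearson r between rows; constant rows get r = 0 (distance 1)."""
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s): correlation set to 0",
            stacklevel=2,
        )
    centered = values - values.mean(axis=1, keepdims=True)
    norm = np.where(constant, 1.0, np.sqrt((centered**2).sum(axis=1)))
    unit = centered / norm[:, None]
    r = unit @ unit.T
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(Z)

    def rec(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return rec(tree, tree.dist) + ";"


def hierarchical_cluster(values: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of genes (1 − Pearson) and arrays (Euclidean).

    Dendrograms are serialized as Newick; the returned ``ordered`` matrix
    is the heatmap table with rows and columns in dendrogram leaf order.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 genes and 2 arrays")
    gene_d = squareform(correlation_distance(values.to_numpy()), checks=False)
    gene_Z = linkage(gene_d, method="average")
    array_Z = linkage(pdist(values.to_numpy().T, metric="euclidean"), method="average")
    gene_order = leaves_list(gene_Z)
    array_order = leaves_list(array_Z)
    ordered = values.iloc[gene_order, array_order]
    return ClusterResult(
        gene_linkage=gene_Z,
        array_linkage=array_Z,
        gene_newick=_linkage_to_newick(gene_Z, list(values.index)),
        array_newick=_linkage_to_newick(array_Z, list(values.columns)),
        ordered=ordered,
    )
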