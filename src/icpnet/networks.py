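"""Co-expression and interaction networks, k-cores, and core-gene nomination.

The co-expression network connects gene pairs whose Pearson correlation
across arrays reaches |r| >= r_min (default 0.9; with six arrays the
p < 0.05 point at df = 4 is |r| = 0.811, so 0.9 adds margin).  Degree
centrality and k-core decomposition identify the cohesive core; the
KEGG-style interaction network is consumed as a supplied edge list.  A
gene is nominated as core when it sits in the maximum k-core of the
co-expression network or its interaction degree is in the top fraction;
the combination rule is an explicit, pluggable policy.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import EdgeList, ExpressionMatrix


def coexpression_candidates(
    matrix: ExpressionMatrix,
    extra_genes=(),
    variance_min: float = 0.5,
) -> list[str]:
    """Genes worth correlating: an explicit set plus high-variation genes.

    With six arrays, ranking genes by variance and taking a top-K list
    groups background genes by whichever array happens to be extreme and
    manufactures spurious cliques; an absolute cutoff on the across-array
    variance (default 0.5 log2², i.e. a typical swing of ~1.6-fold,
    sitting between the pooled-noise floor and any real co-regulation
    signal) avoids that artifact.
    """
    variances = matrix.values.var(axis=1, ddof=1)
    keep = set(variances[variances >= variance_min].index) | set(extra_genes)
    return [g for g in matrix.gene_ids if g in keep]


def pairwise_pearson(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between gene rows across arrays.

    Needs at least 3 arrays.  Zero-variance genes have no defined
    correlation and are excluded with a warning.  Returns a symmetric
    genes x genes DataFrame (diagonal 1 by convention, ignored
    downstream).
    """
    if len(matrix.array_ids) < 3:
        raise ValueError("pairwise correlation needs at least 3 arrays")
    if genes is None:
        genes = matrix.gene_ids
    else:
        missing = sorted(set(genes) - set(matrix.gene_ids))
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:10]}")
        genes = [g for g in matrix.gene_ids if g in set(genes)]
    values = matrix.values.loc[genes].to_numpy()
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        warnings.warn(
            f"excluding {len(dropped)} zero-variance gene(s) from correlation",
            stacklevel=2,
        )
        genes = [g for g, k in zip(genes, keep) if k]
        values = values[keep]
    if len(genes) == 0:
        return pd.DataFrame(dtype=float)
    r = np.corrcoef(values)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=genes, columns=genes)


def build_coexpression(correlations: pd.DataFrame, r_min: float = 0.9) -> nx.Graph:
    """Edge iff |r| >= r_min; isolated nodes retained; weight = signed r."""
    if not (0.0 < r_min <= 1.0):
        raise ValueError("r_min must be in (0, 1]")
    G = nx.Graph()
    genes = list(correlations.index)
    G.add_nodes_from(genes)
    r = correlations.to_numpy()
    ii, jj = np.where(np.triu(np.abs(r) >= r_min, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(genes[i], genes[j], weight=float(r[i, j]))
    return G


def kcore_decompose(network: nx.Graph) -> dict[str, int]:
    """Core number per node (largest k whose k-core contains the node)."""
    if network.number_of_nodes() == 0:
        return {}
    return nx.core_number(network)


def max_kcore(network: nx.Graph) -> tuple[set[str], int]:
    """Nodes of the highest non-empty k-core, with that k.

    An empty network yields (empty set, 0); an edgeless network has
    maximum core level 0 (every node).
    """
    core = kcore_decompose(network)
    if not core:
        return set(), 0
    k = max(core.values())
    return {v for v, c in core.items() if c == k}, k


def interaction_network(
    edges: EdgeList, gene_attributes: dict[str, dict] | None = None
) -> nx.Graph:
    """Interaction graph restricted to attributed genes plus direct partners.

    ``gene_attributes`` maps gene → attributes (e.g. membership:
    intersection/mild_only/severe_only, direction: up/down).  Attributes
    naming genes absent from the edge list are dropped with a warning.
    With no attributes the full edge list is used.
    """
    G_all = nx.Graph()
    for a, b in edges.edges:
        G_all.add_edge(a, b)
    if gene_attributes is None:
        G = G_all
    else:
        known = {g for g in gene_attributes if g in G_all}
        unknown = sorted(set(gene_attributes) - known)
        if unknown:
            warnings.warn(
                f"dropping attributes for {len(unknown)} gene(s) absent from the "
                f"edge list (e.g. {unknown[:5]})",
                stacklevel=2,
            )
        keep = set(known)
        for g in known:
            keep |= set(G_all.neighbors(g))
        G = G_all.subgraph(keep).copy()
        nx.set_node_attributes(G, {g: gene_attributes[g] for g in known})
    return G


def identify_core_genes(
    coexpr: nx.Graph,
    interaction: nx.Graph,
    top_fraction: float = 0.05,
    rule=None,
) -> pd.DataFrame:
    """Nominate core regulatory genes from the two networks.

    Default rule: a gene is core iff it belongs to the maximum non-trivial
    k-core (k >= 1) of the co-expression network OR its interaction-network
    degree is within the top ``top_fraction`` of positive degrees.  The
    ranking is deterministic: (core number desc, interaction degree desc,
    co-expression degree desc, gene id).  Pass ``rule`` (a callable
    ``rule(gene, info) -> bool``) to substitute another policy.
    """
    core = kcore_decompose(coexpr)
    max_core, k = max_kcore(coexpr)
    if k == 0:
        max_core = set()
    deg_int = dict(interaction.degree()) if interaction.number_of_nodes() else {}
    positive = sorted((d for d in deg_int.values() if d > 0), reverse=True)
    if positive:
        n_top = max(1, math.ceil(top_fraction * len(positive)))
        cutoff = positive[n_top - 1]
    else:
        cutoff = math.inf
    genes = sorted(set(coexpr.nodes) | set(deg_int))
    rows = []
    for g in genes:
        info = {
            "core_number": core.get(g, 0),
            "degree_coexpr": coexpr.degree(g) if g in coexpr else 0,
            "degree_interaction": deg_int.get(g, 0),
            "in_max_kcore": g in max_core,
        }
        if rule is not None:
            is_core = bool(rule(g, info))
        else:
            is_core = info["in_max_kcore"] or (
                info["degree_interaction"] >= cutoff and info["degree_interaction"] > 0
            )
        if is_core:
            rows.append((g, *info.values()))
    df = pd.DataFrame(
        rows,
        columns=["gene", "core_number", "degree_coexpr", "degree_interaction", "in_max_kcore"],
    )
    if df.empty:
        return df
    df = df.sort_values(
        ["core_number", "degree_interaction", "degree_coexpr", "gene"],
        ascending=[False, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return df


def node_metrics(
    coexpr: nx.Graph, gene_attributes: dict[str, dict] | None = None
) -> pd.DataFrame:
    """Per-node degree and core number of the co-expression network."""
    core = kcore_decompose(coexpr)
    attrs = gene_attributes or {}
    rows = [
        (
            g,
            coexpr.degree(g),
            core.get(g, 0),
            attrs.get(g, {}).get("membership", ""),
            attrs.get(g, {}).get("direction", ""),
        )
        for g in sorted(coexpr.nodes)
    ]
    return pd.DataFrame(
        rows, columns=["gene", "degree", "core_number", "membership", "direction"]
    )
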