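"""GO-style term over-representation with the enrichment ratio Re.

For a term covering n of the N universe genes, of which nf are among the
Nf differentially expressed genes, the one-sided Fisher (hypergeometric
upper-tail) p-value is

    p = P(X >= nf),  X ~ Hypergeometric(N, Nf, n),

computed by exact integer summation, and the enrichment ratio is

    Re = (nf / n) / (Nf / N),

the term's DE fraction relative to the array-wide DE fraction (Re > 1
means over-representation).  P-values are BH-adjusted across the terms
tested within a contrast.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .diffexpr import adjust_bh
from .io_formats import term_to_genes

RESULT_COLUMNS = ("term", "nf", "n", "Nf", "N", "p", "fdr", "Re")


def _check_counts(nf: int, n: int, Nf: int, N: int) -> None:
    if min(nf, n, Nf, N) < 0:
        raise ValueError("counts must be non-negative")
    if nf > min(n, Nf) or n > N or Nf > N:
        raise ValueError(
            f"invalid counts: need nf <= min(n, Nf), n <= N, Nf <= N; "
            f"got (nf={nf}, n={n}, Nf={Nf}, N={N})"
        )


def fisher_term_test(nf: int, n: int, Nf: int, N: int) -> float:
    """One-sided over-representation p = P(X >= nf), exact integer arithmetic."""
    _check_counts(nf, n, Nf, N)
    if nf == 0:
        return 1.0
    hi = min(n, Nf)
    numerator = sum(comb(Nf, k) * comb(N - Nf, n - k) for k in range(nf, hi + 1))
    return float(min(Fraction(numerator, comb(N, n)), 1))


def enrichment_ratio(nf: int, n: int, Nf: int, N: int) -> float:
    """Re = (nf/n)/(Nf/N); undefined (raises) when n, Nf or N is zero."""
    _check_counts(nf, n, Nf, N)
    if n == 0 or Nf == 0 or N == 0:
        raise ZeroDivisionError(
            f"enrichment ratio undefined for (nf={nf}, n={n}, Nf={Nf}, N={N})"
        )
    return (nf / n) / (Nf / N)


def enrich_all(
    de_genes, annotation: pd.DataFrame, universe
) -> pd.DataFrame:
    """Test every annotated term against the DE set over the given universe.

    The universe is the flag-filtered gene set (N = its size); terms are
    intersected with it and terms with no universe gene are skipped.
    Results are BH-adjusted across tested terms and sorted by
    (fdr, Re descending, term).  With an empty DE set all p = 1 and
    Re = 0.
    """
    universe = set(universe)
    de = set(de_genes)
    stray = sorted(de - universe)
    if stray:
        raise ValueError(f"DE genes outside the universe: {stray[:10]}")
    N = len(universe)
    Nf = len(de)
    rows = []
    for term, genes in sorted(term_to_genes(annotation).items()):
        members = genes & universe
        n = len(members)
        if n == 0:
            continue
        nf = len(members & de)
        p = fisher_term_test(nf, n, Nf, N)
        if Nf == 0 or nf == 0:
            re = 0.0
        else:
            re = enrichment_ratio(nf, n, Nf, N)
        rows.append((term, nf, n, Nf, N, p, re))
    if not rows:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    df = pd.DataFrame(rows, columns=["term", "nf", "n", "Nf", "N", "p", "Re"])
    df["fdr"] = adjust_bh(df["p"].to_numpy())
    df = df.sort_values(
        ["fdr", "Re", "term"], ascending=[True, False, True], kind="stable"
    ).reset_index(drop=True)
    return df[list(RESULT_COLUMNS)]


def significant_terms(result: pd.DataFrame, fdr_threshold: float = 0.05) -> list[str]:
    """Terms with FDR below the threshold, in result ranking order."""
    return list(result.loc[result["fdr"] < fdr_threshold, "term"])


def categorize_terms(
    mild_terms: list[str],
    severe_terms: list[str],
    top_k_intersection: int = 10,
    top_k_unique: int = 5,
) -> dict[str, list[str]]:
    """Split significant terms into intersection / mild-only / severe-only.

    Inputs are each contrast's significant terms in that contrast's own
    ranking order.  The intersection is ranked by the minimum rank across
    the two contrasts; the unique lists keep their contrast's order.  Each
    list is truncated to its top-k (no padding when fewer exist).
    """
    mild_rank = {t: i for i, t in enumerate(mild_terms)}
    severe_rank = {t: i for i, t in enumerate(severe_terms)}
    inter = sorted(
        set(mild_terms) & set(severe_terms),
        key=lambda t: (min(mild_rank[t], severe_rank[t]), t),
    )
    mild_only = [t for t in mild_terms if t not in severe_rank]
    severe_only = [t for t in severe_terms if t not in mild_rank]
    return {
        "intersection": inter[:top_k_intersection],
        "mild_only": mild_only[:top_k_unique],
        "severe_only": severe_only[:top_k_unique],
    }
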