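"""Hypergeometric over-representation of gene sets in flat term maps.

Terms (GO categories or pathways) are flat term -> gene-set maps; no DAG
propagation is performed.  For a background universe of N genes, a term
annotating K of them and a DE set of n genes of which k carry the term,
the enrichment p-value is the upper tail P(X >= k) of
Hypergeometric(N, K, n).  Family-wise error is controlled by Bonferroni
over the number of tested terms (BH-FDR available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

CATEGORIES = ("biological_process", "molecular_function", "cellular_component", "pathway")


@dataclass(frozen=True)
class TermMap:
    term_id: str
    name: str
    category: str
    genes: frozenset


def read_term_map(path: str | Path) -> list[TermMap]:
    """Read a TSV with columns term_id, term_name, category, gene_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"term_id", "term_name", "category", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"term map must have columns {sorted(required)}")
    out = []
    for (term_id, name, category), group in df.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        out.append(TermMap(term_id, name, category, frozenset(group["gene_id"])))
    return out


def hypergeom_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def category_shares(term_counts: dict[str, int]) -> dict[str, float]:
    """Percentage of assigned terms per category, 1 decimal, half-up."""
    total = sum(term_counts.values())
    if total == 0:
        return {c: 0.0 for c in term_counts}
    return {
        c: float((Decimal(v) * 100 / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        for c, v in term_counts.items()
    }


def enrich(
    de_genes,
    background,
    term_maps: list[TermMap],
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> tuple[pd.DataFrame, dict]:
    """Test every term with at least one DE gene for over-representation.

    The correction multiplicity m is the number of terms actually tested
    (those with k >= 1).  Returns the result frame sorted by p and a
    summary with per-category assigned-term counts and their percentage
    shares.
    """
    background = set(background)
    de = set(de_genes)
    if not background:
        raise ValueError("empty background universe")
    if not de <= background:
        raise ValueError("DE genes must be a subset of the background")
    N, n = len(background), len(de)

    rows = []
    for term in term_maps:
        annotated = term.genes & background
        k = len(annotated & de)
        if k == 0:
            continue  # terms never hit by a DE gene are not "assigned"
        K = len(annotated)
        rows.append(
            {
                "term_id": term.term_id,
                "name": term.name,
                "category": term.category,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": hypergeom_p(N, K, n, k),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "category", "N", "K", "n", "k", "p"]
    )
    m = len(df)
    if m:
        if method == "bonferroni":
            df["corrected"] = (df["p"] * m).clip(upper=1.0)
        elif method == "bh":
            from .expression_de import bh_fdr

            df["corrected"] = bh_fdr(df["p"].to_numpy())
        else:
            raise ValueError(f"unknown correction method {method!r}")
        df["significant"] = df["corrected"] <= alpha
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["corrected"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)

    counts = df["category"].value_counts().to_dict() if m else {}
    summary = {
        "tested_terms": m,
        "significant_terms": int(df["significant"].sum()) if m else 0,
        "category_counts": counts,
        "category_percentages": category_shares(counts),
    }
    return df, summary
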