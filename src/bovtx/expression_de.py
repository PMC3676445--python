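"""Per-gene quantification and two-library differential expression.

Expression is measured as raw exon-overlapping read counts and RPKM
(reads per kilobase of exon model per million mapped reads,
RPKM = count / (library/1e6 * length/1e3)).  Differential expression
between two un-replicated libraries uses the Audic-Claverie exact test:
conditioned on observing x counts in library 1 (size N1), the count y in
library 2 (size N2) follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative-binomial tail whose two-sided p-value is twice the smaller
tail, capped at 1.  Multiple testing is controlled with the
Benjamini-Hochberg step-up, and calls additionally require a
library-size-normalised fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_formats import UNIQUE, AlignmentRecord, GenomeAnnotation


@dataclass
class GeneCountTable:
    """Per-gene counts and RPKM for two libraries ("a" and "b").

    ``n_a``/``n_b`` are the library sizes (total mapped reads) used both
    for RPKM and as N1/N2 of the exact test.
    """

    table: pd.DataFrame  # index: gene; columns: length, count_a, count_b, rpkm_a, rpkm_b
    n_a: int
    n_b: int

    @classmethod
    def from_counts(
        cls,
        counts_a: pd.Series,
        counts_b: pd.Series,
        lengths: pd.Series,
        n_a: int | None = None,
        n_b: int | None = None,
    ) -> "GeneCountTable":
        genes = lengths.index
        ca = counts_a.reindex(genes, fill_value=0).astype(int)
        cb = counts_b.reindex(genes, fill_value=0).astype(int)
        n_a = int(ca.sum()) if n_a is None else int(n_a)
        n_b = int(cb.sum()) if n_b is None else int(n_b)
        table = pd.DataFrame(
            {
                "length": lengths.astype(int),
                "count_a": ca,
                "count_b": cb,
                "rpkm_a": [rpkm(c, l, n_a) for c, l in zip(ca, lengths)],
                "rpkm_b": [rpkm(c, l, n_b) for c, l in zip(cb, lengths)],
            },
            index=genes,
        )
        return cls(table, n_a, n_b)


def count_reads_per_gene(
    records: list[AlignmentRecord], annotation: GenomeAnnotation
) -> tuple[pd.Series, set[str]]:
    """Unique-read counts per gene; a read counts for every gene whose
    exon union any of its aligned blocks overlaps.

    Returns the per-gene counts and the set of read ids that hit exons of
    more than one gene (counted for each, flagged ambiguous).
    """
    exon_index: dict[str, list[tuple[int, int, str]]] = {}
    for gene_id, gene in annotation.genes.items():
        for s, e in annotation.exon_union(gene_id):
            exon_index.setdefault(gene.chromosome, []).append((s, e, gene_id))
    for chrom in exon_index:
        exon_index[chrom].sort()

    counts = {g: 0 for g in annotation.genes}
    ambiguous: set[str] = set()
    for rec in records:
        if rec.multiplicity != UNIQUE:
            continue
        ivals = exon_index.get(rec.chromosome)
        if not ivals:
            continue
        hit: set[str] = set()
        for bs, be in rec.blocks:
            for s, e, gene_id in ivals:
                if s >= be:
                    break
                if e > bs:
                    hit.add(gene_id)
        for gene_id in hit:
            counts[gene_id] += 1
        if len(hit) > 1:
            ambiguous.add(rec.read_id)
    return pd.Series(counts, name="count"), ambiguous


def rpkm(count: int, exon_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon model length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    return count / ((total_mapped / 1e6) * (exon_length_bp / 1e3))


def _ac_log_pmf(k: np.ndarray, x: int, log_ratio: float, log1p_ratio: float) -> np.ndarray:
    # log p(k|x) for the conditional count distribution; k may be a vector
    return (
        k * log_ratio
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log1p_ratio
    )


_TINY = 5e-324  # smallest positive double; p-values never underflow to 0


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library 1, size n1)
    and y (library 2, size n2).

    Both tails are accumulated in log space; the two-sided value is
    min(1, 2*min(P(Y<=y), P(Y>=y))) and is strictly positive.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    ratio = n2 / n1
    log_ratio = np.log(ratio)
    log1p_ratio = np.log1p(ratio)

    ks = np.arange(y + 1)
    log_terms = _ac_log_pmf(ks, x, log_ratio, log1p_ratio)
    log_lower = logsumexp(log_terms)                     # P(Y <= y)
    lower = float(np.exp(log_lower))
    if y == 0:
        upper = 1.0
    else:
        upper = 1.0 - float(np.exp(logsumexp(log_terms[:-1])))  # P(Y >= y)
    if upper < 1e-12:
        # cancellation: accumulate the upper tail directly until it converges
        mean = (x + 1) * ratio
        horizon = int(max(y, mean) + 20 * np.sqrt(max(y, mean) + 1) + 50)
        ks_up = np.arange(y, horizon + 1)
        upper = float(np.exp(logsumexp(_ac_log_pmf(ks_up, x, log_ratio, log1p_ratio))))
    p = 2.0 * min(lower, upper)
    return float(min(1.0, max(p, _TINY)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-safe)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    table: GeneCountTable,
    fdr_max: float = 0.001,
    lfc_min: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Audic-Claverie test + BH-FDR + fold-change thresholds for every gene.

    The log2 ratio is computed on library-size-normalised counts with a
    pseudocount of 1 added to both normalised counts (ratio only — the
    exact test always sees the raw counts).  Direction "up" means higher
    in library a.  Returns the per-gene frame and an {up, down} summary.
    """
    t = table.table
    n1, n2 = table.n_a, table.n_b
    # normalise both libraries to their geometric-mean size: symmetric, so
    # swapping the libraries negates every ratio exactly
    scale = float(np.sqrt(n1 * n2))
    norm_a = t["count_a"].to_numpy(float) * (scale / n1)
    norm_b = t["count_b"].to_numpy(float) * (scale / n2)
    log2_ratio = np.log2(norm_a + 1.0) - np.log2(norm_b + 1.0)
    p = np.array(
        [audic_claverie_p(int(x), int(y), n1, n2) for x, y in zip(t["count_a"], t["count_b"])]
    )
    q = bh_fdr(p)
    call = np.where(
        (q <= fdr_max) & (np.abs(log2_ratio) >= lfc_min),
        np.where(log2_ratio > 0, "up", "down"),
        "not-DE",
    )
    result = t.copy()
    result["log2_ratio"] = log2_ratio
    result["p"] = p
    result["q"] = q
    result["call"] = call
    summary = {
        "up": int((call == "up").sum()),
        "down": int((call == "down").sum()),
        "not_de": int((call == "not-DE").sum()),
    }
    return result, summary
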