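"""Bayesian consensus genotype calling from read pileups.

A simplified diploid consensus caller in the SOAPsnp mould: at every
covered site the likelihood of each of the ten diploid genotypes is the
product over base observations of a per-base error model
(epsilon_i = 10^(-Q_i/10); a wrong base is any of the three others with
equal probability, and a heterozygote emits each allele with probability
1/2).  Combined with a reference-aware diploid prior, the genotype with
the highest posterior is the consensus; its Phred-scaled confidence is
-10*log10(1 - posterior).  A site is reported as a SNP when the
consensus differs from the reference, and passes when the consensus
quality is >= 20 and at least two distinct unique reads carry the
non-reference allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

from .io_formats import UNIQUE, AlignmentRecord

ALPHABET = "ACGT"
GENOTYPES = tuple("".join(g) for g in combinations_with_replacement(ALPHABET, 2))
_TRANSITions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITions


@dataclass
class PileupColumn:
    chromosome: str
    position: int
    ref: str
    bases: list[str] = field(default_factory=list)
    quals: list[int] = field(default_factory=list)
    read_ids: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.bases)


@dataclass
class GenotypePrior:
    """Reference-aware prior over the ten diploid genotypes.

    ``het_rate`` is the prior probability that a site is heterozygous
    with the reference allele, ``hom_rate`` that it is homozygous for a
    non-reference allele; transitions are up-weighted over transversions
    by ``titv``.  Genotypes containing no reference allele get the tiny
    residual mass het_rate*hom_rate.  The full vector is renormalised to
    sum to exactly 1.
    """

    het_rate: float = 1e-3
    hom_rate: float = 5e-4
    titv: float = 2.0

    def probabilities(self, ref: str) -> dict[str, float]:
        if ref not in ALPHABET:
            raise ValueError(f"reference base must be one of {ALPHABET}, got {ref!r}")
        alts = [b for b in ALPHABET if b != ref]
        weights = {b: (self.titv if _is_transition(ref, b) else 1.0) for b in alts}
        wsum = sum(weights.values())
        prior: dict[str, float] = {}
        for gt in GENOTYPES:
            a, b = gt
            if a == ref and b == ref:
                prior[gt] = 1.0 - self.het_rate - self.hom_rate
            elif ref in gt:
                alt = b if a == ref else a
                prior[gt] = self.het_rate * weights[alt] / wsum
            elif a == b:
                prior[gt] = self.hom_rate * weights[a] / wsum
            else:
                prior[gt] = self.het_rate * self.hom_rate
        total = sum(prior.values())
        return {g: p / total for g, p in prior.items()}


@dataclass
class SNPCall:
    chromosome: str
    position: int
    ref: str
    genotype: str
    quality: float
    alt_support: int
    depth: int
    passed: bool
    reasons: tuple[str, ...]


def build_pileup(
    records: list[AlignmentRecord], genome: dict[str, str]
) -> dict[tuple[str, int], PileupColumn]:
    """Stack base observations from unique reads at every covered site.

    Splice gaps contribute no observation.  Base and quality are taken at
    the read offset implied by the aligned blocks.
    """
    columns: dict[tuple[str, int], PileupColumn] = {}
    for rec in records:
        if rec.multiplicity != UNIQUE or not rec.blocks:
            continue
        seq = genome[rec.chromosome]
        offset = 0
        for bs, be in rec.blocks:
            if be > len(seq):
                raise ValueError(
                    f"block [{bs},{be}) of {rec.read_id} beyond end of {rec.chromosome}"
                )
            for i in range(bs, be):
                base = rec.bases[offset + (i - bs)]
                qual = rec.qualities[offset + (i - bs)] if rec.qualities else 0
                key = (rec.chromosome, i)
                col = columns.get(key)
                if col is None:
                    col = columns[key] = PileupColumn(rec.chromosome, i, seq[i])
                col.bases.append(base)
                col.quals.append(qual)
                col.read_ids.append(rec.read_id)
            offset += be - bs
    return columns


def genotype_posteriors(column: PileupColumn, prior: GenotypePrior) -> dict[str, float]:
    """Posterior over the ten diploid genotypes at one column."""
    log_prior = {g: math.log(p) for g, p in prior.probabilities(column.ref).items()}
    log_post = {}
    for gt in GENOTYPES:
        a, b = gt
        ll = 0.0
        for base, q in zip(column.bases, column.quals):
            eps = 10.0 ** (-q / 10.0)
            pa = 1.0 - eps if base == a else eps / 3.0
            pb = 1.0 - eps if base == b else eps / 3.0
            ll += math.log(0.5 * pa + 0.5 * pb)
        log_post[gt] = ll + log_prior[gt]
    mx = max(log_post.values())
    unnorm = {g: math.exp(v - mx) for g, v in log_post.items()}
    z = sum(unnorm.values())
    return {g: v / z for g, v in unnorm.items()}


def genotype_posterior(
    column: PileupColumn, prior: GenotypePrior, max_quality: float = 99.0
) -> tuple[str, float]:
    """Best genotype and its Phred-scaled consensus quality.

    Ties break toward reference-containing genotypes, then lexicographic.
    """
    if column.depth < 1:
        raise ValueError("posterior undefined for an empty column")
    post = genotype_posteriors(column, prior)
    best_p = max(post.values())
    candidates = [g for g, p in post.items() if p == best_p]
    candidates.sort(key=lambda g: (column.ref not in g, g))
    best = candidates[0]
    quality = -10.0 * math.log10(max(1.0 - best_p, 10 ** (-max_quality / 10.0)))
    return best, min(quality, max_quality)


def call_snps(
    columns: dict[tuple[str, int], PileupColumn],
    prior: GenotypePrior | None = None,
    min_quality: float = 20.0,
    min_alt_reads: int = 2,
) -> list[SNPCall]:
    """Report every site whose consensus genotype differs from reference.

    A call passes when the consensus quality reaches ``min_quality`` and
    at least ``min_alt_reads`` distinct unique reads carry a
    non-reference allele of the called genotype; failed calls keep their
    reasons.
    """
    prior = prior or GenotypePrior()
    calls = []
    for key in sorted(columns):
        col = columns[key]
        if col.depth == 0:
            continue
        best, quality = genotype_posterior(col, prior)
        if best == col.ref * 2:
            continue
        alt_alleles = set(best) - {col.ref}
        supporting = {
            rid for rid, b in zip(col.read_ids, col.bases) if b in alt_alleles
        }
        reasons = []
        if quality < min_quality:
            reasons.append(f"q{int(min_quality)}")
        if len(supporting) < min_alt_reads:
            reasons.append(f"alt{min_alt_reads}")
        calls.append(
            SNPCall(
                chromosome=col.chromosome,
                position=col.position,
                ref=col.ref,
                genotype=best,
                quality=quality,
                alt_support=len(supporting),
                depth=col.depth,
                passed=not reasons,
                reasons=tuple(reasons),
            )
        )
    return calls


def filter_coding(calls: list[SNPCall], annotation) -> list[SNPCall]:
    """Optional restriction of calls to sites inside annotated exons."""
    exon_union: dict[str, list[tuple[int, int]]] = {}
    for gene_id, gene in annotation.genes.items():
        exon_union.setdefault(gene.chromosome, []).extend(annotation.exon_union(gene_id))
    kept = []
    for call in calls:
        ivals = exon_union.get(call.chromosome, ())
        if any(s <= call.position < e for s, e in ivals):
            kept.append(call)
    return kept
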