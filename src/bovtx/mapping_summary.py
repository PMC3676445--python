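"""Read-alignment category accounting against genome and gene scopes.

Mirrors the standard bulk RNA-seq mapping report: total reads/base pairs,
mapped, perfectly matched, mismatched (at most 3 bp), uniquely matched,
multi-position, unmapped — each with a count and a percentage of total
reads rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io_formats import MULTI, UNIQUE, UNMAPPED, AlignmentRecord, GenomeAnnotation


class UndefinedPercentage(ArithmeticError):
    """Raised when a percentage is requested over a zero total."""


def percentage(count: int, total: int) -> float:
    """100*count/total, rounded half-up to 2 decimals.

    Half-up (rather than banker's) rounding is what published mapping
    tables use; the choice is observable in cells like 1/3 -> 33.33.
    """
    if total == 0:
        raise UndefinedPercentage("percentage undefined for total == 0")
    if not (0 <= count <= total):
        raise ValueError(f"count {count} outside [0, {total}]")
    value = (Decimal(count) * 100) / Decimal(total)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MappingSummary:
    total_reads: int
    total_bp: int
    mapped: int
    perfect: int
    mismatch_le3: int
    unique: int
    multi: int
    unmapped: int
    scope: str = "genome"
    undefined: bool = False  # True when total_reads == 0

    _CATEGORIES = (
        ("total_reads", "Total reads"),
        ("mapped", "Total mapped reads"),
        ("perfect", "Perfectly matched reads"),
        ("mismatch_le3", "Reads with <=3 bp mismatch"),
        ("unique", "Uniquely matched reads"),
        ("multi", "Multi-position matched reads"),
        ("unmapped", "Total unmapped reads"),
    )

    def percent(self, field_name: str) -> float:
        if self.undefined:
            return 0.00
        return percentage(getattr(self, field_name), self.total_reads)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": label, "count": getattr(self, name), "percentage": self.percent(name)}
            for name, label in self._CATEGORIES
        ]
        return pd.DataFrame(rows)


def _overlaps_exons(record: AlignmentRecord, exon_union: dict[str, list[tuple[int, int]]]) -> bool:
    ivals = exon_union.get(record.chromosome)
    if not ivals:
        return False
    import bisect

    starts = [s for s, _ in ivals]
    for bs, be in record.blocks:
        # candidate exon: the one starting at or before the block end
        i = bisect.bisect_right(starts, be - 1) - 1
        # walk left while exons could still overlap (exons are merged/disjoint,
        # so only the nearest one can overlap a given block)
        if i >= 0 and ivals[i][1] > bs:
            return True
    return False


def summarize(
    records: list[AlignmentRecord],
    scope: str = "genome",
    annotation: GenomeAnnotation | None = None,
) -> MappingSummary:
    """Tally the mapping categories for one library.

    ``scope="genome"`` counts a read as mapped when it aligned anywhere;
    ``scope="genes"`` counts it as mapped only when at least one aligned
    block overlaps an annotated exon by >= 1 bp (the least-assumption
    definition of gene-scope mapping).  The partition identities
    mapped + unmapped == total, unique + multi == mapped and
    perfect + mismatched == mapped hold by construction.
    """
    if scope not in ("genome", "genes"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "genes":
        if annotation is None:
            raise ValueError("gene scope requires an annotation")
        exon_union = {}
        for gene_id, gene in annotation.genes.items():
            exon_union.setdefault(gene.chromosome, []).extend(annotation.exon_union(gene_id))
        for chrom in exon_union:
            merged: list[tuple[int, int]] = []
            for s, e in sorted(exon_union[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            exon_union[chrom] = merged

    total = len(records)
    total_bp = 0
    mapped = perfect = unique = multi = 0
    for rec in records:
        total_bp += len(rec.bases) if rec.bases else rec.aligned_length
        if rec.multiplicity == UNMAPPED:
            continue
        if scope == "genes" and not _overlaps_exons(rec, exon_union):
            continue
        mapped += 1
        if rec.mismatches == 0:
            perfect += 1
        if rec.multiplicity == UNIQUE:
            unique += 1
        else:
            multi += 1
    return MappingSummary(
        total_reads=total,
        total_bp=total_bp,
        mapped=mapped,
        perfect=perfect,
        mismatch_le3=mapped - perfect,
        unique=unique,
        multi=multi,
        unmapped=total - mapped,
        scope=scope,
        undefined=(total == 0),
    )
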