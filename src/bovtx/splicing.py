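"""Splice-junction extraction and alternative-splicing classification.

Junctions come straight from the gaps of spliced (``N``-containing)
unique alignments.  Per gene, the junction set plus the exon coverage
profile is classified into the four event types analysed here: exon
skipping (ES), intron retention (IR), alternative 5' splice site (A5SS)
and alternative 3' splice site (A3SS).  Alternative first/last exons and
mutually exclusive exons are deliberately out of scope.

The 5'/3' labels are strand-aware: for two junctions sharing their
left-hand (donor-coordinate) boundary, the varying boundary is the 3'
splice site on the + strand but the 5' splice site on the - strand, so
the labels swap exactly under strand reversal.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .io_formats import UNIQUE, AlignmentRecord, GenomeAnnotation

ES = "exon_skipping"
IR = "intron_retention"
A5SS = "alt_5ss"
A3SS = "alt_3ss"
EVENT_TYPES = (ES, IR, A5SS, A3SS)


@dataclass
class JunctionSite:
    chromosome: str
    donor: int     # end of the upstream block (coordinate-wise left)
    acceptor: int  # start of the downstream block
    support: int
    strand: str | None = None   # set once assigned to a gene
    ambiguous: bool = False     # inside >1 overlapping gene span


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    type: str
    junctions: tuple[tuple[int, int], ...]  # (donor, acceptor) evidence
    interval: tuple[int, int] | None        # skipped exon or retained intron
    support: tuple[int, ...]


def extract_junctions(
    records: list[AlignmentRecord], min_anchor: int = 8
) -> list[JunctionSite]:
    """One junction per distinct (chrom, donor, acceptor) among unique reads.

    Support counts distinct unique reads spanning the gap with at least
    ``min_anchor`` aligned bases on each side (short anchors are the
    classic source of spurious junctions).
    """
    supporting: dict[tuple[str, int, int], set[str]] = defaultdict(set)
    for rec in records:
        if rec.multiplicity != UNIQUE or len(rec.blocks) < 2:
            continue
        for (s1, e1), (s2, e2) in zip(rec.blocks, rec.blocks[1:]):
            if e1 - s1 >= min_anchor and e2 - s2 >= min_anchor:
                supporting[(rec.chromosome, e1, s2)].add(rec.read_id)
    return [
        JunctionSite(chrom, donor, acceptor, support=len(reads))
        for (chrom, donor, acceptor), reads in sorted(supporting.items())
    ]


def assign_junctions_to_genes(
    junctions: list[JunctionSite], annotation: GenomeAnnotation
) -> dict[str, list[JunctionSite]]:
    """Assign each junction to every gene whose span contains both boundaries.

    Junctions landing in more than one (overlapping) gene are flagged
    ambiguous but still assigned to each; junctions inside no gene are
    dropped from AS calling.
    """
    by_gene: dict[str, list[JunctionSite]] = defaultdict(list)
    genes_by_chrom: dict[str, list] = defaultdict(list)
    for gene in annotation.genes.values():
        genes_by_chrom[gene.chromosome].append(gene)
    for jct in junctions:
        owners = [
            g
            for g in genes_by_chrom.get(jct.chromosome, [])
            if g.start <= jct.donor and jct.acceptor <= g.end
        ]
        if len(owners) > 1:
            jct.ambiguous = True
        for gene in owners:
            jct.strand = gene.strand if len(owners) == 1 else jct.strand
            by_gene[gene.id].append(jct)
    return dict(by_gene)


def _annotated_internal_exons(annotation: GenomeAnnotation, gene_id: str) -> set[tuple[int, int]]:
    internal: set[tuple[int, int]] = set()
    for tx in annotation.transcripts_of(gene_id):
        for exon in tx.exons[1:-1]:
            internal.add(exon)
    return internal


def _annotated_introns(annotation: GenomeAnnotation, gene_id: str) -> set[tuple[int, int]]:
    introns: set[tuple[int, int]] = set()
    for tx in annotation.transcripts_of(gene_id):
        introns.update(tx.introns())
    return introns


def classify_as_events(
    gene_id: str,
    junctions: list[JunctionSite],
    annotation: GenomeAnnotation,
    depth: np.ndarray | None = None,
    min_support: int = 2,
    min_depth: int = 2,
) -> list[ASEvent]:
    """Classify one gene's junction set into the four AS event types.

    A5SS/A3SS pair any two well-supported junctions sharing one boundary
    (novel boundaries participate).  Exon skipping is called against
    annotated internal exons only: a junction must bridge the complete
    exon while its inclusion is independently evidenced by a flanking
    junction or by exon coverage >= min_depth.  Intron retention demands
    both full intron coverage >= min_depth and a junction supporting the
    spliced form — without the junction, pre-mRNA or a mis-annotated
    intron would be indistinguishable from retention.
    """
    gene = annotation.genes[gene_id]
    strong = sorted(
        (j for j in junctions if j.support >= min_support),
        key=lambda j: (j.donor, j.acceptor),
    )
    events: list[ASEvent] = []
    internal_exons = sorted(_annotated_internal_exons(annotation, gene_id))

    def spans_whole_exon(lo: int, hi: int) -> bool:
        return any(lo <= es and ee <= hi for es, ee in internal_exons)

    # --- alternative splice sites -------------------------------------
    by_donor: dict[int, list[JunctionSite]] = defaultdict(list)
    by_acceptor: dict[int, list[JunctionSite]] = defaultdict(list)
    for j in strong:
        by_donor[j.donor].append(j)
        by_acceptor[j.acceptor].append(j)
    # shared donor, varying acceptor: 3'SS varies on +, 5'SS on -
    shared_donor_type = A3SS if gene.strand == "+" else A5SS
    shared_acceptor_type = A5SS if gene.strand == "+" else A3SS
    for donor, group in sorted(by_donor.items()):
        for j1, j2 in combinations(group, 2):
            lo, hi = sorted((j1.acceptor, j2.acceptor))
            if spans_whole_exon(lo, hi):
                continue  # differs by a complete exon: that is skipping
            events.append(
                ASEvent(
                    gene_id,
                    shared_donor_type,
                    ((j1.donor, j1.acceptor), (j2.donor, j2.acceptor)),
                    None,
                    (j1.support, j2.support),
                )
            )
    for acceptor, group in sorted(by_acceptor.items()):
        for j1, j2 in combinations(group, 2):
            lo, hi = sorted((j1.donor, j2.donor))
            if spans_whole_exon(lo, hi):
                continue
            events.append(
                ASEvent(
                    gene_id,
                    shared_acceptor_type,
                    ((j1.donor, j1.acceptor), (j2.donor, j2.acceptor)),
                    None,
                    (j1.support, j2.support),
                )
            )

    # --- exon skipping -------------------------------------------------
    for exon in internal_exons:
        es, ee = exon
        for j in strong:
            if j.donor <= es and j.acceptor >= ee:
                included_by_junction = any(
                    (k.acceptor == es or k.donor == ee) and k is not j for k in strong
                )
                included_by_coverage = (
                    depth is not None
                    and ee <= len(depth)
                    and bool(np.all(depth[es:ee] >= min_depth))
                )
                if included_by_junction or included_by_coverage:
                    events.append(
                        ASEvent(gene_id, ES, ((j.donor, j.acceptor),), exon, (j.support,))
                    )

    # --- intron retention ----------------------------------------------
    if depth is not None:
        for intron in sorted(_annotated_introns(annotation, gene_id)):
            istart, iend = intron
            spliced = [j for j in strong if j.donor == istart and j.acceptor == iend]
            if not spliced:
                continue
            if iend <= len(depth) and bool(np.all(depth[istart:iend] >= min_depth)):
                events.append(
                    ASEvent(gene_id, IR, ((istart, iend),), intron, (spliced[0].support,))
                )

    return events


def summarize_as(events: list[ASEvent]) -> dict:
    """Per-type event and gene tallies plus retained-intron size stats."""
    event_counts = Counter(e.type for e in events)
    genes_per_type: dict[str, set[str]] = defaultdict(set)
    events_per_gene = Counter()
    for e in events:
        genes_per_type[e.type].add(e.gene_id)
        events_per_gene[e.gene_id] += 1
    k_hist = Counter(events_per_gene.values())
    n_spliced = len(events_per_gene)
    n_multi = sum(1 for n in events_per_gene.values() if n >= 2)
    ir_sizes = [e.interval[1] - e.interval[0] for e in events if e.type == IR]
    return {
        "event_counts": {t: event_counts.get(t, 0) for t in EVENT_TYPES},
        "gene_counts": {t: len(genes_per_type.get(t, ())) for t in EVENT_TYPES},
        "genes_with_k_events": dict(sorted(k_hist.items())),
        "multi_event_fraction": (n_multi / n_spliced) if n_spliced else 0.0,
        "retained_intron_sizes": {
            "n": len(ir_sizes),
            "mean": float(np.mean(ir_sizes)) if ir_sizes else float("nan"),
            "min": min(ir_sizes) if ir_sizes else None,
            "max": max(ir_sizes) if ir_sizes else None,
        },
    }
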