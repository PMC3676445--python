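"""Transcriptionally active regions, novel transcript units, gene refinement.

The detection chain is: per-base coverage from uniquely mapped reads ->
maximal runs of depth >= 2 (TARs) -> TARs connected by paired-end links
into transcript units -> units surviving the intergenic filters become
putative novel transcript units.  The same TARs, compared against the
annotated gene spans, yield 5'/3' boundary extensions.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from .io_formats import UNIQUE, AlignmentRecord, GenomeAnnotation


@dataclass
class TAR:
    """A maximal run of bases each covered by >= min_depth unique reads."""

    id: str
    chromosome: str
    start: int
    end: int
    min_coverage: int
    mean_coverage: float
    support: int = 0  # unique reads with a block overlapping the run

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptUnit:
    id: str
    chromosome: str
    tar_ids: tuple[str, ...]
    start: int
    end: int
    total_length: int      # sum of member-TAR lengths, not the span
    mean_coverage: float   # averaged over member-TAR bases only
    n_blocks: int


@dataclass
class NovelTU:
    unit: TranscriptUnit
    # all four must be True for a unit to be returned as novel
    intergenic: bool
    no_gene_overlap: bool
    min_length: bool
    min_mean_coverage: bool


@dataclass
class GeneExtension:
    gene_id: str
    end: str  # "5p" or "3p", strand-aware
    length: int
    tar_id: str


def compute_coverage(records: list[AlignmentRecord], chromosome: str, chrom_length: int) -> np.ndarray:
    """Per-base depth of uniquely mapped read blocks on one chromosome.

    Splice gaps contribute nothing.  Implemented as a difference array so
    the cost is O(reads + chromosome length).
    """
    diff = np.zeros(chrom_length + 1, dtype=np.int32)
    for rec in records:
        if rec.multiplicity != UNIQUE or rec.chromosome != chromosome:
            continue
        for s, e in rec.blocks:
            if s < 0 or e > chrom_length:
                raise ValueError(
                    f"block [{s},{e}) of {rec.read_id} outside chromosome "
                    f"{chromosome} (length {chrom_length})"
                )
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1], dtype=np.int32)


def detect_tars(
    depth: np.ndarray, chromosome: str = "chr", min_depth: int = 2
) -> list[TAR]:
    """Maximal runs where every base has depth >= min_depth."""
    mask = np.asarray(depth) >= min_depth
    if mask.size == 0 or not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
    starts, ends = edges[::2], edges[1::2]
    tars = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        window = depth[s:e]
        tars.append(
            TAR(
                id=f"{chromosome}:TAR{i}",
                chromosome=chromosome,
                start=int(s),
                end=int(e),
                min_coverage=int(window.min()),
                mean_coverage=float(window.mean()),
            )
        )
    return tars


def intergenic_regions(annotation: GenomeAnnotation, buffer_bp: int = 200) -> dict[str, list[tuple[int, int]]]:
    """Intergenic space with a buffer on the gene side of every boundary.

    Between adjacent gene spans [a,b) and [c,d) the intergenic interval is
    [b+buffer, c-buffer), kept only when positive-length (i.e. the gap
    exceeds 2*buffer).  Chromosome-end flanks are included, buffered only
    on the gene side.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in annotation.chromosomes.items():
        genes = annotation.genes_on(chrom)
        regions: list[tuple[int, int]] = []
        if not genes:
            regions.append((0, length))
        else:
            # merge overlapping gene spans so nested genes do not create
            # spurious "intergenic" space
            spans: list[list[int]] = []
            for g in genes:
                if spans and g.start <= spans[-1][1]:
                    spans[-1][1] = max(spans[-1][1], g.end)
                else:
                    spans.append([g.start, g.end])
            first_start, last_end = spans[0][0], spans[-1][1]
            if first_start - buffer_bp > 0:
                regions.append((0, first_start - buffer_bp))
            for (_, b), (c, _) in zip(spans, spans[1:]):
                if c - b > 2 * buffer_bp:
                    regions.append((b + buffer_bp, c - buffer_bp))
            if last_end + buffer_bp < length:
                regions.append((last_end + buffer_bp, length))
        out[chrom] = regions
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _tars_hit(record: AlignmentRecord, starts: list[int], tars: list[TAR]) -> set[int]:
    hit: set[int] = set()
    for bs, be in record.blocks:
        i = bisect_right(starts, bs)
        # TARs are disjoint and sorted; any TAR overlapping [bs,be) has
        # start < be and end > bs
        j = max(i - 1, 0)
        while j < len(tars) and tars[j].start < be:
            if tars[j].end > bs:
                hit.add(j)
            j += 1
    return hit


def join_tars(
    tars: list[TAR],
    read_pairs: list[tuple[AlignmentRecord, AlignmentRecord]],
) -> list[TranscriptUnit]:
    """Connect TARs linked by at least one paired-end read into units.

    A pair links every TAR touched by either mate (a spliced mate can
    touch two).  Mates falling in no TAR link nothing.  Singleton TARs
    become singleton units.
    """
    by_chrom: dict[str, list[int]] = {}
    for idx, tar in enumerate(tars):
        by_chrom.setdefault(tar.chromosome, []).append(idx)
    starts_by_chrom = {
        chrom: [tars[i].start for i in idxs] for chrom, idxs in by_chrom.items()
    }

    uf = _UnionFind(len(tars))
    for r1, r2 in read_pairs:
        touched: list[int] = []
        for rec in (r1, r2):
            idxs = by_chrom.get(rec.chromosome)
            if not idxs:
                continue
            local = _tars_hit(
                rec, starts_by_chrom[rec.chromosome], [tars[i] for i in idxs]
            )
            touched.extend(idxs[k] for k in local)
        for a, b in zip(touched, touched[1:]):
            if tars[a].chromosome == tars[b].chromosome:
                uf.union(a, b)

    components: dict[int, list[int]] = {}
    for idx in range(len(tars)):
        components.setdefault(uf.find(idx), []).append(idx)

    units = []
    for n, members in enumerate(sorted(components.values(), key=lambda m: (tars[m[0]].chromosome, tars[m[0]].start))):
        members.sort(key=lambda i: tars[i].start)
        mtars = [tars[i] for i in members]
        total_len = sum(t.length for t in mtars)
        mean_cov = sum(t.mean_coverage * t.length for t in mtars) / total_len
        units.append(
            TranscriptUnit(
                id=f"TU{n}",
                chromosome=mtars[0].chromosome,
                tar_ids=tuple(t.id for t in mtars),
                start=min(t.start for t in mtars),
                end=max(t.end for t in mtars),
                total_length=total_len,
                mean_coverage=mean_cov,
                n_blocks=len(mtars),
            )
        )
    return units


def call_novel_tus(
    units: list[TranscriptUnit],
    annotation: GenomeAnnotation,
    intergenic: dict[str, list[tuple[int, int]]],
    min_length: int = 150,
    min_mean_coverage: float = 2.0,
) -> list[NovelTU]:
    """Apply the four novelty filters; only units passing all four return.

    (i) no overlap with any annotated gene span, (ii) span inside an
    intergenic interval, (iii) total mapped length >= min_length,
    (iv) mean coverage over member bases >= min_mean_coverage.  The
    filters commute, so their order is irrelevant.
    """
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes.values():
        gene_spans.setdefault(gene.chromosome, []).append((gene.start, gene.end))
    for chrom in gene_spans:
        gene_spans[chrom].sort()

    novel = []
    for unit in units:
        spans = gene_spans.get(unit.chromosome, [])
        no_overlap = not any(s < unit.end and e > unit.start for s, e in spans)
        inter = intergenic.get(unit.chromosome, [])
        inside = any(s <= unit.start and unit.end <= e for s, e in inter)
        long_enough = unit.total_length >= min_length
        covered = unit.mean_coverage >= min_mean_coverage
        if no_overlap and inside and long_enough and covered:
            novel.append(
                NovelTU(
                    unit=unit,
                    intergenic=inside,
                    no_gene_overlap=no_overlap,
                    min_length=long_enough,
                    min_mean_coverage=covered,
                )
            )
    return novel


def refine_boundaries(
    annotation: GenomeAnnotation,
    tars: list[TAR],
    read_pairs: list[tuple[AlignmentRecord, AlignmentRecord]] | None = None,
    require_pair_link: bool = False,
) -> list[GeneExtension]:
    """Extend annotated gene boundaries from TARs over terminal exons.

    A TAR overlapping a gene's terminal exon and protruding beyond the
    annotated span yields an extension at that end, labelled 5'/3' by
    strand.  When several TARs protrude at one end the longest protrusion
    is reported.  With ``require_pair_link`` a protruding TAR must
    additionally be pair-connected to a TAR overlapping the gene body.
    """
    by_chrom: dict[str, list[TAR]] = {}
    for tar in tars:
        by_chrom.setdefault(tar.chromosome, []).append(tar)

    linked: dict[str, set[str]] = {}
    if require_pair_link and read_pairs:
        units = join_tars(tars, read_pairs)
        for unit in units:
            for tid in unit.tar_ids:
                linked[tid] = set(unit.tar_ids)

    extensions = []
    for gene in sorted(annotation.genes.values(), key=lambda g: (g.chromosome, g.start)):
        union = annotation.exon_union(gene.id)
        if not union:
            continue
        left_exon, right_exon = union[0], union[-1]
        candidates = by_chrom.get(gene.chromosome, [])

        def body_linked(tar: TAR) -> bool:
            if not require_pair_link:
                return True
            group = linked.get(tar.id, {tar.id})
            for other in candidates:
                if other.id in group and other.start < gene.end and other.end > gene.start:
                    if other.id != tar.id or (tar.start < gene.end and tar.end > gene.start):
                        return True
            return False

        best_left = best_right = None
        for tar in candidates:
            if tar.start < left_exon[1] and tar.end > left_exon[0] and tar.start < gene.start:
                if body_linked(tar) and (best_left is None or tar.start < best_left.start):
                    best_left = tar
            if tar.start < right_exon[1] and tar.end > right_exon[0] and tar.end > gene.end:
                if body_linked(tar) and (best_right is None or tar.end > best_right.end):
                    best_right = tar
        if best_left is not None:
            label = "5p" if gene.strand == "+" else "3p"
            extensions.append(GeneExtension(gene.id, label, gene.start - best_left.start, best_left.id))
        if best_right is not None:
            label = "3p" if gene.strand == "+" else "5p"
            extensions.append(GeneExtension(gene.id, label, best_right.end - gene.end, best_right.id))
    return extensions


def count_tar_support(tars: list[TAR], records: list[AlignmentRecord]) -> None:
    """Fill each TAR's supporting unique-read count in place."""
    for tar in tars:
        tar.support = 0
    by_chrom: dict[str, list[TAR]] = {}
    for tar in tars:
        by_chrom.setdefault(tar.chromosome, []).append(tar)
    for chrom, chrom_tars in by_chrom.items():
        chrom_tars.sort(key=lambda t: t.start)
        starts = [t.start for t in chrom_tars]
        for rec in records:
            if rec.multiplicity != UNIQUE or rec.chromosome != chrom:
                continue
            for idx in _tars_hit(rec, starts, chrom_tars):
                chrom_tars[idx].support += 1
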