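"""Standard-format I/O and the shared coordinate conventions.

Every stage of the pipeline speaks 0-based half-open coordinates
internally; conversion to/from the 1-based closed conventions of GTF and
VCF happens only here, at the file boundary.  SAM parsing is delegated to
pysam; the other text formats are simple enough to emit directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"

_CHROM_LEN_PRAGMA = "#!chromosome-length"


class FormatError(ValueError):
    """A file violated the expectations of its declared format."""


@dataclass(frozen=True)
class Gene:
    """An annotated gene: the span covers all exons of all its transcripts."""

    id: str
    chromosome: str
    strand: str  # "+" or "-"
    start: int   # 0-based half-open span over all exons
    end: int


@dataclass(frozen=True)
class Transcript:
    id: str
    gene_id: str
    exons: tuple[tuple[int, int], ...]  # ordered, non-overlapping, half-open

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in genomic coordinates."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class GenomeAnnotation:
    """Genes -> transcripts -> exons plus chromosome lengths.

    The coordinate backbone for every downstream stage.  ``validate``
    enforces the structural invariants; readers call it before returning.
    """

    chromosomes: dict[str, int] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def validate(self) -> None:
        for tx in self.transcripts.values():
            if tx.gene_id not in self.genes:
                raise FormatError(f"transcript {tx.id} references unknown gene {tx.gene_id}")
            gene = self.genes[tx.gene_id]
            if gene.chromosome not in self.chromosomes:
                raise FormatError(f"gene {gene.id} on undeclared chromosome {gene.chromosome}")
            length = self.chromosomes[gene.chromosome]
            prev_end = -1
            for s, e in tx.exons:
                if not (0 <= s < e <= length):
                    raise FormatError(
                        f"exon [{s},{e}) of {tx.id} outside chromosome "
                        f"{gene.chromosome} (length {length})"
                    )
                if s < prev_end:
                    raise FormatError(f"exons of {tx.id} overlap or are unsorted")
                prev_end = e

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def genes_on(self, chromosome: str) -> list[Gene]:
        """Genes on one chromosome, sorted by span start."""
        return sorted(
            (g for g in self.genes.values() if g.chromosome == chromosome),
            key=lambda g: (g.start, g.end),
        )

    def exon_union(self, gene_id: str) -> list[tuple[int, int]]:
        """Merged exon intervals over all transcripts of a gene."""
        exons = sorted(
            e for t in self.transcripts_of(gene_id) for e in t.exons
        )
        merged: list[tuple[int, int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def exon_model_length(self, gene_id: str) -> int:
        return sum(e - s for s, e in self.exon_union(gene_id))


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment in internal coordinates.

    ``blocks`` are the gapless aligned stretches; gaps between consecutive
    blocks are splice gaps (SAM ``N``).  Unmapped records carry no blocks.
    """

    read_id: str
    chromosome: str | None
    strand: str
    blocks: tuple[tuple[int, int], ...]
    mismatches: int
    multiplicity: str  # UNIQUE | MULTI | UNMAPPED
    mate_id: str | None
    bases: str
    qualities: tuple[int, ...]

    @property
    def qname(self) -> str:
        return self.read_id.rsplit("/", 1)[0]

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def _merge_adjacent(blocks: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


# ---------------------------------------------------------------------------
# GTF

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise FormatError(f"GTF line {lineno}: malformed attribute {chunk!r}")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path, chromosome_lengths: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Parse exon features of a GTF file into a :class:`GenomeAnnotation`.

    GTF is 1-based closed; intervals are converted to 0-based half-open.
    Chromosome lengths come from (in order of precedence) the
    ``chromosome_lengths`` argument, ``#!chromosome-length NAME LEN``
    header pragmas as written by :func:`write_gtf`, or, failing both, the
    maximum exon end seen on each chromosome.
    """
    chrom_lengths: dict[str, int] = dict(chromosome_lengths or {})
    pragma_lengths: dict[str, int] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # transcript -> (chrom, strand)

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if line.startswith(_CHROM_LEN_PRAGMA):
                try:
                    _, name, length = line.split()
                    pragma_lengths[name] = int(length)
                except ValueError:
                    raise FormatError(f"GTF line {lineno}: malformed chromosome-length pragma")
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"GTF line {lineno}: non-integer coordinates")
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"GTF line {lineno}: invalid interval {start}-{end}")
            attrs = _parse_gtf_attributes(attr_text, lineno)
            try:
                gene_id, tx_id = attrs["gene_id"], attrs["transcript_id"]
            except KeyError as exc:
                raise FormatError(f"GTF line {lineno}: missing attribute {exc}")
            exons.setdefault(tx_id, []).append((start_i - 1, end_i))
            tx_gene[tx_id] = gene_id
            tx_meta[tx_id] = (chrom, strand)

    if not chrom_lengths:
        chrom_lengths = pragma_lengths
    annotation = GenomeAnnotation(chromosomes=dict(chrom_lengths))
    gene_bounds: dict[str, list[int]] = {}
    for tx_id, ivals in exons.items():
        ivals.sort()
        chrom, strand = tx_meta[tx_id]
        gene_id = tx_gene[tx_id]
        annotation.transcripts[tx_id] = Transcript(tx_id, gene_id, tuple(ivals))
        bounds = gene_bounds.setdefault(gene_id, [ivals[0][0], ivals[-1][1]])
        bounds[0] = min(bounds[0], ivals[0][0])
        bounds[1] = max(bounds[1], ivals[-1][1])
        if chrom not in annotation.chromosomes:
            annotation.chromosomes[chrom] = 0
        if not pragma_lengths and chromosome_lengths is None:
            annotation.chromosomes[chrom] = max(annotation.chromosomes[chrom], ivals[-1][1])
        annotation.genes[gene_id] = Gene(gene_id, chrom, strand, *bounds)
    annotation.validate()
    return annotation


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Emit exon features (1-based closed) plus chromosome-length pragmas."""
    with open(path, "w") as out:
        for name in sorted(annotation.chromosomes):
            out.write(f"{_CHROM_LEN_PRAGMA} {name} {annotation.chromosomes[name]}\n")
        for tx in sorted(annotation.transcripts.values(), key=lambda t: (t.gene_id, t.id)):
            gene = annotation.genes[tx.gene_id]
            for i, (s, e) in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{gene.id}"; transcript_id "{tx.id}"; '
                    f'exon_number "{i}";'
                )
                out.write(
                    f"{gene.chromosome}\tbovtx\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# SAM

def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse a SAM file into :class:`AlignmentRecord` objects.

    CIGAR M/=/X consume aligned blocks, N opens a splice gap, soft clips
    are ignored for blocks.  Multiplicity comes from the unmapped flag and
    the NH tag (NH > 1 -> multi).  Mates are linked by query name with a
    ``/1`` / ``/2`` suffix distinguishing the two reads of a pair.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        header_refs = set(sam.references)
        for aln in sam:
            suffix = "/2" if aln.is_read2 else "/1"
            read_id = aln.query_name + suffix
            mate_id = None
            if aln.is_paired:
                mate_id = aln.query_name + ("/1" if aln.is_read2 else "/2")
            quals = tuple(aln.query_qualities) if aln.query_qualities is not None else ()
            bases = aln.query_sequence or ""
            if aln.is_unmapped:
                records.append(
                    AlignmentRecord(read_id, None, "+", (), 0, UNMAPPED, mate_id, bases, quals)
                )
                continue
            if aln.reference_name not in header_refs:
                raise FormatError(
                    f"record {aln.query_name} references chromosome "
                    f"{aln.reference_name} absent from header"
                )
            blocks = _merge_adjacent([tuple(b) for b in aln.get_blocks()])
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    read_id,
                    aln.reference_name,
                    "-" if aln.is_reverse else "+",
                    blocks,
                    int(nm),
                    MULTI if nh > 1 else UNIQUE,
                    mate_id,
                    bases,
                    quals,
                )
            )
    return records


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    cigar: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            cigar.append((3, gap))  # N
        cigar.append((0, e - s))  # M
    return cigar


def write_sam(records: Iterable[AlignmentRecord], path: str | Path, chromosomes: Mapping[str, int]) -> None:
    """Write records as a text SAM with the given reference header.

    Output is byte-deterministic for a fixed record order, which is what
    lets identical simulator seeds produce identical files.
    """
    names = sorted(chromosomes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(chromosomes[n])} for n in names],
    }
    ref_index = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.query_sequence = rec.bases or None
            if rec.qualities:
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in rec.qualities)
                )
            flag = 0
            if rec.mate_id is not None:
                flag |= 0x1
                flag |= 0x40 if rec.read_id.endswith("/1") else 0x80
            if rec.multiplicity == UNMAPPED:
                flag |= 0x4
                a.flag = flag
                out.write(a)
                continue
            if rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            a.reference_id = ref_index[rec.chromosome]
            a.reference_start = rec.blocks[0][0]
            a.mapping_quality = 0 if rec.multiplicity == MULTI else 60
            a.cigar = _blocks_to_cigar(rec.blocks)
            a.set_tag("NM", int(rec.mismatches))
            a.set_tag("NH", 2 if rec.multiplicity == MULTI else 1)
            out.write(a)


def pair_records(records: Iterable[AlignmentRecord]) -> list[tuple[AlignmentRecord, AlignmentRecord]]:
    """Group mapped mates into pairs by query name; orphans are dropped."""
    by_id: dict[str, AlignmentRecord] = {}
    pairs: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    for rec in records:
        if rec.mate_id is None or rec.multiplicity == UNMAPPED:
            continue
        mate = by_id.pop(rec.mate_id, None)
        if mate is None:
            by_id[rec.read_id] = rec
        else:
            pairs.append((mate, rec))
    return pairs


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    with pysam.FastxFile(str(path)) as fx:
        return {entry.name: entry.sequence.upper() for entry in fx}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name in sorted(sequences):
            out.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / VCF / TSV

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    rows = sorted(intervals, key=lambda r: (str(r[0]), int(r[1]), int(r[2])))
    with open(path, "w") as out:
        for row in rows:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            if end <= start:
                raise FormatError(f"empty or inverted BED interval [{start},{end}) on {chrom}")
            name = f"\t{row[3]}" if len(row) > 3 else ""
            out.write(f"{chrom}\t{start}\t{end}{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {lineno}: fewer than 3 columns")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=q{min_qual},Description="Consensus quality below {min_qual}">
##FILTER=<ID=alt{min_alt},Description="Fewer than {min_alt} unique reads supporting the alternate allele">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Consensus (genotype) quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample
"""


def write_vcf(snps: Iterable, path: str | Path, min_qual: int = 20, min_alt: int = 2) -> None:
    """Write SNP calls (1-based POS) to a minimal single-sample VCF.

    ``snps`` are objects with ``chromosome, position (0-based), ref,
    genotype, quality, alt_support, depth, passed, reasons`` attributes.
    """
    calls = sorted(snps, key=lambda s: (s.chromosome, s.position))
    with open(path, "w") as out:
        out.write(_VCF_HEADER.format(min_qual=min_qual, min_alt=min_alt))
        for snp in calls:
            alts = sorted(set(snp.genotype) - {snp.ref})
            alt_field = ",".join(alts) if alts else "."
            allele_index = {snp.ref: 0}
            for i, a in enumerate(alts, start=1):
                allele_index[a] = i
            gt = "/".join(str(allele_index[a]) for a in sorted(snp.genotype))
            filt = "PASS" if snp.passed else ";".join(snp.reasons)
            out.write(
                f"{snp.chromosome}\t{snp.position + 1}\t.\t{snp.ref}\t{alt_field}\t"
                f"{snp.quality:.0f}\t{filt}\tDP={snp.depth}\tGT:GQ:DP\t"
                f"{gt}:{snp.quality:.0f}:{snp.depth}\n"
            )


def read_vcf(path: str | Path) -> list[dict]:
    """Strict re-parse of the VCFs this module writes (for round trips)."""
    rows = []
    with open(path) as handle:
        saw_header = False
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise FormatError(f"VCF line {lineno}: data before #CHROM header")
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 10:
                raise FormatError(f"VCF line {lineno}: expected 10 columns")
            pos = int(fields[1])
            if pos < 1:
                raise FormatError(f"VCF line {lineno}: POS must be >= 1")
            rows.append(
                {
                    "chromosome": fields[0],
                    "position": pos - 1,
                    "ref": fields[3],
                    "alt": fields[4],
                    "qual": float(fields[5]),
                    "filter": fields[6],
                }
            )
    return rows


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
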