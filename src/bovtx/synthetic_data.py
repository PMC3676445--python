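"""Synthetic genome, annotation and spliced paired-end alignments.

The generator emulates a two-condition ("emb135" embryonic vs
"adult30m" adult) bulk RNA-seq experiment on a toy multi-gene genome:
per-gene fragment counts are Poisson (the same sampling model the exact
count test assumes), reads are 90 bp paired-end from ~300 bp fragments,
and the emitted SAM carries planted truth for every downstream stage —
intergenic novel transcript units, alternative-splicing events of the
four analysed types, variant sites, and unique/multi/unmapped read
categories.  Identical seed and config give byte-identical output.

What it does NOT model: GC or fragment bias, empirical error profiles,
RNA amplification or pooling variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    MULTI,
    UNIQUE,
    UNMAPPED,
    AlignmentRecord,
    Gene,
    GenomeAnnotation,
    Transcript,
    write_fasta,
    write_gtf,
    write_sam,
    write_tsv,
)
from .splicing import A3SS, A5SS, ES, IR

CONDITIONS = ("emb135", "adult30m")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """The stated world of the simulation.

    Defaults mirror the emulated study design where it states one:
    90 bp reads (the mapping table's base-pair totals divided by read
    counts), ~300 bp fragments (a ~200-bp gel cut from 200-700 nt RNA
    fragments), ~4% multi-mapped and ~21% unmapped reads and ~23%
    mismatch-carrying mapped reads (the mapping table's category shares),
    and base quality Q30 with error rate 10^(-Q/10).
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (120_000,)
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (150, 400)
    mean_fragments_per_gene: float = 60.0
    target_coverage: float | None = None  # overrides the fragment mean with
    # transcript-length-scaled means delivering this exonic depth uniformly
    fold_changes: dict[str, float] = field(default_factory=dict)  # gene -> emb135/adult30m ratio
    n_novel_tus: int = 8
    novel_tu_length: tuple[int, int] = (300, 800)
    novel_tu_depth: float = 10.0
    as_events: dict[str, int] = field(
        default_factory=lambda: {ES: 2, IR: 2, A5SS: 2, A3SS: 2}
    )
    as_support: int = 6
    n_variants: int = 10
    het_fraction: float = 0.5
    multi_fraction: float = 0.04
    unmapped_fraction: float = 0.21
    mismatch_fraction: float = 0.23
    read_length: int = 90
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    base_quality: int = 30
    error_rate: float | None = None  # None -> 10^(-base_quality/10)

    def __post_init__(self) -> None:
        for name in ("multi_fraction", "unmapped_fraction", "mismatch_fraction", "het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.multi_fraction + self.unmapped_fraction > 1.0:
            raise ValueError("multiplicity fractions must sum to at most 1")
        for name in ("read_length", "n_genes", "mean_fragments_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.exon_length[0] < self.read_length // 2:
            raise ValueError(
                "shortest exon must accommodate a junction anchor of half a read"
            )

    @property
    def effective_error_rate(self) -> float:
        if self.error_rate is not None:
            return self.error_rate
        return 10.0 ** (-self.base_quality / 10.0)


@dataclass
class TruthTables:
    """Planted ground truth, reconstructible from the emitted alignments."""

    gene_counts: pd.DataFrame          # index gene; columns: one per condition (drawn fragment counts)
    novel_tus: list[tuple[str, int, int, str]]   # (chrom, start, end, id)
    as_events: list[dict]              # type, gene, junctions/interval
    variants: list[dict]               # chrom, pos, ref, alt, genotype
    read_categories: dict[str, dict[str, str]]   # condition -> qname -> unique|multi|unmapped
    mismatch_reads: dict[str, set]     # condition -> qnames with planted mismatches


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    records: dict[str, list[AlignmentRecord]]  # per condition
    truth: TruthTables

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gtf(self.annotation, outdir / "genes.gtf")
        for cond in CONDITIONS:
            write_sam(self.records[cond], outdir / f"{cond}.sam", self.annotation.chromosomes)
        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        write_tsv(self.truth.gene_counts.reset_index(names="gene"), truth_dir / "gene_counts.tsv")
        write_tsv(
            pd.DataFrame(self.truth.novel_tus, columns=["chrom", "start", "end", "id"]),
            truth_dir / "novel_tus.tsv",
        )
        write_tsv(pd.DataFrame(self.truth.as_events), truth_dir / "as_events.tsv")
        write_tsv(pd.DataFrame(self.truth.variants), truth_dir / "variants.tsv")


# ---------------------------------------------------------------------------
# genome

def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenomeAnnotation, list[tuple[str, int, int]]]:
    """Random genome + gene annotation + reserved novel-TU intervals.

    Genes are laid out left to right with gaps comfortably above the
    400 bp double-buffer; every other sufficiently wide gap hosts one of
    the reserved intergenic intervals (60 bp clear of each 200 bp
    buffer) where planted novel transcript units will be expressed.
    """
    rng = np.random.default_rng([config.seed, 0])
    annotation = GenomeAnnotation(
        chromosomes={f"chr{i + 1}": int(l) for i, l in enumerate(config.chromosome_lengths)}
    )
    chrom_names = sorted(annotation.chromosomes)
    tu_slots: list[tuple[str, int, int]] = []

    genes_placed = 0
    tu_placed = 0
    chrom_iter = iter(chrom_names)
    chrom = next(chrom_iter)
    cursor = 300
    margin = 260  # 200 bp buffer + 60 bp clearance inside the intergenic space
    while genes_placed < config.n_genes:
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_exons)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, max(n_exons - 1, 0))
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"

        tu_deficit = (config.n_novel_tus - tu_placed) >= (config.n_genes - genes_placed)
        want_tu = tu_placed < config.n_novel_tus and (genes_placed % 2 == 1 or tu_deficit)
        tu_len = int(rng.integers(*config.novel_tu_length)) if want_tu else 0
        tail_room = (2 * margin + tu_len) if want_tu else 500
        if cursor + gene_len + tail_room + 300 > annotation.chromosomes[chrom]:
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise ValueError(
                    f"cannot fit {config.n_genes} genes into chromosomes "
                    f"{config.chromosome_lengths}"
                )
            cursor = 300
            continue

        gene_id = f"G{genes_placed:03d}"
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        annotation.genes[gene_id] = Gene(gene_id, chrom, strand, exons[0][0], exons[-1][1])
        annotation.transcripts[f"T{genes_placed:03d}"] = Transcript(
            f"T{genes_placed:03d}", gene_id, tuple(exons)
        )
        cursor = exons[-1][1]
        genes_placed += 1

        if want_tu:
            tu_start = cursor + margin
            tu_slots.append((chrom, tu_start, tu_start + tu_len))
            tu_placed += 1
            cursor = tu_start + tu_len + margin
        else:
            cursor += int(rng.integers(500, 900))

    genome = {
        name: "".join(rng.choice(_BASES, size=length))
        for name, length in sorted(annotation.chromosomes.items())
    }
    annotation.validate()
    return genome, annotation, tu_slots


# ---------------------------------------------------------------------------
# transcript coordinate helpers

def _tx_blocks(exons: tuple[tuple[int, int], ...], start: int, end: int) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate interval [start,end) onto genomic blocks."""
    blocks = []
    off = 0
    for es, ee in exons:
        elen = ee - es
        lo, hi = max(start - off, 0), min(end - off, elen)
        if lo < hi:
            blocks.append((es + lo, es + hi))
        off += elen
        if off >= end:
            break
    return tuple(blocks)


def _read_sequence(
    genome_seq: str,
    blocks: tuple[tuple[int, int], ...],
    variant_map: dict[int, str],
) -> str:
    parts = []
    for s, e in blocks:
        seg = list(genome_seq[s:e])
        for pos, alt in variant_map.items():
            if s <= pos < e:
                seg[pos - s] = alt
        parts.append("".join(seg))
    return "".join(parts)


# ---------------------------------------------------------------------------
# alignments

def _plan_variants(config: SimulationConfig, genome, annotation, rng) -> list[dict]:
    variants = []
    taken: set[tuple[str, int]] = set()
    gene_ids = sorted(annotation.genes)
    if not gene_ids:
        return variants
    rl = config.read_length
    for v in range(config.n_variants):
        gene = annotation.genes[gene_ids[v % len(gene_ids)]]
        tx = annotation.transcripts_of(gene.id)[0]
        positions = np.concatenate([np.arange(s, e) for s, e in tx.exons])
        # keep variants a read length clear of the transcript ends, where
        # fragment geometry thins the coverage below its nominal depth
        if positions.size > 2 * rl:
            positions = positions[rl:-rl]
        for _ in range(50):
            pos = int(rng.choice(positions))
            if (gene.chromosome, pos) not in taken:
                break
        else:
            continue
        taken.add((gene.chromosome, pos))
        ref = genome[gene.chromosome][pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        genotype = "het" if rng.random() < config.het_fraction else "hom"
        variants.append(
            {"chrom": gene.chromosome, "pos": pos, "ref": ref, "alt": alt,
             "genotype": genotype, "gene": gene.id}
        )
    return sorted(variants, key=lambda v: (v["chrom"], v["pos"]))


def _plan_as_events(config: SimulationConfig, annotation, rng) -> list[dict]:
    """Choose host genes and alternative junctions for each planted event."""
    plans: list[dict] = []
    used_genes: set[str] = set()
    txs = sorted(annotation.transcripts.values(), key=lambda t: t.id)
    shift = 12  # bp offset of the alternative splice boundary

    def pick(min_exons: int):
        for tx in txs:
            if tx.gene_id not in used_genes and len(tx.exons) >= min_exons:
                used_genes.add(tx.gene_id)
                return tx
        return None

    for ev_type in (ES, IR, A5SS, A3SS):
        for _ in range(config.as_events.get(ev_type, 0)):
            tx = pick(3)
            if tx is None:
                break
            gene = annotation.genes[tx.gene_id]
            introns = tx.introns()
            if ev_type == ES:
                i = int(rng.integers(1, len(tx.exons) - 1))  # internal exon index
                plan = {
                    "type": ES,
                    "gene": tx.gene_id,
                    "exon": tx.exons[i],
                    "alt_junction": (tx.exons[i - 1][1], tx.exons[i + 1][0]),
                    "annotated_junctions": (introns[i - 1], introns[i]),
                }
            elif ev_type == IR:
                j = int(rng.integers(0, len(introns)))
                plan = {
                    "type": IR,
                    "gene": tx.gene_id,
                    "intron": introns[j],
                    "annotated_junctions": (introns[j],),
                    "alt_junction": None,
                }
            else:
                j = int(rng.integers(0, len(introns)))
                donor, acceptor = introns[j]
                # the transcript-5' boundary is the donor on +, acceptor on -
                vary_donor = (ev_type == A5SS) == (gene.strand == "+")
                if vary_donor:
                    alt = (donor - shift, acceptor)
                else:
                    alt = (donor, acceptor + shift)
                plan = {
                    "type": ev_type,
                    "gene": tx.gene_id,
                    "alt_junction": alt,
                    "annotated_junctions": (introns[j],),
                }
            plans.append(plan)
    return plans


def simulate_alignments(
    config: SimulationConfig,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    tu_slots: list[tuple[str, int, int]],
) -> tuple[dict[str, list[AlignmentRecord]], TruthTables]:
    """Emit per-condition alignment records plus the full truth tables.

    Gene-expression fragments draw their multiplicity category
    (unique/multi/unmapped) and mismatch status at the configured
    fractions; planted evidence reads (novel-TU coverage, AS junction
    support, intron-retention coverage) are always unique and clean so
    that planted truth is recoverable by construction.
    """
    rng = np.random.default_rng([config.seed, 1])
    rl = config.read_length
    err = config.effective_error_rate
    qual = tuple([config.base_quality] * rl)

    variants = _plan_variants(config, genome, annotation, rng)
    var_by_chrom: dict[str, dict[int, dict]] = {}
    hom_by_chrom: dict[str, dict[int, str]] = {}
    for v in variants:
        var_by_chrom.setdefault(v["chrom"], {})[v["pos"]] = v
        if v["genotype"] == "hom":
            hom_by_chrom.setdefault(v["chrom"], {})[v["pos"]] = v["alt"]
    as_plans = _plan_as_events(config, annotation, rng)

    gene_ids = sorted(annotation.genes)
    counts = {cond: {} for cond in CONDITIONS}
    records: dict[str, list[AlignmentRecord]] = {cond: [] for cond in CONDITIONS}
    categories: dict[str, dict[str, str]] = {cond: {} for cond in CONDITIONS}
    mismatch_reads: dict[str, set] = {cond: set() for cond in CONDITIONS}

    def emit_pair(cond, qname, chrom, blocks1, blocks2, var_map, category, planted_mm):
        seq = genome[chrom]
        recs = []
        for suffix, blocks, strand in (("/1", blocks1, "+"), ("/2", blocks2, "-")):
            bases = _read_sequence(seq, blocks, var_map)
            barr = np.frombuffer(bases.encode(), dtype="S1").astype("U1")
            if err > 0:
                flip = rng.random(len(barr)) < err
                if flip.any():
                    repl = rng.choice(_BASES, size=int(flip.sum()))
                    # a "flipped" base may coincide with the original; that
                    # simply lowers the realised error rate slightly
                    barr[flip] = repl
            if planted_mm and suffix == "/1":
                k = int(rng.integers(1, 4))
                idx = rng.choice(len(barr), size=k, replace=False)
                for i in idx:
                    ref_b = bases[i]
                    barr[i] = str(rng.choice([b for b in "ACGT" if b != ref_b]))
            final = "".join(barr)
            # mismatches against the *reference* (variant alleles count too)
            nm = 0
            off = 0
            for s, e in blocks:
                ref_seg = seq[s:e]
                nm += sum(1 for a, b in zip(final[off : off + e - s], ref_seg) if a != b)
                off += e - s
            if category == UNMAPPED:
                recs.append(
                    AlignmentRecord(qname + suffix, None, "+", (), 0, UNMAPPED,
                                    qname + ("/2" if suffix == "/1" else "/1"), final, qual)
                )
            else:
                recs.append(
                    AlignmentRecord(
                        qname + suffix, chrom, strand, blocks, nm, category,
                        qname + ("/2" if suffix == "/1" else "/1"), final, qual,
                    )
                )
        records[cond].extend(recs)

    # ---- gene expression fragments -----------------------------------
    for cond in CONDITIONS:
        for g, gene_id in enumerate(gene_ids):
            tx = annotation.transcripts[f"T{g:03d}"]
            gene = annotation.genes[gene_id]
            fold = config.fold_changes.get(gene_id, 1.0)
            if config.target_coverage is not None:
                base_mean = config.target_coverage * tx.length / (2 * rl)
            else:
                base_mean = config.mean_fragments_per_gene
            mean = base_mean * (fold if cond == "emb135" else 1.0)
            n_frag = int(rng.poisson(mean))
            counts[cond][gene_id] = n_frag
            tlen = tx.length
            if tlen < rl:
                raise ValueError(f"read length {rl} exceeds transcript length of {gene_id}")
            chrom_vars = var_by_chrom.get(gene.chromosome, {})
            for i in range(n_frag):
                flen = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd), rl, tlen))
                start = int(rng.integers(0, tlen - flen + 1))
                blocks1 = _tx_blocks(tx.exons, start, start + rl)
                blocks2 = _tx_blocks(tx.exons, start + flen - rl, start + flen)
                u = rng.random()
                if u < config.unmapped_fraction:
                    category = UNMAPPED
                elif u < config.unmapped_fraction + config.multi_fraction:
                    category = MULTI
                else:
                    category = UNIQUE
                planted_mm = category != UNMAPPED and rng.random() < config.mismatch_fraction
                var_map: dict[int, str] = {}
                for pos, v in chrom_vars.items():
                    if v["genotype"] == "hom" or rng.random() < 0.5:
                        var_map[pos] = v["alt"]
                qname = f"{cond}.{gene_id}.f{i:05d}"
                categories[cond][qname] = category
                if planted_mm:
                    mismatch_reads[cond].add(qname)
                emit_pair(cond, qname, gene.chromosome, blocks1, blocks2, var_map, category, planted_mm)

    # ---- planted novel transcript units ------------------------------
    novel_truth = []
    for k, (chrom, tu_start, tu_end) in enumerate(tu_slots):
        tu_id = f"NTU{k:02d}"
        novel_truth.append((chrom, tu_start, tu_end, tu_id))
        tu_len = tu_end - tu_start
        flen = min(tu_len, 2 * rl)
        step = max(1, int(2 * rl / config.novel_tu_depth))
        starts = sorted(set(range(0, tu_len - flen + 1, step)) | {tu_len - flen})
        # duplicate the terminal fragments so the very first and last bases
        # of the unit reach the depth-2 floor like every interior base
        starts += [0, tu_len - flen]
        for cond in CONDITIONS:
            for i, s in enumerate(starts):
                blocks1 = ((tu_start + s, tu_start + s + rl),)
                blocks2 = ((tu_start + s + flen - rl, tu_start + s + flen),)
                emit_pair(cond, f"{cond}.{tu_id}.f{i:05d}", chrom, blocks1, blocks2, {}, UNIQUE, False)

    # ---- planted AS evidence reads -----------------------------------
    as_truth = []
    anchor = rl // 2
    for n, plan in enumerate(as_plans):
        gene = annotation.genes[plan["gene"]]
        chrom = gene.chromosome
        junctions = list(plan["annotated_junctions"])
        if plan["alt_junction"] is not None:
            junctions.append(plan["alt_junction"])
        as_truth.append(
            {
                "type": plan["type"],
                "gene": plan["gene"],
                "detail": plan.get("exon") or plan.get("intron") or plan["alt_junction"],
                "alt_junction": plan["alt_junction"],
                "intron": plan.get("intron"),
                "exon": plan.get("exon"),
            }
        )
        for cond in CONDITIONS:
            for j, (donor, acceptor) in enumerate(junctions):
                blocks = ((donor - anchor, donor), (acceptor, acceptor + (rl - anchor)))
                for i in range(config.as_support):
                    qname = f"{cond}.AS{n:02d}.j{j}.f{i:02d}"
                    # homozygous variant alleles appear on every haplotype,
                    # evidence reads included
                    bases = _read_sequence(genome[chrom], blocks, hom_by_chrom.get(chrom, {}))
                    nm = sum(1 for p in hom_by_chrom.get(chrom, {}) if any(s <= p < e for s, e in blocks))
                    records[cond].append(
                        AlignmentRecord(qname + "/1", chrom, "+", blocks, nm, UNIQUE, None, bases, qual)
                    )
            if plan["type"] == IR:
                istart, iend = plan["intron"]
                lo, hi = istart - 40, iend + 40
                step = max(1, rl // 3)
                tile = sorted(set(range(lo, hi - rl + 1, step)) | {hi - rl})
                for i, s in enumerate(tile):
                    blocks = ((s, s + rl),)
                    bases = _read_sequence(genome[chrom], blocks, hom_by_chrom.get(chrom, {}))
                    nm = sum(1 for p in hom_by_chrom.get(chrom, {}) if s <= p < s + rl)
                    records[cond].append(
                        AlignmentRecord(
                            f"{cond}.AS{n:02d}.ir.f{i:03d}/1", chrom, "+", blocks, nm,
                            UNIQUE, None, bases, qual,
                        )
                    )

    gene_counts = pd.DataFrame(counts, columns=list(CONDITIONS)).loc[gene_ids]
    gene_counts.index.name = "gene"
    truth = TruthTables(
        gene_counts=gene_counts,
        novel_tus=novel_truth,
        as_events=as_truth,
        variants=variants,
        read_categories=categories,
        mismatch_reads=mismatch_reads,
    )
    return records, truth


def simulate_dataset(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """End-to-end simulation; optionally writes FASTA/GTF/SAM/truth files."""
    genome, annotation, tu_slots = simulate_genome(config)
    records, truth = simulate_alignments(config, genome, annotation, tu_slots)
    dataset = SimulatedDataset(config, genome, annotation, records, truth)
    if outdir is not None:
        dataset.write(outdir)
    return dataset


def simulate_count_table(
    means_a,
    means_b,
    lengths=None,
    seed: int = 0,
    names=None,
):
    """Count-level Poisson simulation of a two-library experiment.

    Draws per-gene counts directly from the Poisson model the exact test
    assumes, skipping read emission; used for statistical calibration at
    scales where emitting SAM would be wasteful.  Returns a
    :class:`~bovtx.expression_de.GeneCountTable`.
    """
    from .expression_de import GeneCountTable

    rng = np.random.default_rng(seed)
    means_a = np.asarray(means_a, dtype=float)
    means_b = np.asarray(means_b, dtype=float)
    if means_a.shape != means_b.shape:
        raise ValueError("the two mean vectors must have equal length")
    n = means_a.size
    if names is None:
        names = [f"G{i:04d}" for i in range(n)]
    if lengths is None:
        lengths = np.full(n, 1000)
    counts_a = pd.Series(rng.poisson(means_a), index=names)
    counts_b = pd.Series(rng.poisson(means_b), index=names)
    return GeneCountTable.from_counts(
        counts_a, counts_b, pd.Series(np.asarray(lengths), index=names)
    )
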