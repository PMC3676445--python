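"""Convenience orchestration over the analysis stages.

Thin wrappers that wire the per-stage functions together for the common
"one SAM + one GTF in, results out" workflows used by the example
scripts; all scientific behaviour lives in the stage modules.
"""

from __future__ import annotations

import numpy as np

from . import snp_calling, splicing, transcript_discovery as td
from .expression_de import GeneCountTable, call_de, count_reads_per_gene
from .io_formats import UNIQUE, UNMAPPED, AlignmentRecord, GenomeAnnotation, pair_records


def coverage_by_chromosome(
    records: list[AlignmentRecord], annotation: GenomeAnnotation
) -> dict[str, np.ndarray]:
    return {
        chrom: td.compute_coverage(records, chrom, length)
        for chrom, length in sorted(annotation.chromosomes.items())
    }


def discover_novel_tus(
    records: list[AlignmentRecord],
    annotation: GenomeAnnotation,
    min_depth: int = 2,
    min_length: int = 150,
    min_mean_coverage: float = 2.0,
):
    """Coverage -> TARs -> paired-end joining -> intergenic novelty filters."""
    coverage = coverage_by_chromosome(records, annotation)
    tars = []
    for chrom, depth in coverage.items():
        tars.extend(td.detect_tars(depth, chromosome=chrom, min_depth=min_depth))
    pairs = pair_records(records)
    units = td.join_tars(tars, pairs)
    intergenic = td.intergenic_regions(annotation)
    novel = td.call_novel_tus(
        units, annotation, intergenic,
        min_length=min_length, min_mean_coverage=min_mean_coverage,
    )
    return novel, units, tars


def classify_all_as_events(
    records: list[AlignmentRecord],
    annotation: GenomeAnnotation,
    min_support: int = 2,
    min_depth: int = 2,
    min_anchor: int = 8,
):
    """Junction extraction, gene assignment and per-gene classification."""
    junctions = splicing.extract_junctions(records, min_anchor=min_anchor)
    by_gene = splicing.assign_junctions_to_genes(junctions, annotation)
    coverage = coverage_by_chromosome(records, annotation)
    events = []
    for gene_id in sorted(by_gene):
        gene = annotation.genes[gene_id]
        events.extend(
            splicing.classify_as_events(
                gene_id, by_gene[gene_id], annotation,
                depth=coverage[gene.chromosome],
                min_support=min_support, min_depth=min_depth,
            )
        )
    return events, junctions


def build_count_table(
    records_a: list[AlignmentRecord],
    records_b: list[AlignmentRecord],
    annotation: GenomeAnnotation,
) -> GeneCountTable:
    """Counts + RPKM for two libraries; library size = total mapped reads."""
    counts_a, _ = count_reads_per_gene(records_a, annotation)
    counts_b, _ = count_reads_per_gene(records_b, annotation)
    import pandas as pd

    lengths = pd.Series(
        {g: annotation.exon_model_length(g) for g in sorted(annotation.genes)}
    )
    n_a = sum(1 for r in records_a if r.multiplicity != UNMAPPED)
    n_b = sum(1 for r in records_b if r.multiplicity != UNMAPPED)
    return GeneCountTable.from_counts(counts_a, counts_b, lengths, n_a, n_b)


def run_de(records_a, records_b, annotation, fdr_max=0.001, lfc_min=1.0):
    table = build_count_table(records_a, records_b, annotation)
    return call_de(table, fdr_max=fdr_max, lfc_min=lfc_min)


def run_snp_calling(
    records: list[AlignmentRecord],
    genome: dict[str, str],
    prior: snp_calling.GenotypePrior | None = None,
    min_quality: float = 20.0,
    min_alt_reads: int = 2,
):
    columns = snp_calling.build_pileup(records, genome)
    return snp_calling.call_snps(
        columns, prior, min_quality=min_quality, min_alt_reads=min_alt_reads
    )
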