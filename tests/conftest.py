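import pytest

from bovtx.io_formats import Gene, GenomeAnnotation, Transcript
from bovtx.splicing import A3SS, A5SS, ES, IR
from bovtx.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's stated world: errors, multi/unmapped reads and all."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free world: no errors, no multi/unmapped reads, no mismatches.

    Used by the planted-truth recovery tests, which demand exact
    sensitivity and zero false positives.
    """
    cfg = SimulationConfig(
        seed=11,
        multi_fraction=0.0,
        unmapped_fraction=0.0,
        mismatch_fraction=0.0,
        error_rate=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def snp_dataset():
    """Error-free 20x-coverage world with 30 planted hom/het variants."""
    cfg = SimulationConfig(
        seed=23,
        chromosome_lengths=(130_000,),
        n_genes=30,
        target_coverage=20.0,
        n_novel_tus=0,
        as_events={},
        n_variants=30,
        multi_fraction=0.0,
        unmapped_fraction=0.0,
        mismatch_fraction=0.0,
        error_rate=0.0,
    )
    return simulate_dataset(cfg)


def make_annotation(genes, chrom_length=100_000, chrom="chr1"):
    """Build a toy annotation from (gene_id, strand, [exon intervals])."""
    ann = GenomeAnnotation(chromosomes={chrom: chrom_length})
    for gene_id, strand, exons in genes:
        exons = tuple(tuple(e) for e in sorted(exons))
        ann.genes[gene_id] = Gene(gene_id, chrom, strand, exons[0][0], exons[-1][1])
        ann.transcripts[f"tx_{gene_id}"] = Transcript(f"tx_{gene_id}", gene_id, exons)
    ann.validate()
    return ann
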