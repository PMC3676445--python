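# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices that were genuinely open.

## Coordinates and inputs

All internal coordinates are 0-based half-open; conversion to the
1-based closed conventions of GTF and VCF happens only at file
boundaries (`io_formats`). The pipeline starts from alignments: it never
re-aligns, and takes a read's mapping multiplicity (unique / multi /
unmapped) and mismatch count from the record's flags and tags (NH, NM)
as produced upstream or by the simulator. Unmapped and multi-position
reads are excluded from every analysis except the mapping summary,
which exists to count them. GTF files written by the package carry
`#!chromosome-length` pragmas so chromosome bounds survive a round
trip; externally produced GTFs can supply lengths explicitly or fall
back to the maximum exon end.

## Mapping summary

Percentages are count/total·100 rounded **half-up** to two decimals —
the convention validated against every cell of the published two-sample
alignment table this report format imitates (banker's rounding breaks
cells like 1/3 → 33.33). Gene scope counts a read as mapped when any
aligned block overlaps any annotated exon by ≥ 1 bp: the
least-assumption reading of "mapped to genes". The partition identities
(mapped + unmapped = total; unique + multi = mapped;
perfect + mismatched = mapped) hold by construction, with the mismatch
category defined as mapped-but-not-perfect.

## TARs and novel transcript units

- A TAR is a maximal run of bases each covered by ≥ `min_depth`
  (default 2) unique-read blocks; splice gaps contribute nothing.
- Intergenic space is everything more than 200 bp away from a gene
  span, gaps of ≤ 400 bp therefore vanishing. Chromosome-end flanks are
  included, buffered on the gene side only — inclusion maximises
  discoverable space and the provenance of each call records the
  filters it passed.
- Paired-end links connect every TAR touched by either mate of a pair;
  connected components become transcript units.
- A unit is a novel TU when (i) it overlaps no annotated gene span
  (span = min exon start to max exon end across transcripts — the
  conservative reading), (ii) its span lies inside one intergenic
  interval, (iii) its **total mapped length** (sum of member-TAR
  lengths, not the span — coverage gaps are introns) is ≥ 150 bp, and
  (iv) its mean coverage over member-TAR bases (not the span) is ≥ 2.
  The four filters commute; the implementation applies them in one
  pass and a test asserts order-independence.
- Boundary refinement reports, per gene end, the longest TAR protrusion
  beyond the annotated span among TARs overlapping the terminal exon,
  labelled 5′/3′ by strand. By default mere overlap suffices; a
  `require_pair_link` mode additionally demands paired-end connection
  to a TAR in the gene body.

## Alternative splicing

Junctions come from gaps of unique spliced alignments with ≥ 8 bp
anchors on both sides; events require junction support ≥ 2 reads (both
standard guards against alignment artifacts; the source protocol is
silent on them). Junctions are assigned to every gene whose span
contains both boundaries (ambiguous when > 1). Classification:

- **A5SS / A3SS**: two junctions sharing one boundary and differing at
  the other; the label names the transcript-side boundary that varies,
  so it is strand-aware and the labels swap exactly under strand
  reversal (a property test asserts this). Novel (unannotated)
  boundaries participate. A pair whose varying region contains a
  complete annotated internal exon is *not* an alternative splice
  site — that is skipping — keeping the classes disjoint.
- **Exon skipping**: a junction bridges a complete annotated internal
  exon while the exon's inclusion is independently evidenced (a
  flanking junction, or exon coverage ≥ 2). Called against annotated
  exons only.
- **Intron retention**: an annotated intron with *every* base covered
  ≥ 2 **and** a junction supporting the spliced form. Without the
  junction, unspliced pre-mRNA or a mis-annotated intron would be
  indistinguishable from retention; demanding both keeps IR the rarest
  class, as observed in cattle muscle data.

Alternative first/last exons and mutually exclusive exons are out of
scope by design, as is PSI quantification.

## Differential expression

RPKM = count / ((library/10⁶)·(length/10³)) with length the exon-union
model; it is reported, never tested on. The test operates on raw counts
with library sizes N₁, N₂ (total mapped reads by default — whether
"library size" should instead be gene-mapped reads is not documented in
the protocols this imitates; it is configurable). The Audic–Claverie
conditional mass is evaluated in log space via `gammaln`; the two-sided
p is min(1, 2·min(P(Y≤y), P(Y≥y))), floored at the smallest positive
double so it never reports zero. The upper tail is 1 − lower when that
is numerically safe and a direct log-space summation past the mode
otherwise. Equal-library values agree with the exact rational closed
form Σ C(x+k,k)/2^(x+k+1) to 1e-10 relative error, and the general case
with the negative-binomial tail NB(x+1, N₁/(N₁+N₂)) — an independent
oracle in the tests, never the implementation.

The log₂ ratio normalises both libraries to their **geometric-mean**
size and adds a pseudocount of 1 to both normalised counts (ratio only,
never the test): the symmetric scale makes library swapping negate
every ratio exactly, and the pseudocount keeps ratios finite at zero
counts. Note the test itself is direction-conventional (it conditions
on library a), so p-values are not exactly swap-symmetric even though
ratios are. Calls require BH-FDR q ≤ 0.001 and |log₂ ratio| ≥ 1
(two-fold); both thresholds are parameters. The named FDR procedure is
Benjamini–Hochberg step-up (via statsmodels), the standard choice where
the protocol names only "FDR". Total-count normalisation carries the
usual composition bias: strongly asymmetric DE inflates one library's
size and shrinks every measured ratio toward it, visible in the
examples at 20-gene scale.

## Term enrichment

Flat term → gene maps; no ontology-DAG propagation (pre-propagated maps
are accepted as-is). The background universe is caller-supplied;
annotated sets are intersected with it. Terms with k = 0 DE members are
not "assigned" and do not enter the correction multiplicity m.
Bonferroni (min(1, m·p)) is the default correction for both GO-style
and pathway-style maps; BH is available by flag. Category shares are
percentages of assigned terms at 1 decimal, half-up.

## SNP calling

Per site, likelihoods over the 10 diploid genotypes:
P(b|aa) = Π [1−ε or ε/3], P(b|ab) = Π [½P(b|a) + ½P(b|b)], with
ε = 10^(−Q/10) from the declared base quality (no recalibration — the
quality string is trusted). The prior puts 1e-3 on ref-het, 5e-4 on
hom-alt, transitions weighted 2:1 over transversions, residual mass
het·hom on the three no-reference genotypes, renormalised to 1.
Consensus = argmax posterior, ties broken toward reference-containing
genotypes then lexicographically; consensus quality
= −10·log₁₀(1−posterior), capped at 99. "Quality ≥ 20" is read as this
consensus quality, not base quality. A pass needs quality ≥ 20 and ≥ 2
distinct unique reads carrying a called non-reference allele. An
optional exon-overlap filter restricts calls to coding regions without
claiming equivalence to any particular coding-region definition.

## Synthetic data: what the generator states

Defaults encode the emulated study design: 90 bp paired-end reads (the
mapping table's base-pair totals divided by its read counts — the prose
value of 100 bp disagrees with the table and the table wins), fragment
length ~N(300, 50) clipped to the transcript (a ~200 bp gel cut of
200–700 nt RNA fragments), per-gene fragment counts Poisson with a
condition-specific mean (fold changes multiply the embryonic mean) —
deliberately the same sampling model the exact test assumes, so type-I
error is testable. Category fractions default to the mapping table's
shares: 4 % multi, 21 % unmapped, 23 % of mapped reads carrying planted
1–3 bp mismatches. Base quality is constant Q30 with error rate
10^(−Q/10); an explicit `error_rate` override (0 for the noise-free
recovery fixtures) exists because several planted-truth guarantees are
stated for error-free worlds. `target_coverage` replaces the constant
fragment mean with transcript-length-scaled means when a stage (SNP
recovery at 20×) states depth rather than counts.

Planted truth is recoverable by construction: evidence reads (novel-TU
tiling, AS junction support, intron-retention tiling) are always unique
and error-free, novel-TU fragments are tiled with duplicated terminal
fragments so every base of the planted interval reaches the depth-2
floor, variants sit at least a read length inside the transcript where
coverage is at its nominal depth, and homozygous alleles appear on
evidence reads too. Identical seed + config gives byte-identical
FASTA/GTF/SAM output.

Not modelled: GC/fragment bias, empirical error profiles, RNA
amplification and individual-pooling variance (the emulated design
pools three animals per condition after two rounds of amplification —
a green test here says nothing about that variance), isoform mixtures
(one transcript per gene), or indels. Scale is desk-sized (tens of
genes, ~10⁴ reads); the published headline counts (tens of thousands of
novel TUs and SNPs) are dataset-dependent and not reproducible without
the original data, which was never deposited. Recovery tests therefore
check *properties* (sensitivity 1.0 and zero false positives in stated
noise-free worlds, calibration within binomial error elsewhere), not
headline numbers.

## Known limitations

- Exact-test p-values are asymmetric in the two libraries (a
  conditioning choice inherent to the method); borderline calls could
  differ under library swap.
- The ES inclusion-evidence rule accepts either a flanking junction or
  exon coverage; at very shallow depth this under-calls skipping.
- `refine_boundaries` reports extensions only where a TAR protrudes;
  coverage thinning at transcript edges means shallow libraries rarely
  show extensions even when transcription runs past the annotation.
- Enrichment treats terms independently; correlated (nested) terms make
  Bonferroni doubly conservative.
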