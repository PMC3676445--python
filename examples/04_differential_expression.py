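"""Call differential expression between the two libraries.

Per-gene counts (reads overlapping the exon union) are compared with the
Audic-Claverie exact test, which conditions on the count in one library
and asks how surprising the other is given the library sizes.  Calls
require both BH-adjusted q <= 0.001 and a two-fold change
(|log2 ratio| >= 1) on geometric-mean-normalised counts.  Four genes are
planted at four-fold up-regulation in the embryonic library.
"""

from bovtx.pipeline import run_de
from bovtx.synthetic_data import SimulationConfig, simulate_dataset

folds = {f"G{i:03d}": 4.0 for i in range(4)}
dataset = simulate_dataset(
    SimulationConfig(seed=42, fold_changes=folds, mean_fragments_per_gene=120.0)
)
result, summary = run_de(
    dataset.records["emb135"], dataset.records["adult30m"], dataset.annotation
)

print(result[result["call"] != "not-DE"][
    ["count_a", "count_b", "rpkm_a", "rpkm_b", "log2_ratio", "p", "q", "call"]
].round(3).to_string())
print()
print(f"summary: {summary}  (planted 4x-up genes: {sorted(folds)})")
print()
print(
    "The measured log2 ratios of planted genes fall below log2(4)=2:\n"
    "with only 20 genes, the up-regulated ones inflate the embryonic\n"
    "library size, and total-count normalisation absorbs part of the\n"
    "fold change (composition bias).  A planted gene whose ratio drifts\n"
    "below the two-fold bar is reported not-DE, as happens here."
)
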