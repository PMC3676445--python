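"""Discover novel transcript units in intergenic space.

Per-base coverage from unique reads yields transcriptionally active
regions (TARs: maximal runs with depth >= 2); paired-end links join TARs
into transcript units; units in intergenic space (200 bp buffers) with
no gene overlap, total length >= 150 bp and mean coverage >= 2 are
called novel.  The simulation plants eight intergenic transcripts, so
eight units should pass all four filters.
"""

from bovtx.pipeline import discover_novel_tus
from bovtx.synthetic_data import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=42))
novel, units, tars = discover_novel_tus(dataset.records["emb135"], dataset.annotation)

print(f"TARs detected:      {len(tars)}")
print(f"transcript units:   {len(units)}")
print(f"novel TUs called:   {len(novel)}   (planted: {len(dataset.truth.novel_tus)})")
print()
print("novel TU intervals (vs planted truth):")
for n, truth in zip(
    sorted(novel, key=lambda n: (n.unit.chromosome, n.unit.start)),
    sorted(dataset.truth.novel_tus),
):
    u = n.unit
    print(
        f"  {u.chromosome}:{u.start}-{u.end}  length={u.total_length}  "
        f"mean_cov={u.mean_coverage:.1f}   truth {truth[0]}:{truth[1]}-{truth[2]}"
    )
print()
print(
    "Recovered intervals match the planted ones exactly here: the\n"
    "generator tiles fragments so even the terminal bases reach the\n"
    "depth-2 floor.  At random (non-tiled) coverage the edges would be\n"
    "trimmed by up to a read length."
)
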