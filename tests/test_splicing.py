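"""Junction extraction and four-type alternative-splicing classification."""

from collections import Counter

import numpy as np
import pytest

from bovtx import io_formats as iof
from bovtx import splicing as sp
from bovtx.pipeline import classify_all_as_events
from tests.conftest import make_annotation


def _read(read_id, blocks, chrom="chr1", mult=iof.UNIQUE):
    return iof.AlignmentRecord(read_id, chrom, "+", tuple(blocks), 0, mult, None, "", ())


class TestExtractJunctions:
    def test_gap_defines_junction(self):
        (j,) = sp.extract_junctions([_read("a/1", [(0, 50), (250, 300)])], min_anchor=8)
        assert (j.donor, j.acceptor, j.support) == (50, 250, 1)

    def test_no_gapped_reads_empty(self):
        assert sp.extract_junctions([_read("a/1", [(0, 90)])]) == []

    def test_short_anchor_and_multi_reads_skipped(self):
        records = [
            _read("a/1", [(0, 5), (250, 300)]),                 # anchor too short
            _read("b/1", [(0, 50), (250, 300)], mult=iof.MULTI),  # not unique
        ]
        assert sp.extract_junctions(records) == []

    def test_support_counts_distinct_reads(self):
        records = [_read(f"r{i}/1", [(0, 50), (250, 300)]) for i in range(5)]
        (j,) = sp.extract_junctions(records)
        assert j.support == 5

    def test_planted_junctions_recovered_exactly(self, clean_dataset):
        records = clean_dataset.records["emb135"]
        junctions = {
            (j.chromosome, j.donor, j.acceptor)
            for j in sp.extract_junctions(records)
            if j.support >= 5
        }
        for truth in clean_dataset.truth.as_events:
            if truth["alt_junction"] is not None:
                gene = clean_dataset.annotation.genes[truth["gene"]]
                assert (gene.chromosome, *truth["alt_junction"]) in junctions


class TestAssign:
    def test_in_gene_in_intergenic_and_ambiguous(self):
        ann = make_annotation(
            [
                ("g1", "+", [(1000, 1200), (1800, 2000)]),
                ("g2", "+", [(1500, 1700), (2500, 3000)]),  # overlaps g1 span
                ("g3", "+", [(8000, 9000)]),
            ]
        )
        j_inside = sp.JunctionSite("chr1", 1600, 1750, 4)
        j_outside = sp.JunctionSite("chr1", 5000, 5200, 4)
        by_gene = sp.assign_junctions_to_genes([j_inside, j_outside], ann)
        assert set(by_gene) == {"g1", "g2"}
        assert j_inside.ambiguous
        assert all(j_outside not in v for v in by_gene.values())


def _two_junction_fixture(strand):
    ann = make_annotation([("g", strand, [(0, 150), (700, 900)])], chrom_length=2000)
    junctions = [sp.JunctionSite("chr1", 100, 500, 4), sp.JunctionSite("chr1", 100, 600, 4)]
    return ann, junctions


class TestClassify:
    def test_shared_donor_plus_strand_is_alt_3ss(self):
        ann, junctions = _two_junction_fixture("+")
        (event,) = sp.classify_as_events("g", junctions, ann)
        assert event.type == sp.A3SS

    def test_shared_donor_minus_strand_is_alt_5ss(self):
        ann, junctions = _two_junction_fixture("-")
        (event,) = sp.classify_as_events("g", junctions, ann)
        assert event.type == sp.A5SS

    def test_labels_swap_exactly_under_strand_reversal(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d1, d2 = sorted(rng.integers(50, 300, 2))
            a = int(rng.integers(600, 900))
            junctions = lambda: [
                sp.JunctionSite("chr1", int(d1), a, 3),
                sp.JunctionSite("chr1", int(d2), a, 3),
            ]
            plus_ann = make_annotation([("g", "+", [(0, 40), (950, 1100)])], chrom_length=2000)
            minus_ann = make_annotation([("g", "-", [(0, 40), (950, 1100)])], chrom_length=2000)
            plus = sp.classify_as_events("g", junctions(), plus_ann)
            minus = sp.classify_as_events("g", junctions(), minus_ann)
            swap = {sp.A5SS: sp.A3SS, sp.A3SS: sp.A5SS}
            assert [swap[e.type] for e in plus] == [e.type for e in minus]

    def test_exon_skipping_on_three_exon_gene(self):
        # exons [0,100), [200,300), [400,500); skip junction bridges exon 2
        ann = make_annotation([("g", "+", [(0, 100), (200, 300), (400, 500)])], chrom_length=1000)
        junctions = [
            sp.JunctionSite("chr1", 100, 200, 4),
            sp.JunctionSite("chr1", 300, 400, 4),
            sp.JunctionSite("chr1", 100, 400, 3),
        ]
        events = sp.classify_as_events("g", junctions, ann)
        assert Counter(e.type for e in events) == {sp.ES: 1}
        (es,) = events
        assert es.interval == (200, 300)
        assert es.junctions == ((100, 400),)

    def test_skipping_needs_inclusion_evidence(self):
        ann = make_annotation([("g", "+", [(0, 100), (200, 300), (400, 500)])], chrom_length=1000)
        skip_only = [sp.JunctionSite("chr1", 100, 400, 3)]
        assert sp.classify_as_events("g", skip_only, ann) == []
        # exon coverage >= min_depth also counts as inclusion evidence
        depth = np.zeros(1000, dtype=int)
        depth[200:300] = 3
        events = sp.classify_as_events("g", skip_only, ann, depth=depth)
        assert [e.type for e in events] == [sp.ES]

    def test_intron_retention_needs_coverage_and_junction(self):
        ann = make_annotation([("g", "+", [(0, 200), (400, 600)])], chrom_length=1000)
        spliced = [sp.JunctionSite("chr1", 200, 400, 4)]
        covered = np.zeros(1000, dtype=int)
        covered[0:600] = 3
        events = sp.classify_as_events("g", spliced, ann, depth=covered)
        assert [e.type for e in events] == [sp.IR]
        assert events[0].interval == (200, 400)
        # full coverage without the spliced junction: not retention
        assert sp.classify_as_events("g", [], ann, depth=covered) == []
        # junction without full intron coverage: not retention
        gap = covered.copy()
        gap[300] = 0
        assert sp.classify_as_events("g", spliced, ann, depth=gap) == []

    def test_classification_is_input_order_independent(self):
        ann, junctions = _two_junction_fixture("+")
        fwd = sp.classify_as_events("g", junctions, ann)
        rev = sp.classify_as_events("g", junctions[::-1], ann)
        assert fwd == rev

    def test_planted_event_types_recovered(self, clean_dataset):
        events, _ = classify_all_as_events(
            clean_dataset.records["adult30m"], clean_dataset.annotation
        )
        truth = clean_dataset.truth.as_events
        truth_by_gene = {(t["gene"], t["type"]) for t in truth}
        found_by_gene = {(e.gene_id, e.type) for e in events}
        assert truth_by_gene <= found_by_gene


class TestSummarize:
    def test_single_event_tallies(self):
        e = sp.ASEvent("g1", sp.A3SS, ((10, 20),), None, (3,))
        s = sp.summarize_as([e])
        assert s["event_counts"][sp.A3SS] == 1
        assert s["gene_counts"][sp.A3SS] == 1
        assert s["multi_event_fraction"] == 0.0

    def test_multi_event_gene(self):
        events = [
            sp.ASEvent("g1", sp.A3SS, ((10, 20),), None, (3,)),
            sp.ASEvent("g1", sp.ES, ((10, 40),), (20, 30), (3,)),
        ]
        s = sp.summarize_as(events)
        assert s["multi_event_fraction"] == 1.0
        assert s["genes_with_k_events"] == {2: 1}

    def test_retained_intron_size_stats(self):
        events = [
            sp.ASEvent("g1", sp.IR, ((100, 400),), (100, 400), (3,)),
            sp.ASEvent("g2", sp.IR, ((0, 100),), (0, 100), (3,)),
        ]
        stats = sp.summarize_as(events)["retained_intron_sizes"]
        assert stats["n"] == 2 and stats["mean"] == 200.0
        assert (stats["min"], stats["max"]) == (100, 300)
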