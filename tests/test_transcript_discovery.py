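"""TAR detection, intergenic arithmetic, paired-end joining, refinement."""

import numpy as np
import pytest

from bovtx import io_formats as iof
from bovtx import transcript_discovery as td
from bovtx.pipeline import discover_novel_tus
from tests.conftest import make_annotation


def _read(read_id, blocks, chrom="chr1", mult=iof.UNIQUE, mate=None):
    return iof.AlignmentRecord(read_id, chrom, "+", tuple(blocks), 0, mult, mate, "", ())


class TestCoverage:
    def test_no_records_all_zero(self):
        assert (td.compute_coverage([], "chr1", 50) == 0).all()

    def test_overlapping_blocks(self):
        records = [_read("a/1", [(0, 10)]), _read("b/1", [(5, 15)])]
        depth = td.compute_coverage(records, "chr1", 20)
        assert list(depth[:15]) == [1] * 5 + [2] * 5 + [1] * 5

    def test_multi_reads_and_splice_gaps_excluded(self):
        records = [
            _read("a/1", [(0, 10), (20, 30)]),
            _read("m/1", [(0, 30)], mult=iof.MULTI),
        ]
        depth = td.compute_coverage(records, "chr1", 40)
        assert depth[:10].sum() == 10 and depth[10:20].sum() == 0 and depth[20:30].sum() == 10

    def test_matches_brute_force_membership_count(self, clean_dataset):
        chrom = "chr1"
        length = clean_dataset.annotation.chromosomes[chrom]
        records = [
            r for r in clean_dataset.records["emb135"] if r.chromosome == chrom
        ][:200]
        depth = td.compute_coverage(records, chrom, length)
        brute = np.zeros(length, dtype=int)
        for rec in records:
            if rec.multiplicity != iof.UNIQUE:
                continue
            for s, e in rec.blocks:
                for i in range(s, e):
                    brute[i] += 1
        assert (depth == brute).all()

    def test_block_outside_chromosome_errors(self):
        with pytest.raises(ValueError):
            td.compute_coverage([_read("a/1", [(90, 120)])], "chr1", 100)


def _oracle_tars(depth, min_depth):
    """Independent linear scan: emit maximal runs with depth >= min_depth."""
    runs, start = [], None
    for i, d in enumerate(list(depth) + [min_depth - 1]):
        if d >= min_depth and start is None:
            start = i
        elif d < min_depth and start is not None:
            runs.append((start, i))
            start = None
    return runs


class TestDetectTars:
    def test_run_scan_example(self):
        tars = td.detect_tars(np.array([0, 1, 2, 2, 3, 1, 2, 2]))
        assert [(t.start, t.end) for t in tars] == [(2, 5), (6, 8)]
        assert tars[0].min_coverage == 2 and tars[0].mean_coverage == pytest.approx(7 / 3)

    def test_all_covered_single_tar(self):
        tars = td.detect_tars(np.full(30, 5))
        assert [(t.start, t.end) for t in tars] == [(0, 30)]

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        depth = rng.poisson(1.5, size=2000)
        tars = td.detect_tars(depth)
        assert [(t.start, t.end) for t in tars] == _oracle_tars(depth, 2)

    def test_maximality_and_disjointness(self):
        rng = np.random.default_rng(99)
        depth = rng.poisson(2.0, size=5000)
        tars = td.detect_tars(depth)
        for t in tars:
            assert (depth[t.start:t.end] >= 2).all()
            assert t.start == 0 or depth[t.start - 1] < 2
            assert t.end == len(depth) or depth[t.end] < 2
        for a, b in zip(tars, tars[1:]):
            assert a.end < b.start


class TestIntergenic:
    def test_buffered_gap(self):
        ann = make_annotation([("g1", "+", [(1000, 2000)]), ("g2", "+", [(5000, 6000)])],
                              chrom_length=10_000)
        regions = td.intergenic_regions(ann)["chr1"]
        assert (2200, 4800) in regions

    def test_gap_of_400_or_less_yields_nothing(self):
        ann = make_annotation([("g1", "+", [(1000, 2000)]), ("g2", "+", [(2400, 3000)])],
                              chrom_length=4000)
        regions = td.intergenic_regions(ann)["chr1"]
        assert not any(s >= 2000 and e <= 2400 for s, e in regions)

    def test_chromosome_end_flanks_buffered_on_gene_side(self):
        ann = make_annotation([("g1", "+", [(1000, 2000)])], chrom_length=5000)
        assert td.intergenic_regions(ann)["chr1"] == [(0, 800), (2200, 5000)]

    def test_matches_set_arithmetic_oracle(self, clean_dataset):
        ann = clean_dataset.annotation
        for chrom, length in ann.chromosomes.items():
            # oracle: mark every base within a gene span or its 200bp buffer
            blocked = np.zeros(length, dtype=bool)
            for g in ann.genes_on(chrom):
                blocked[max(g.start - 200, 0): min(g.end + 200, length)] = True
            expected = _oracle_tars(~blocked, 1)
            assert td.intergenic_regions(ann)[chrom] == expected


class TestJoinTars:
    def _tars(self, intervals):
        return [
            td.TAR(f"T{i}", "chr1", s, e, 2, 2.0) for i, (s, e) in enumerate(intervals)
        ]

    def test_no_pairs_gives_singletons(self):
        tars = self._tars([(0, 100), (200, 300), (500, 600)])
        units = td.join_tars(tars, [])
        assert [u.tar_ids for u in units] == [("T0",), ("T1",), ("T2",)]

    def test_transitive_linking(self):
        tars = self._tars([(0, 100), (200, 300), (500, 600)])
        pairs = [
            (_read("p1/1", [(10, 50)], mate="p1/2"), _read("p1/2", [(210, 260)], mate="p1/1")),
            (_read("p2/1", [(250, 290)], mate="p2/2"), _read("p2/2", [(510, 560)], mate="p2/1")),
        ]
        (unit,) = td.join_tars(tars, pairs)
        assert unit.tar_ids == ("T0", "T1", "T2")
        assert unit.total_length == 300 and unit.n_blocks == 3

    @pytest.mark.parametrize("seed", range(15))
    def test_components_match_networkx_oracle(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        n = 12
        tars = self._tars([(i * 300, i * 300 + 100) for i in range(n)])
        g = nx.Graph()
        g.add_nodes_from(range(n))
        pairs = []
        for k in range(rng.integers(0, 15)):
            i, j = rng.integers(0, n, 2)
            g.add_edge(int(i), int(j))
            pairs.append(
                (
                    _read(f"p{k}/1", [(int(i) * 300 + 10, int(i) * 300 + 60)], mate=f"p{k}/2"),
                    _read(f"p{k}/2", [(int(j) * 300 + 10, int(j) * 300 + 60)], mate=f"p{k}/1"),
                )
            )
        units = td.join_tars(tars, pairs)
        ours = {frozenset(u.tar_ids) for u in units}
        expected = {
            frozenset(f"T{i}" for i in comp) for comp in nx.connected_components(g)
        }
        assert ours == expected


class TestNovelTU:
    def _unit(self, start, end, total_length=None, mean_cov=5.0):
        total = total_length if total_length is not None else end - start
        return td.TranscriptUnit("TU0", "chr1", ("T0",), start, end, total, mean_cov, 1)

    def setup_method(self):
        self.ann = make_annotation(
            [("g1", "+", [(1000, 2000)]), ("g2", "+", [(8000, 9000)])], chrom_length=12_000
        )
        self.inter = td.intergenic_regions(self.ann)

    def test_short_unit_rejected(self):
        unit = self._unit(3000, 3149)
        assert td.call_novel_tus([unit], self.ann, self.inter) == []

    def test_one_bp_gene_overlap_rejected(self):
        unit = self._unit(1999, 2600, total_length=601)
        assert td.call_novel_tus([unit], self.ann, self.inter) == []

    def test_low_coverage_rejected_and_filters_order_free(self):
        unit = self._unit(3000, 3600, mean_cov=1.5)
        assert td.call_novel_tus([unit], self.ann, self.inter) == []

    def test_passing_unit_has_full_provenance(self):
        unit = self._unit(3000, 3600)
        (novel,) = td.call_novel_tus([unit], self.ann, self.inter)
        assert novel.intergenic and novel.no_gene_overlap
        assert novel.min_length and novel.min_mean_coverage

    def test_planted_recovery_exact(self, clean_dataset):
        novel, _, _ = discover_novel_tus(
            clean_dataset.records["emb135"], clean_dataset.annotation
        )
        truth = clean_dataset.truth.novel_tus
        assert len(novel) == len(truth) == 8
        rl = clean_dataset.config.read_length
        for n, (chrom, start, end, _tu) in zip(
            sorted(novel, key=lambda n: (n.unit.chromosome, n.unit.start)),
            sorted(truth),
        ):
            assert n.unit.chromosome == chrom
            assert abs(n.unit.start - start) <= rl
            assert abs(n.unit.end - end) <= rl


class TestRefine:
    def test_plus_strand_extensions(self):
        ann = make_annotation([("g1", "+", [(1000, 1400), (1700, 2000)])], chrom_length=4000)
        tar = td.TAR("T0", "chr1", 900, 2300, 2, 3.0)
        exts = td.refine_boundaries(ann, [tar])
        by_end = {e.end: e for e in exts}
        assert by_end["5p"].length == 100
        assert by_end["3p"].length == 300

    def test_tar_inside_gene_gives_no_extension(self):
        ann = make_annotation([("g1", "+", [(1000, 2000)])], chrom_length=4000)
        assert td.refine_boundaries(ann, [td.TAR("T0", "chr1", 1100, 1900, 2, 3.0)]) == []

    def test_minus_strand_mirrors_plus_strand_labels(self):
        exons = [(1000, 1400), (1700, 2000)]
        tar = td.TAR("T0", "chr1", 900, 2300, 2, 3.0)
        plus = td.refine_boundaries(make_annotation([("g", "+", exons)], chrom_length=4000), [tar])
        minus = td.refine_boundaries(make_annotation([("g", "-", exons)], chrom_length=4000), [tar])
        plus_map = {e.end: e.length for e in plus}
        minus_map = {e.end: e.length for e in minus}
        assert plus_map == {"5p": 100, "3p": 300}
        assert minus_map == {"3p": 100, "5p": 300}
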