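"""RPKM, the exact count test, BH-FDR and the DE calling thresholds."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bovtx import io_formats as iof
from bovtx.expression_de import (
    GeneCountTable,
    audic_claverie_p,
    bh_fdr,
    call_de,
    count_reads_per_gene,
    rpkm,
)
from tests.conftest import make_annotation


class TestRpkm:
    def test_formula(self):
        assert rpkm(100, 1000, 10_000_000) == pytest.approx(10.0)
        assert rpkm(0, 5000, 10_000_000) == 0.0
        # spot value against independent arithmetic
        assert rpkm(458, 2300, 20_427_874) == pytest.approx(
            458 / ((20_427_874 / 1e6) * 2.3)
        )

    def test_joint_scale_invariance(self):
        base = rpkm(100, 1500, 2_000_000)
        for c in (2, 10, 37):
            assert rpkm(100 * c, 1500, 2_000_000 * c) == pytest.approx(base)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 1000)
        with pytest.raises(ValueError):
            rpkm(10, 100, 0)


def _closed_form_p(x, y):
    """Equal-library two-sided p via exact rational arithmetic.

    For N1=N2 the conditional mass is p(k|x) = C(x+k,k) / 2^(x+k+1); the
    two-sided p doubles the smaller of the two inclusive tails.
    """
    import math

    def pmf(k):
        return Fraction(math.comb(x + k, k), 2 ** (x + k + 1))

    lower = sum(pmf(k) for k in range(y + 1))
    upper = 1 - sum(pmf(k) for k in range(y))
    return float(min(Fraction(1), 2 * min(lower, upper)))


class TestAudicClaverie:
    def test_boundary_case_p_is_one(self):
        assert audic_claverie_p(0, 0, 1e6, 1e6) == 1.0

    def test_extreme_discordance(self):
        # x=10, y=0: twice the single lower-tail term 1/2^11
        assert audic_claverie_p(10, 0, 1e6, 1e6) == pytest.approx(2 / 2048, rel=1e-12)

    @pytest.mark.parametrize(
        "x,y", [(0, 5), (3, 3), (10, 25), (50, 50), (100, 60), (7, 0), (200, 260)]
    )
    def test_equal_libraries_match_closed_form(self, x, y):
        assert audic_claverie_p(x, y, 5e6, 5e6) == pytest.approx(
            _closed_form_p(x, y), rel=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_unequal_libraries_match_nbinom_tails(self, seed):
        """Independent oracle: conditional distribution of y given x is
        NegativeBinomial(x+1, N1/(N1+N2))."""
        rng = np.random.default_rng(seed)
        x = int(rng.integers(0, 200))
        y = int(rng.integers(0, 200))
        n1 = float(rng.integers(1_000_000, 30_000_000))
        n2 = float(rng.integers(1_000_000, 30_000_000))
        dist = stats.nbinom(x + 1, n1 / (n1 + n2))
        expected = min(1.0, 2 * min(dist.cdf(y), dist.sf(y - 1)))
        assert audic_claverie_p(x, y, n1, n2) == pytest.approx(expected, rel=1e-9)

    def test_p_peaks_at_proportional_counts(self):
        # the two-sided p is largest where the observed ratio matches the
        # library-size ratio; the cap at 1 lets immediate neighbours tie,
        # so assert the peak is at (or within one count-SD of) y = x*N2/N1
        for x, n1, n2 in [(40, 1e6, 1e6), (30, 1e6, 2e6), (60, 3e6, 1e6)]:
            ys = np.arange(0, int(4 * x * n2 / n1) + 5)
            ps = np.array([audic_claverie_p(x, int(y), n1, n2) for y in ys])
            y_star = x * n2 / n1
            sd = np.sqrt((x + 1) * (n2 / n1) * (1 + n2 / n1))
            assert abs(int(ys[np.argmax(ps)]) - y_star) <= sd
            assert ps[int(round(y_star))] >= 0.9 * ps.max()

    def test_never_underflows_to_zero(self):
        assert audic_claverie_p(0, 2000, 1e7, 1e7) > 0.0
        assert audic_claverie_p(3000, 0, 1e7, 1e7) > 0.0


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([1e-4, 0.02, 0.9]) == pytest.approx([3e-4, 0.03, 0.9])
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_monotone_and_order_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        perm = rng.permutation(50)
        assert bh_fdr(p[perm]) == pytest.approx(q[perm])


def _table(counts_a, counts_b, lengths=None, n_a=None, n_b=None):
    n = len(counts_a)
    idx = [f"g{i}" for i in range(n)]
    return GeneCountTable.from_counts(
        pd.Series(counts_a, index=idx),
        pd.Series(counts_b, index=idx),
        pd.Series(lengths if lengths is not None else [1000] * n, index=idx),
        n_a=n_a,
        n_b=n_b,
    )


class TestCallDe:
    def test_identical_counts_not_de(self):
        res, summary = call_de(_table([100, 50], [100, 50]))
        assert (res["log2_ratio"] == 0).all()
        assert (res["call"] == "not-DE").all()
        assert summary == {"up": 0, "down": 0, "not_de": 2}

    def test_fold_change_threshold_blocks_significant_gene(self):
        # counts differ hugely in significance but below the 2-fold bar
        res, _ = call_de(_table([40_000, 100], [22_000, 100], n_a=10**6, n_b=10**6))
        g0 = res.iloc[0]
        assert g0["q"] < 1e-9 and abs(g0["log2_ratio"]) < 1.0
        assert g0["call"] == "not-DE"

    def test_swapping_libraries_negates_ratios_and_swaps_calls(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(200, 50)
        b = (a * rng.choice([0.2, 1.0, 5.0], 50)).astype(int)
        res_ab, sum_ab = call_de(_table(a, b))
        res_ba, sum_ba = call_de(_table(b, a))
        assert res_ab["log2_ratio"].to_numpy() == pytest.approx(
            -res_ba["log2_ratio"].to_numpy()
        )
        assert (sum_ab["up"], sum_ab["down"]) == (sum_ba["down"], sum_ba["up"])

    def test_rpkm_zero_iff_count_zero(self):
        table = _table([0, 10], [5, 0])
        t = table.table
        assert ((t["rpkm_a"] == 0) == (t["count_a"] == 0)).all()
        assert ((t["rpkm_b"] == 0) == (t["count_b"] == 0)).all()


class TestCounting:
    def test_exon_union_rule(self):
        ann = make_annotation([("g1", "+", [(100, 200), (400, 500)])])
        intronic = iof.AlignmentRecord("a/1", "chr1", "+", ((250, 340),), 0, iof.UNIQUE, None, "", ())
        exonic = iof.AlignmentRecord("b/1", "chr1", "+", ((150, 240),), 0, iof.UNIQUE, None, "", ())
        counts, ambiguous = count_reads_per_gene([intronic, exonic], ann)
        assert counts["g1"] == 1 and not ambiguous

    def test_empty_input_all_zero(self):
        ann = make_annotation([("g1", "+", [(100, 200)])])
        counts, _ = count_reads_per_gene([], ann)
        assert (counts == 0).all()

    def test_planted_counts_recovered(self, clean_dataset):
        counts, _ = count_reads_per_gene(
            clean_dataset.records["emb135"], clean_dataset.annotation
        )
        truth = clean_dataset.truth.gene_counts["emb135"]
        # each fragment contributes its two mates; evidence reads of AS
        # hosts add extra, so check only genes without planted AS events
        as_genes = {t["gene"] for t in clean_dataset.truth.as_events}
        for gene, expected_fragments in truth.items():
            if gene in as_genes:
                continue
            assert counts[gene] == 2 * expected_fragments

    def test_read_spanning_two_genes_counts_for_both(self):
        ann = make_annotation(
            [("g1", "+", [(100, 200)]), ("g2", "+", [(220, 300)])]
        )
        spanning = iof.AlignmentRecord(
            "a/1", "chr1", "+", ((150, 260),), 0, iof.UNIQUE, None, "", ()
        )
        counts, ambiguous = count_reads_per_gene([spanning], ann)
        assert counts["g1"] == 1 and counts["g2"] == 1
        assert ambiguous == {"a/1"}
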