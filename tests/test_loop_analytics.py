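import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loopmet.genomic_io import GenomicInterval, Loop
from loopmet.loop_analytics import (ContactMatrix, assign_ep, cap_top_quantile,
                                    classify_distance, count_ep_per_gene,
                                    define_promoters, distance_distribution,
                                    filter_significant_loops, ice_balance)

from conftest import brute_force_ep, make_loop


class TestSignificance:
    def test_h3k27ac_rule(self):
        kept = filter_significant_loops(
            [make_loop(reads=4, fdr=0.005), make_loop(reads=3, fdr=0.005),
             make_loop(reads=40, fdr=0.02)], "H3K27Ac")
        assert len(kept) == 1 and kept[0].read_count == 4

    def test_mettl3_has_no_read_floor(self):
        loops = [make_loop(reads=1, fdr=0.04, assay="METTL3"),
                 make_loop(reads=100, fdr=0.06, assay="METTL3")]
        kept = filter_significant_loops(loops, "METTL3")
        assert len(kept) == 1 and kept[0].fdr == 0.04

    def test_unknown_assay_and_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unknown assay"):
            filter_significant_loops([], "CTCF")
        with pytest.raises(ValueError, match="assay"):
            filter_significant_loops([make_loop(assay="METTL3")], "H3K27Ac")

    @given(st.lists(st.tuples(st.integers(0, 100),
                              st.floats(0, 1, allow_nan=False)), max_size=50),
           st.floats(0.001, 0.1), st.floats(0.001, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_relaxing_fdr_is_monotone(self, specs, t1, t2):
        loops = [make_loop(reads=r, fdr=f) for r, f in specs]
        lo, hi = sorted((t1, t2))
        strict = filter_significant_loops(loops, "H3K27Ac", fdr=lo)
        relaxed = filter_significant_loops(loops, "H3K27Ac", fdr=hi)
        assert set(map(id, strict)) <= set(map(id, relaxed))


class TestDistance:
    @pytest.mark.parametrize("d,expected", [
        (3_000, "short"), (4_999, "short"), (5_000, "medium"),
        (1_000_000, "medium"), (2_000_000, "medium"), (2_000_001, "long"),
    ])
    def test_classes_with_boundaries(self, d, expected):
        # anchors of width 2 centred 1 bp in, so midpoints differ by exactly d
        lp = make_loop(start_a=0, end_a=2, start_b=d, end_b=d + 2)
        assert classify_distance(lp) == expected

    def test_inter_chromosomal_is_trans(self):
        lp = make_loop(chrom_b="chr2")
        assert classify_distance(lp) == "trans"

    def test_distribution_percentages(self):
        loops = [make_loop(start_b=3000, end_b=4000)] * 3 \
            + [make_loop(start_b=3_000_000, end_b=3_001_000)]
        dist = distance_distribution(loops)
        assert dist.loc["short", "pct"] == 75.0
        assert dist.loc["long", "pct"] == 25.0
        assert dist["count"].sum() == 4

    def test_distribution_matches_per_loop_tally(self):
        rng = np.random.default_rng(9)
        loops = []
        for _ in range(1000):
            trans = rng.random() < 0.1
            s1 = int(rng.integers(0, 10**7))
            s2 = int(rng.integers(0, 10**7))
            loops.append(make_loop(start_a=s1, end_a=s1 + 500,
                                   chrom_b="chr2" if trans else "chr1",
                                   start_b=s2, end_b=s2 + 500))
        dist = distance_distribution(loops)
        tally = {c: 0 for c in ("short", "medium", "long", "trans")}
        for lp in loops:
            tally[classify_distance(lp)] += 1
        assert dist["count"].to_dict() == tally
        assert abs(dist["pct"].sum() - 100.0) < 1e-9

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            dist = distance_distribution([])
        assert (dist["count"] == 0).all()


class TestPromotersAndEp:
    def test_window_is_tss_plus_minus_flank(self, tiny_catalog):
        windows = {p.gene_id: p.interval
                   for p in define_promoters(tiny_catalog)}
        assert windows["gA"] == GenomicInterval("chr1", 9_000, 11_000)
        # minus-strand gene: symmetric window about end-1
        assert windows["gB"] == GenomicInterval("chr1", 56_999, 58_999)

    def test_window_clipped_at_chromosome_start(self, tiny_catalog):
        from loopmet.genomic_io import GeneCatalog, GeneModel
        g = GeneModel("g0", "chr1", "+", 500, 5_000)
        (pw,) = define_promoters(GeneCatalog([g]))
        assert (pw.interval.start, pw.interval.end) == (0, 1_500)

    def test_either_side_overlap_and_both_genes(self, tiny_catalog):
        promoters = define_promoters(tiny_catalog)
        # anchor_b touches gA promoter only by its last base
        one_side = make_loop(start_a=100_000, end_a=101_000,
                             start_b=8_000, end_b=9_001)
        # both anchors in promoters of two different genes
        both = make_loop(start_a=10_500, end_a=10_600,
                         start_b=57_000, end_b=57_100)
        none = make_loop(start_a=100_000, end_a=101_000,
                         start_b=200_000, end_b=201_000)
        got = assign_ep([one_side, both, none], promoters)
        assert got == [frozenset({"gA"}), frozenset({"gA", "gB"}),
                       frozenset()]

    def test_matches_all_pairs_oracle(self, default_bundle):
        cfg, catalog, sizes = default_bundle
        rng = np.random.default_rng(3)
        promoters = define_promoters(catalog)
        loops = []
        for _ in range(2000):
            chrom = f"chr{int(rng.integers(1, 5))}"
            s1 = int(rng.integers(0, sizes[chrom] - 2000))
            s2 = int(rng.integers(0, sizes[chrom] - 2000))
            loops.append(make_loop(chrom_a=chrom, start_a=s1, end_a=s1 + 800,
                                   start_b=s2, end_b=s2 + 800))
        assert assign_ep(loops, promoters) == brute_force_ep(loops, promoters)

    def test_count_and_delta_sign_conventions(self, tiny_catalog):
        promoters = define_promoters(tiny_catalog)
        near_a = make_loop(start_a=9_500, end_a=9_700,
                           start_b=500_000, end_b=500_200)
        assignments = {
            "growing": assign_ep([near_a], promoters),
            "senescent": assign_ep([near_a] * 3, promoters),
        }
        tab = count_ep_per_gene(assignments, tiny_catalog)
        row = tab.set_index("gene_id").loc["gA"]
        assert (row.ep_growing, row.ep_senescent, row.delta_ep) == (1, 3, 2)
        flipped = count_ep_per_gene(assignments, tiny_catalog,
                                    sign="growing_minus_senescent")
        assert flipped.set_index("gene_id").loc["gA", "delta_ep"] == -2
        # genes without EP loops are present with zero counts
        assert tab.set_index("gene_id").loc["gC"].tolist() == [0, 0, 0]

    def test_missing_condition_raises(self, tiny_catalog):
        with pytest.raises(KeyError, match="senescent"):
            count_ep_per_gene({"growing": []}, tiny_catalog)


class TestIce:
    def test_already_balanced_two_by_two(self):
        m = ContactMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]))
        out = ice_balance(m)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-12)

    def test_zero_row_preserved_and_mass_conserved(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0.5, 2.0, (20, 20))
        A = (A + A.T) / 2
        A[5, :] = 0.0
        A[:, 5] = 0.0
        out = ice_balance(ContactMatrix(A))
        assert (out.values[5, :] == 0).all() and (out.values[:, 5] == 0).all()
        assert abs(out.values.sum() - A.sum()) / A.sum() < 1e-9

    def test_balances_random_positive_matrix(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0.1, 1.0, (50, 50))
        A = (A + A.T) / 2
        out = ice_balance(ContactMatrix(A), iterations=30)
        s = out.values.sum(axis=1)
        assert s.std() / s.mean() < 1e-6
        np.testing.assert_allclose(out.values, out.values.T, rtol=1e-12)

    def test_rejects_asymmetric_and_negative(self):
        with pytest.raises(ValueError, match="symmetric"):
            ice_balance(ContactMatrix(np.array([[1.0, 2.0], [3.0, 1.0]])))
        with pytest.raises(ValueError, match="negative"):
            ice_balance(ContactMatrix(np.array([[1.0, -2.0], [-2.0, 1.0]])))


class TestCap:
    def test_caps_to_95th_percentile_value(self):
        vals = np.diag(np.arange(1.0, 101.0))
        out = cap_top_quantile(ContactMatrix(vals), q=0.05)
        nonzero = out.values[out.values > 0]
        assert nonzero.max() == 95.0
        assert (np.sort(nonzero)[:94] == np.arange(1.0, 95.0)).all()

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        A = rng.lognormal(0, 1, (30, 30))
        A = (A + A.T) / 2
        once = cap_top_quantile(ContactMatrix(A))
        twice = cap_top_quantile(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            out = cap_top_quantile(ContactMatrix(np.zeros((4, 4))))
        assert (out.values == 0).all()
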