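import json

import numpy as np
import pandas as pd
import pytest

from loopmet.loop_analytics import (assign_ep, count_ep_per_gene,
                                    define_promoters,
                                    filter_significant_loops)
from loopmet.m6a import classify_polymethylated, count_unique_sites
from loopmet.synthetic import (GeneratorConfig, generate_all,
                               generate_ct_table, generate_expression,
                               generate_genome, generate_isotopologues,
                               generate_loops, generate_m6a)
from loopmet.tracing import (correct_isotopologue_table,
                             labeled_fraction_table)


class TestGenome:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(seed=1, n_genes=50)
        a, sa = generate_genome(cfg)
        b, sb = generate_genome(cfg)
        assert sa == sb
        for ga, gb in zip(a, b):
            assert ga == gb

    def test_empty_catalog(self):
        cat, _ = generate_genome(GeneratorConfig(seed=1, n_genes=0))
        assert len(cat) == 0

    def test_genes_fit_and_regions_inside_span(self, default_bundle):
        _, catalog, sizes = default_bundle
        prev_end = {}
        for g in catalog:
            assert g.end <= sizes[g.chrom]
            assert g.start >= prev_end.get(g.chrom, 0)  # non-overlapping
            prev_end[g.chrom] = g.end
            for ivs in g.regions.values():
                for iv in ivs:
                    assert g.start <= iv.start < iv.end <= g.end

    def test_overfull_chromosome_rejected(self):
        cfg = GeneratorConfig(seed=1, chrom_sizes=(40_000,), n_genes=30)
        with pytest.raises(ValueError, match="larger chromosomes"):
            generate_genome(cfg)


class TestLoopsPlanting:
    def test_planted_ep_counts_recovered_through_pipeline(self, default_bundle):
        cfg, catalog, sizes = default_bundle
        loops, truth = generate_loops(cfg, catalog, sizes)
        promoters = define_promoters(catalog)
        assignments = {
            cond: assign_ep(filter_significant_loops(lps, "H3K27Ac"),
                            promoters)
            for cond, lps in loops.items()}
        got = count_ep_per_gene(assignments, catalog)
        merged = got.merge(truth, on="gene_id", suffixes=("", "_planted"))
        assert (merged["ep_growing"] == merged["ep_growing_planted"]).all()
        assert (merged["ep_senescent"] == merged["ep_senescent_planted"]).all()
        assert (merged["delta_ep"] == merged["delta_ep_planted"]).all()

    def test_background_only_yields_zero_ep(self):
        cfg = GeneratorConfig(seed=2, n_genes=30, delta_ep_values=(0,),
                              extra_ep_range=(0, 0), n_background_loops=300)
        catalog, sizes = generate_genome(cfg)
        loops, truth = generate_loops(cfg, catalog, sizes)
        assert (truth["ep_growing"] == 0).all()
        promoters = define_promoters(catalog)
        for lps in loops.values():
            for genes in assign_ep(lps, promoters):
                assert genes == frozenset()


class TestExpressionPlanting:
    def test_zero_noise_linearity(self):
        cfg = GeneratorConfig(seed=3, coupling_noise_sd=0.0, mtc_up_lfc=0.0)
        truth = pd.DataFrame({
            "gene_id": [f"G{i:04d}" for i in range(200)],
            "ep_growing": 0, "ep_senescent": 0,
            "delta_ep": np.tile([-2, -1, 0, 1, 2], 40)})
        expr, _ = generate_expression(cfg, truth)
        sen = expr[expr["contrast"] == "sen_vs_growing"]
        np.testing.assert_allclose(
            sen["log_fc"], cfg.coupling_slope * truth["delta_ep"], atol=1e-12)

    def test_kd_contrasts_reverse_planted_subset(self, default_bundle):
        cfg, catalog, sizes = default_bundle
        _, truth = generate_loops(cfg, catalog, sizes)
        expr, mtc = generate_expression(cfg, truth)
        assert len(mtc) == cfg.n_mtc_genes
        delta = truth.set_index("gene_id")["delta_ep"]
        assert all(delta[g] > 0 for g in mtc)
        for contrast in ("shMETTL3_vs_sen", "shMETTL14_vs_sen"):
            sub = expr[expr["contrast"] == contrast].set_index("gene_id")
            assert (sub.loc[sorted(mtc), "log_fc"] < -1).all()
            assert (sub.loc[sorted(mtc), "padj"] < 0.05).all()


class TestM6aPlanting:
    def test_planted_counts_survive_merge(self, default_bundle):
        cfg, catalog, _ = default_bundle
        peaks, _, truth = generate_m6a(cfg, catalog)
        sites = count_unique_sites(peaks, catalog)
        for tid, planted in truth["site_counts"].items():
            assert len(sites[tid]) == planted
        calls = classify_polymethylated(sites)
        poly = set(calls.loc[calls["is_polymethylated"], "transcript_id"])
        assert poly == set(truth["polymethylated"])

    def test_seed_determinism(self, default_bundle):
        cfg, catalog, _ = default_bundle
        p1, e1, t1 = generate_m6a(cfg, catalog)
        p2, e2, t2 = generate_m6a(cfg, catalog)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(e1, e2)
        assert t1 == t2


class TestIsotopologuePlanting:
    def test_noise_free_round_trip(self):
        cfg = GeneratorConfig(seed=4, intensity_noise_sigma=0.0)
        table, truth = generate_isotopologues(cfg)
        corrected = correct_isotopologue_table(table, p13c=cfg.p13c)
        for spec in cfg.panel:
            for group, f in spec.fractions.items():
                sub = corrected[(corrected["metabolite"] == spec.name)
                                & (corrected["group"] == group)]
                np.testing.assert_allclose(sub[f"mid_{spec.m_label}"], f,
                                           atol=1e-9)
                np.testing.assert_allclose(sub["mid_0"], 1 - f, atol=1e-9)

    def test_ct_table_fold_recovery(self):
        cfg = GeneratorConfig(seed=5, ct_noise_sd=0.0)
        table, truth = generate_ct_table(cfg, true_fold=4.0)
        from loopmet.qpcr import CtMeasurement, ddct_fold_change
        cal = table[table["sample"] == "calibrator"].iloc[0]
        trt = table[table["sample"] == "treated"].iloc[0]
        fold = ddct_fold_change(
            CtMeasurement("t", trt["target_ct"], trt["reference_ct"]),
            CtMeasurement("c", cal["target_ct"], cal["reference_ct"]))
        assert fold == pytest.approx(4.0)


class TestBundle:
    def test_generate_all_is_byte_deterministic(self, tmp_path):
        cfg = GeneratorConfig(seed=6, n_genes=60, n_background_loops=100,
                              n_poly_transcripts=8, n_poly_down=2,
                              n_nonpoly_with_sites=20)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_all(cfg, d1)
        generate_all(cfg, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_truth_manifest_contents(self, tmp_path):
        cfg = GeneratorConfig(seed=7, n_genes=60, n_background_loops=50,
                              n_poly_transcripts=8, n_poly_down=2,
                              n_nonpoly_with_sites=20, n_mtc_genes=5)
        truth = generate_all(cfg, tmp_path / "x")
        with open(tmp_path / "x" / "truth.json") as fh:
            on_disk = json.load(fh)
        assert on_disk["mtc_genes"] == sorted(truth["mtc_genes"])
        assert len(on_disk["m6a"]["polymethylated"]) == 8
        assert len(on_disk["m6a"]["poly_down"]) == 2
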