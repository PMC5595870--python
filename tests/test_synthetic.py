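"""Ground-truth guarantees of the synthetic multi-region generator."""

import numpy as np
import pandas as pd
import pytest

from preclone import clonality as cl
from preclone import phylogeny as ph
from preclone import synthetic as syn


class TestCloneTree:
    def test_degenerate_single_clone(self):
        tree = syn.simulate_clone_tree(1, 10, 5, seed=1)
        assert tree.nodes == [0]
        assert len(tree.mutations[0]) == 10

    def test_trunk_count_template(self):
        # the multi-region template scenario: 29 trunk mutations
        tree = syn.simulate_clone_tree(4, 29, 10, seed=2)
        assert len(tree.mutations[0]) == 29
        for node in tree.nodes[1:]:
            assert len(tree.mutations[node]) == 10

    def test_same_seed_identical(self):
        a = syn.simulate_clone_tree(4, 12, 6, seed=3)
        b = syn.simulate_clone_tree(4, 12, 6, seed=3)
        assert [m.id for m in a.all_mutations()] == [m.id for m in b.all_mutations()]
        assert a.parent == b.parent
        assert a.segments == b.segments

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_clone_tree(0, 10, 5, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_clone_tree(2, -1, 5, seed=1)

    def test_mutations_inherited_by_descendants(self, small_tree):
        for node in small_tree.nodes[1:]:
            parent = small_tree.parent[node]
            parent_ids = {m.id for m in small_tree.clone_mutations(parent)}
            child_ids = {m.id for m in small_tree.clone_mutations(node)}
            assert parent_ids <= child_ids

    def test_segment_invariants(self, small_tree):
        for node in small_tree.nodes:
            for seg in small_tree.segments[node]:
                assert seg.major >= seg.minor >= 0
                assert seg.total == seg.major + seg.minor

    def test_two_hit_configuration(self):
        tree = syn.simulate_clone_tree(2, 10, 5, seed=4, tp53_two_hit=True)
        genes = [m.gene for m in tree.mutations[0]]
        assert "TP53" in genes
        chrom, pos = syn.GENE_LOCI["TP53"]
        seg = tree.segment_at(0, chrom, pos)
        assert (seg.total, seg.minor) == (1, 0)


class TestRegions:
    def test_pure_regions_all_clonal(self, small_tree):
        regions = syn.simulate_regions(small_tree, 4, mixing=0.0, seed=5)
        ccf = syn.true_ccf_table(small_tree, regions)
        assert set(np.unique(ccf.values)) <= {0.0, 1.0}

    def test_mixing_half_gives_ccf_half(self):
        tree = syn.simulate_clone_tree(2, 5, 5, seed=6)
        regions = syn.simulate_regions(tree, 1, mixing=0.5, seed=7,
                                       dominant_clones=[1])
        child_mut = tree.mutations[1][0]
        assert syn.true_ccf(tree, regions[0], child_mut) == pytest.approx(0.5)
        trunk_mut = tree.mutations[0][0]
        assert syn.true_ccf(tree, regions[0], trunk_mut) == pytest.approx(1.0)

    def test_nine_regions(self, small_tree):
        assert len(syn.simulate_regions(small_tree, 9, seed=8)) == 9

    def test_purity_within_range(self, small_regions):
        assert all(0.3 <= r.purity <= 0.9 for r in small_regions)

    def test_fractions_sum_to_one(self, small_regions):
        for r in small_regions:
            assert sum(r.fractions.values()) == pytest.approx(1.0)

    def test_trunk_ccf_one_everywhere(self, small_tree, small_regions):
        for region in small_regions:
            for m in small_tree.mutations[0]:
                assert syn.true_ccf(small_tree, region, m) == 1.0


class TestReads:
    def test_mean_depth(self, small_reads):
        assert small_reads.variants.n.mean() == pytest.approx(80, rel=0.05)

    def test_read_counts_bounded(self, small_reads):
        v = small_reads.variants
        assert ((v.a >= 0) & (v.a <= v.n)).all()

    def test_vaf_converges_to_expectation(self):
        # law of large numbers at depth 1e5: within 3 binomial SDs of VAFe
        tree = syn.simulate_clone_tree(2, 5, 5, seed=9)
        regions = syn.simulate_regions(tree, 2, purity_range=(0.6, 0.6), seed=10)
        reads = syn.simulate_reads(tree, regions, mean_depth=100_000, seed=11)
        merged = reads.variants.merge(reads.truth, on=["mutation_id", "sample"])
        for row in merged.itertuples():
            if row.vafe == 0:
                assert row.a == 0 or row.a / row.n < 0.001
                continue
            sd = np.sqrt(row.vafe * (1 - row.vafe) / row.n)
            assert abs(row.a / row.n - row.vafe) <= 3 * sd

    def test_pure_diploid_site_vaf_half(self):
        tree = syn.simulate_clone_tree(1, 3, 0, seed=12)
        regions = [syn.RegionMixture("S1", "ESCC", "TD", 1.0, {0: 1.0})]
        reads = syn.simulate_reads(tree, regions, mean_depth=200_000, seed=13)
        vaf = reads.variants.a / reads.variants.n
        assert np.allclose(vaf, 0.5, atol=0.01)

    def test_truth_vafe_matches_clonality_model(self, small_reads):
        t = small_reads.truth
        carried = t[t.true_ccf > 0]
        sheet = small_reads.sample_sheet.set_index("sample")
        for row in carried.head(80).itertuples():
            p = float(sheet.loc[row.sample, "purity"])
            # sheet purity is rounded to 4 decimals
            assert row.vafe == pytest.approx(
                cl.expected_vaf(p, int(row.cn), int(row.cnt), row.true_ccf),
                abs=5e-4)

    def test_window_coverage_expectation_follows_cn(self):
        # diploid pure sample at 1x: window coverage ~ window width in Kb
        tree = syn.simulate_clone_tree(1, 2, 0, seed=14)
        regions = [syn.RegionMixture("S1", "ESCC", "TD", 1.0, {0: 1.0})]
        reads = syn.simulate_reads(tree, regions, mean_depth=50, wgs_depth=1.0,
                                   seed=15)
        cov = reads.coverage
        full = cov[(cov.end - cov.start) == 500_000]
        assert full.cov_kb.mean() == pytest.approx(500.0, rel=0.02)

    def test_deterministic_files(self, small_tree, small_regions, tmp_path):
        from preclone import io as pio
        a = syn.simulate_reads(small_tree, small_regions, seed=30)
        b = syn.simulate_reads(small_tree, small_regions, seed=30)
        pio.write_dataset(a, tmp_path / "a")
        pio.write_dataset(b, tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_bad_depth_rejected(self, small_tree, small_regions):
        with pytest.raises(ValueError):
            syn.simulate_reads(small_tree, small_regions, mean_depth=0)


class TestRoundTrip:
    def test_noiseless_classification_matches_branch_assignment(self):
        tree = syn.simulate_clone_tree(4, 8, 4, seed=16)
        regions = syn.simulate_regions(tree, 4, mixing=0.0, seed=17,
                                       dominant_clones=[0, 1, 2, 3])
        ccf = syn.true_ccf_table(tree, regions)
        cm = ph.CharacterMatrix((ccf > 0).T)
        cat = ph.classify_trunk_shared_private(cm)
        for m in tree.all_mutations():
            n_carrying_regions = sum(
                1 for r in regions if syn.true_ccf(tree, r, m) > 0)
            expected = ("trunk" if n_carrying_regions == len(regions)
                        else "private" if n_carrying_regions == 1 else "shared")
            assert cat[m.id] == expected
        assert set(cat[cat == "trunk"].index) == {m.id for m in tree.mutations[0]}


class TestCohortPresets:
    def test_td_preset_structure(self):
        pt = syn.simulate_patient("TDx", "TD", seed=18, n_regions=4)
        sheet = pt.reads.sample_sheet
        assert set(sheet.grade) <= {"LD", "HD", "ESCC", "MET"}
        assert (sheet.cohort == "TD").all()
        genes = [m.gene for m in pt.tree.mutations[0]]
        assert "TP53" in genes

    def test_ntd_preset_structure(self):
        pt = syn.simulate_patient("NTDx", "NTD", seed=19)
        assert len(pt.regions) == 1
        assert pt.reads.sample_sheet.cohort.iloc[0] == "NTD"
        # diploid genome, no LOH anywhere
        for seg in pt.tree.segments[0]:
            assert (seg.total, seg.major, seg.minor) == (2, 1, 1)

    def test_td_burden_exceeds_ntd(self):
        td = syn.simulate_cohort(2, "TD", seed=20)
        ntd = syn.simulate_cohort(2, "NTD", seed=21)
        td_counts = [len(p.tree.clone_mutations(r.dominant_clone))
                     for p in td.patients for r in p.regions]
        ntd_counts = [len(p.tree.clone_mutations(r.dominant_clone))
                      for p in ntd.patients for r in p.regions]
        assert np.median(td_counts) > np.median(ntd_counts)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_patient("X", "QQ", seed=1)
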