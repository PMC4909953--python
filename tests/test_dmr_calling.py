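import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import methylcmp as m
from conftest import make_bins
from oracles import bh_step_up_naive, fisher_two_sided_exact


class TestFisherExact:
    def test_balanced_table(self):
        assert m.fisher_exact_two_sided(5, 5, 5, 5) == 1.0

    def test_all_zero_convention(self):
        assert m.fisher_exact_two_sided(0, 0, 0, 0) == 1.0

    def test_extreme_table_against_enumeration(self):
        # margins (10,10,10,10): 11 possible tables, enumerated exactly
        assert m.fisher_exact_two_sided(10, 0, 0, 10) == pytest.approx(
            fisher_two_sided_exact(10, 0, 0, 10), abs=1e-12
        )

    def test_random_tables_against_scipy(self):
        rng = np.random.default_rng(11)
        tables = rng.integers(0, 60, size=(200, 4))
        ours = m.fisher_exact_two_sided_many(*tables.T)
        for (a, b, c, d), p in zip(tables, ours):
            if a + b + c + d == 0:
                continue
            assert p == pytest.approx(
                scipy_fisher([[a, b], [c, d]]).pvalue, abs=1e-9
            )

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        tables = rng.integers(0, 40, size=(50, 4))
        direct = m.fisher_exact_two_sided_many(*tables.T)
        swapped = m.fisher_exact_two_sided_many(
            tables[:, 2], tables[:, 3], tables[:, 0], tables[:, 1]
        )
        np.testing.assert_allclose(direct, swapped, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            m.fisher_exact_two_sided(-1, 0, 0, 1)


class TestBHAdjust:
    def test_single_p(self):
        assert m.bh_adjust([0.5]) == pytest.approx([0.5])

    def test_step_up_example(self):
        # direct computation: q_(i) = min_j>=i (4 p_(j) / j) = 0.04 for all
        np.testing.assert_allclose(
            m.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_empty(self):
        assert len(m.bh_adjust([])) == 0

    def test_against_naive_definition(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            p = rng.random(rng.integers(1, 80))
            np.testing.assert_allclose(
                m.bh_adjust(p), bh_step_up_naive(p), atol=1e-12
            )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, p):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        q = m.bh_adjust(p)
        q_perm = m.bh_adjust(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.bh_adjust([0.5, 1.5])


def two_sample_bins(ref_rows, sample_rows):
    return make_bins(ref_rows), make_bins(sample_rows)


class TestCallDmrs:
    def test_low_coverage_bin_excluded_from_testing_and_multiplicity(self):
        # bin at 0 has only 3 covered sites in the sample: not tested, and
        # the BH multiplicity is computed over the remaining bins only
        ref = make_bins(
            [("c1", 0, "CG", 50, 0, 5), ("c1", 100, "CG", 50, 0, 5),
             ("c1", 200, "CG", 48, 2, 5)]
        )
        sam = make_bins(
            [("c1", 0, "CG", 0, 50, 3), ("c1", 100, "CG", 0, 50, 5),
             ("c1", 200, "CG", 2, 48, 5)]
        )
        tested = m.dmr_test_table(ref, sam, "CG")
        assert sorted(tested["start"]) == [100, 200]
        np.testing.assert_allclose(
            tested["q"].to_numpy(), bh_step_up_naive(tested["p_raw"]), atol=1e-12
        )

    def test_effect_size_threshold_blocks_small_differences(self):
        # CHG difference 0.15 < 0.2: significant p but no DMR
        ref = make_bins([("c1", 0, "CHG", 500, 500, 6)])
        sam = make_bins([("c1", 0, "CHG", 350, 650, 6)])
        tested = m.dmr_test_table(ref, sam, "CHG")
        assert tested["q"].iloc[0] < 0.01
        assert len(m.call_dmrs(ref, sam, "CHG")) == 0

    def test_large_difference_called_hypo(self):
        ref = make_bins([("c1", 0, "CHG", 500, 500, 6)])
        sam = make_bins([("c1", 0, "CHG", 100, 900, 6)])
        dmrs = m.call_dmrs(ref, sam, "CHG")
        assert len(dmrs) == 1
        assert dmrs["direction"].iloc[0] == "hypo"
        assert len(m.call_dmrs(ref, sam, "CHG", direction_filter="hyper")) == 0

    def test_swapping_samples_flips_direction_keeps_p(self):
        ref = make_bins([("c1", 0, "CHG", 500, 500, 6), ("c1", 100, "CHG", 90, 10, 5)])
        sam = make_bins([("c1", 0, "CHG", 100, 900, 6), ("c1", 100, "CHG", 85, 15, 5)])
        fwd = m.dmr_test_table(ref, sam, "CHG")
        rev = m.dmr_test_table(sam, ref, "CHG")
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)
        d_fwd = m.call_dmrs(ref, sam, "CHG")
        d_rev = m.call_dmrs(sam, ref, "CHG")
        assert d_fwd["direction"].tolist() == ["hypo"]
        assert d_rev["direction"].tolist() == ["hyper"]

    def test_min_cov_mode_variants(self):
        ref = make_bins([("c1", 0, "CG", 50, 0, 5)])
        sam = make_bins([("c1", 0, "CG", 0, 50, 3)])
        assert len(m.dmr_test_table(ref, sam, "CG", min_cov_mode="each")) == 0
        assert len(m.dmr_test_table(ref, sam, "CG", min_cov_mode="either")) == 1
        assert len(m.dmr_test_table(ref, sam, "CG", min_cov_mode="pooled")) == 1

    def test_mismatched_bin_size_rejected(self):
        ref = make_bins([("c1", 0, "CG", 5, 5, 4)])
        sam = make_bins([("c1", 0, "CG", 5, 5, 4)])
        sam["end"] = 200
        with pytest.raises(ValueError, match="bin_size"):
            m.call_dmrs(ref, sam, "CG")

    def test_unknown_context_rejected(self):
        ref = make_bins([("c1", 0, "CG", 5, 5, 4)])
        with pytest.raises(ValueError, match="context"):
            m.call_dmrs(ref, ref, "CpG")

    def test_monotonicity_in_fdr_and_min_diff(self, small_sim):
        ref = m.bin_methylome(small_sim["calls_wt"])
        sam = m.bin_methylome(small_sim["calls_mut"])
        loose = m.call_dmrs(ref, sam, "CHG", fdr=0.05, min_diff=0.1)
        base = m.call_dmrs(ref, sam, "CHG")
        strict = m.call_dmrs(ref, sam, "CHG", fdr=0.001, min_diff=0.4)
        keys = lambda d: set(zip(d["chrom"], d["start"]))
        assert keys(strict) <= keys(base) <= keys(loose)

    def test_identical_truth_yields_no_dmrs(self):
        """Null comparison: two libraries from one truth, <=2 DMRs/context."""
        cfg = m.SimConfig(
            seed=21, genome=m.GenomeParams(n_chroms=1, chrom_length_bp=300_000)
        )
        genome, comps = m.simulate_genome(cfg)
        feats = m.simulate_features(genome, comps, cfg)
        sites = m.enumerate_cytosines(genome)
        truth = m.simulate_true_methylome(sites, feats, comps, cfg)
        b1 = m.bin_methylome(m.simulate_counts(truth, cfg, replicate=0))
        b2 = m.bin_methylome(m.simulate_counts(truth, cfg, replicate=1))
        for ctx in m.CONTEXTS:
            assert len(m.call_dmrs(b1, b2, ctx)) <= 2


class TestOverlapDmrSets:
    @staticmethod
    def dmr_set(starts, context="CG"):
        return pd.DataFrame(
            {
                "chrom": "c1",
                "start": starts,
                "end": [s + 100 for s in starts],
                "context": context,
                "level_a": 0.9,
                "level_b": 0.1,
                "p_raw": 1e-9,
                "q": 1e-8,
                "direction": "hypo",
            }
        )

    def test_partition(self):
        part = m.overlap_dmr_sets({"a": self.dmr_set([100, 200]),
                                   "b": self.dmr_set([200, 300])})
        assert part[frozenset({"a"})] == [("c1", 100)]
        assert part[frozenset({"b"})] == [("c1", 300)]
        assert part[frozenset({"a", "b"})] == [("c1", 200)]

    def test_disjoint(self):
        part = m.overlap_dmr_sets({"a": self.dmr_set([0]), "b": self.dmr_set([500])})
        assert frozenset({"a", "b"}) not in part

    def test_subset(self):
        part = m.overlap_dmr_sets(
            {"a": self.dmr_set([100]), "b": self.dmr_set([100, 200])}
        )
        assert frozenset({"a"}) not in part
        assert len(part[frozenset({"a", "b"})]) == 1

    def test_counts_conserve_union(self):
        sets = {
            "a": self.dmr_set([0, 100, 200]),
            "b": self.dmr_set([100, 300]),
            "c": self.dmr_set([200, 300, 400]),
        }
        counts = m.venn_counts(m.overlap_dmr_sets(sets))
        union = {(c, s) for df in sets.values() for c, s in zip(df.chrom, df.start)}
        assert sum(counts.values()) == len(union)

    def test_mixed_contexts_rejected(self):
        with pytest.raises(ValueError, match="context"):
            m.overlap_dmr_sets(
                {"a": self.dmr_set([0], "CG"), "b": self.dmr_set([0], "CHG")}
            )


class TestLevelMatrixAndClustering:
    def test_single_bin_level(self):
        bins = make_bins([("c1", 0, "CG", 3, 1, 1)])
        mat = m.dmr_level_matrix([("c1", 0)], {"s": bins}, "CG")
        assert mat.loc[("c1", 0), "s"] == 0.75

    def test_uncovered_bin_is_nan_not_zero(self):
        bins = make_bins([("c1", 0, "CG", 0, 0, 0)])
        mat = m.dmr_level_matrix([("c1", 0), ("c1", 100)], {"s": bins}, "CG")
        assert mat["s"].isna().all()

    def test_null_simulation_columns_agree(self, small_cfg):
        genome, comps = m.simulate_genome(small_cfg)
        feats = m.simulate_features(genome, comps, small_cfg)
        sites = m.enumerate_cytosines(genome)
        truth = m.simulate_true_methylome(sites, feats, comps, small_cfg)
        samples = {
            f"rep{i}": m.bin_methylome(m.simulate_counts(truth, small_cfg, replicate=i))
            for i in range(3)
        }
        some = samples["rep0"]
        cg = some[(some["context"] == "CHG") & (some["n_covered_sites"] >= 4)]
        bins = list(zip(cg["chrom"], cg["start"]))[:2000]
        mat = m.dmr_level_matrix(bins, samples, "CHG")
        means = mat.mean(axis=0, skipna=True)
        assert means.max() - means.min() < 0.02

    def test_first_merge_is_closest_pair(self):
        # pairwise distances: d(0,1)=0.1 < d(1,2)=1.345 < d(0,2)=sqrt(2)
        mat = pd.DataFrame([[0, 0], [0, 0.1], [1, 1]], columns=["a", "b"])
        _, merges = m.cluster_rows(mat)
        assert sorted(merges[0, :2].astype(int).tolist()) == [0, 1]

    def test_identical_rows_merge_at_zero_height(self):
        mat = pd.DataFrame([[0.5, 0.5]] * 4, columns=["a", "b"])
        _, merges = m.cluster_rows(mat)
        np.testing.assert_allclose(merges[:, 2], 0.0)

    def test_row_permutation_preserves_heights(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.random((12, 3)), columns=list("abc"))
        _, merges1 = m.cluster_rows(mat)
        perm = mat.iloc[rng.permutation(len(mat))].reset_index(drop=True)
        _, merges2 = m.cluster_rows(perm)
        np.testing.assert_allclose(
            np.sort(merges1[:, 2]), np.sort(merges2[:, 2]), atol=1e-12
        )

    def test_nan_rows_imputed_or_dropped(self):
        mat = pd.DataFrame(
            [[0.1, np.nan, 0.3], [np.nan, np.nan, 0.9], [0.2, 0.2, 0.2]],
            columns=list("abc"),
        )
        ordered, _ = m.cluster_rows(mat)
        assert len(ordered) == 2  # the <2-defined row is dropped

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            m.cluster_rows(pd.DataFrame([[1.0, 2.0]], columns=["a", "b"]))


class TestAnnotateOverlap:
    features = pd.DataFrame(
        {
            "chrom": ["c1", "c1"],
            "start": [150, 200],
            "end": [400, 300],
            "kind": ["TE", "PCG"],
        }
    )

    @staticmethod
    def dmrs(starts):
        return pd.DataFrame(
            {"chrom": "c1", "start": starts, "end": [s + 100 for s in starts]}
        )

    def test_one_bp_overlap_counts(self):
        out = m.annotate_dmr_overlap(self.dmrs([100]), self.features)
        assert out.set_index("label").loc["TE", "count"] == 1

    def test_half_open_boundary_no_overlap(self):
        out = m.annotate_dmr_overlap(
            self.dmrs([100]), self.features[self.features["kind"] == "PCG"]
        )
        assert out.set_index("label").loc["PCG", "count"] == 0

    def test_bin_can_count_toward_both_labels_and_accounting(self):
        out = m.annotate_dmr_overlap(self.dmrs([250, 900]), self.features).set_index(
            "label"
        )
        assert out.loc["TE", "count"] == 1
        assert out.loc["PCG", "count"] == 1
        assert out.loc["neither", "count"] == 1
        assert out.loc["TE", "count"] + out.loc["PCG", "count"] + out.loc[
            "neither", "count"
        ] >= 2


class TestDmrBedIO:
    def test_roundtrip(self, tmp_path):
        dmrs = TestOverlapDmrSets.dmr_set([100, 300], "CHG")
        path = tmp_path / "dmrs.bed"
        m.write_dmrs_bed(dmrs, path)
        back = m.read_dmrs_bed(path)
        assert back["start"].tolist() == [100, 300]
        assert (back["context"] == "CHG").all()
        assert back["direction"].tolist() == ["hypo", "hypo"]
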