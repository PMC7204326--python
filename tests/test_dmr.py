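"""Tests of the DMR caller and its filtering/annotation procedures."""

import numpy as np
import pytest

from spermpure.dmr import (
    DMRParams,
    annotate_promoters,
    call_dmrs,
    case_control_params,
    intersect_gene_list,
    merge_dmr_sets,
    per_cpg_group_diff,
    range_filter,
    rank_for_validation,
    region_sample_means,
    segment_candidates,
    soma_germ_params,
)
from spermpure.io import GeneModel, Region
from spermpure.simulate import build_references, simulate_wgbs_sample

from .conftest import make_track, recovery_genome_spec


class TestPerCpgDiff:
    def test_full_separation(self):
        a = [make_track([(10, 0)] * 3)]
        b = [make_track([(0, 10)] * 3)]
        d, usable = per_cpg_group_diff(a, b, min_cov=5)
        assert usable.all()
        assert d == pytest.approx([1.0, 1.0, 1.0])

    def test_low_coverage_site_unusable(self):
        a = [make_track([(10, 0), (4, 0)])]  # second site depth 4 < 5
        b = [make_track([(0, 10), (0, 10)])]
        _, usable = per_cpg_group_diff(a, b, min_cov=5)
        assert usable.tolist() == [True, False]

    def test_equal_groups_zero_diff(self):
        a = [make_track([(5, 5)] * 4)]
        b = [make_track([(5, 5)] * 4)]
        d, _ = per_cpg_group_diff(a, b, min_cov=5)
        assert d == pytest.approx([0.0] * 4)

    def test_disjoint_site_universe_rejected(self):
        a = [make_track([(5, 5)] * 3)]
        b = [make_track([(5, 5)] * 3, positions=[1, 2, 3])]
        with pytest.raises(ValueError, match="site universe"):
            per_cpg_group_diff(a, b, min_cov=5)


class TestSegmentation:
    def _run(self, n, d_value=0.9, positions=None, min_cpg=10):
        template = make_track([(1, 1)] * n, positions=positions)
        diffs = np.full(n, d_value)
        usable = np.ones(n, dtype=bool)
        params = DMRParams(min_cpg=min_cpg, min_diff=0.8)
        return segment_candidates(template, diffs, usable, params)

    def test_long_run_becomes_candidate(self):
        cands = self._run(12)
        assert len(cands) == 1

    def test_short_run_dropped(self):
        assert self._run(9) == []

    def test_large_gap_splits_run(self):
        positions = [100 + 10 * i for i in range(8)] + [4000 + 10 * i for i in range(8)]
        cands = self._run(16, positions=positions, min_cpg=5)
        assert len(cands) == 2
        assert cands[0].end <= 200 and cands[1].start >= 4000

    def test_sign_change_splits_run(self):
        template = make_track([(1, 1)] * 12)
        diffs = np.array([0.9] * 6 + [-0.9] * 6)
        cands = segment_candidates(
            template, diffs, np.ones(12, bool), DMRParams(min_cpg=5, min_diff=0.8)
        )
        assert len(cands) == 2


class TestCaller:
    def test_identical_groups_yield_nothing(self, small_refs):
        tracks = [
            simulate_wgbs_sample(small_refs, 0.0, f"s{i}", seed=i) for i in range(4)
        ]
        assert call_dmrs(tracks[:2], tracks[:2], soma_germ_params()) == []

    def test_moderate_difference_fails_stringent_threshold(self):
        # planted difference 0.5 < required 0.8
        a = [make_track([(15, 0)] * 12, sample_id=f"a{i}") for i in range(2)]
        b = [make_track([(7, 8)] * 12, sample_id=f"b{i}") for i in range(2)]
        assert call_dmrs(a, b, soma_germ_params()) == []
        relaxed = case_control_params()
        assert len(call_dmrs(a, b, relaxed)) == 1

    def test_recovery_on_small_planted_genome(self):
        spec = recovery_genome_spec(n_background=8000, n_planted=20)
        refs = build_references(spec, seed=9)
        planted = refs.regions_of("germcell_promoter")
        a = [simulate_wgbs_sample(refs, 0, f"sp{i}", seed=30 + i) for i in range(2)]
        b = [
            simulate_wgbs_sample(refs, 0, f"bl{i}", seed=60 + i, tissue="soma")
            for i in range(2)
        ]
        dmrs = call_dmrs(a, b, soma_germ_params())

        def hits(region, pad=0):
            return any(
                d.region.start < region.end + pad and region.start - pad < d.region.end
                for d in dmrs
            )

        assert sum(hits(p) for p in planted) >= 19
        for d in dmrs:  # no calls away from planted regions
            assert any(
                d.region.start < p.end + 1000 and p.start - 1000 < d.region.end
                for p in planted
            )
        for d in dmrs:  # every reported DMR satisfies all filters
            params = soma_germ_params()
            assert d.n_cpg >= params.min_cpg
            assert abs(d.diff) >= params.min_diff
            assert min(d.mean_cov_per_sample) >= params.min_cov
            assert d.q <= params.max_q


class TestMerge:
    def _dmrs_from(self, tracks_a, tracks_b, regions):
        from spermpure.dmr import DMR

        out = []
        for r in regions:
            out.append(
                DMR(region=r, n_cpg=1, mean_a=1.0, mean_b=0.0, diff=1.0,
                    mean_cov_per_sample=[10.0], p=0.01, q=0.01, direction="a_hyper")
            )
        return out

    @pytest.fixture()
    def tracks(self):
        positions = list(range(100, 400, 10))
        a = [make_track([(10, 0)] * len(positions), positions=positions)]
        b = [make_track([(0, 10)] * len(positions), positions=positions)]
        return a, b

    def test_overlapping_regions_union(self, tracks):
        a, b = tracks
        s1 = self._dmrs_from(a, b, [Region("chr1", 100, 200)])
        s2 = self._dmrs_from(a, b, [Region("chr1", 150, 300)])
        merged = merge_dmr_sets(s1, s2, a, b)
        assert len(merged) == 1
        assert (merged[0].region.start, merged[0].region.end) == (100, 300)
        assert merged[0].diff == pytest.approx(1.0)

    def test_book_ended_regions_merge(self, tracks):
        a, b = tracks
        s1 = self._dmrs_from(a, b, [Region("chr1", 100, 200)])
        s2 = self._dmrs_from(a, b, [Region("chr1", 200, 250)])
        merged = merge_dmr_sets(s1, s2, a, b)
        assert len(merged) == 1
        assert (merged[0].region.start, merged[0].region.end) == (100, 250)

    def test_disjoint_pass_through(self, tracks):
        a, b = tracks
        s1 = self._dmrs_from(a, b, [Region("chr1", 100, 150)])
        s2 = self._dmrs_from(a, b, [Region("chr1", 300, 390)])
        merged = merge_dmr_sets(s1, s2, a, b)
        assert [(d.region.start, d.region.end) for d in merged] == [(100, 150), (300, 390)]

    def test_idempotent_and_commutative(self, tracks):
        a, b = tracks
        s1 = self._dmrs_from(a, b, [Region("chr1", 100, 200)])
        s2 = self._dmrs_from(a, b, [Region("chr1", 150, 300), Region("chr1", 350, 390)])

        def key(dmrs):
            return [(d.region.start, d.region.end, round(d.diff, 9)) for d in dmrs]

        m12 = merge_dmr_sets(s1, s2, a, b)
        m21 = merge_dmr_sets(s2, s1, a, b)
        assert key(m12) == key(m21)
        again = merge_dmr_sets(m12, m12, a, b)
        assert key(again) == key(m12)

    def test_intersection_mode(self, tracks):
        a, b = tracks
        s1 = self._dmrs_from(a, b, [Region("chr1", 100, 200), Region("chr1", 300, 350)])
        s2 = self._dmrs_from(a, b, [Region("chr1", 150, 250)])
        merged = merge_dmr_sets(s1, s2, a, b, mode="intersection")
        assert [(d.region.start, d.region.end) for d in merged] == [(100, 250)]


class TestAnnotation:
    def _dmr(self, start, end):
        from spermpure.dmr import DMR

        return DMR(region=Region("chr1", start, end), n_cpg=10, mean_a=0.0,
                   mean_b=0.9, diff=-0.9, mean_cov_per_sample=[10.0], p=0.001,
                   q=0.01, direction="b_hyper")

    def test_promoter_boundary_half_open(self):
        genes = [GeneModel("g1", "chr1", 10_000)]
        # promoter is [8000, 12000); one-bp overlap counts, book-ended does not
        assert annotate_promoters([self._dmr(11_999, 12_050)], genes) == [["g1"]]
        assert annotate_promoters([self._dmr(12_000, 12_050)], genes) == [[]]

    def test_excluded_biotypes(self):
        genes = [
            GeneModel("ps", "chr1", 10_000, biotype="pseudogene"),
            GeneModel("linc", "chr1", 10_000, biotype="lncRNA"),
        ]
        assert annotate_promoters([self._dmr(9_000, 9_100)], genes) == [["linc"]]

    def test_intersect_gene_list_exhaustive(self):
        dmrs = [self._dmr(i * 1000, i * 1000 + 100) for i in range(10)]
        genes = [f"g{i % 8}" for i in range(10)]
        ann = [[g] for g in genes]
        keep = {"g0", "g1", "g2", "g3", "g4"}
        subset, sub_ann, n_genes = intersect_gene_list(dmrs, ann, keep)
        expected = [d for d, a in zip(dmrs, ann) if a[0] in keep]
        assert subset == expected
        assert n_genes == 5
        empty, _, n0 = intersect_gene_list(dmrs, ann, set())
        assert empty == [] and n0 == 0
        all_in, _, n_all = intersect_gene_list(dmrs, ann, set(genes))
        assert all_in == dmrs and n_all == 8


class TestRangeFilterAndRanking:
    def _dmr_at(self, start=100, end=140, diff=0.4):
        from spermpure.dmr import DMR

        return DMR(region=Region("chr1", start, end), n_cpg=4, mean_a=0.5 + diff,
                   mean_b=0.5, diff=diff, mean_cov_per_sample=[10.0], p=0.01,
                   q=0.01, direction="a_hyper")

    def _ref_tracks(self, means):
        # 4 CpGs at depth 10 inside [100, 140)
        return [
            make_track([(round(m * 10), 10 - round(m * 10))] * 4,
                       sample_id=f"r{i}", positions=[100, 110, 120, 130])
            for i, m in enumerate(means)
        ]

    def test_within_range_kept(self):
        kept = range_filter([self._dmr_at()], self._ref_tracks([0.1, 0.1, 0.2]))
        assert len(kept) == 1

    def test_wide_range_dropped(self):
        assert range_filter([self._dmr_at()], self._ref_tracks([0.1, 0.45])) == []

    def test_boundary_range_dropped_strict(self):
        assert range_filter([self._dmr_at()], self._ref_tracks([0.1, 0.4])) == []

    def test_rank_by_out_of_range_counts(self):
        d1, d2, d3 = (self._dmr_at(100 * i, 100 * i + 40, diff=0.3 + 0.1 * i)
                      for i in (1, 2, 3))
        ref = [[0.1, 0.2]] * 3
        test = [
            [0.15] * 20,                      # all inside
            [0.5] * 5 + [0.15] * 15,          # 5 outside
            [0.15] * 20,                      # all inside
        ]
        ranked = rank_for_validation([d1, d2, d3], ref, test, top_k=3)
        assert ranked[0][0] is d2 and ranked[0][1] == 5
        # remaining tie on count 0 broken by larger |diff| (d3 over d1)
        assert ranked[1][0] is d3 and ranked[2][0] is d1

    def test_planted_shift_ranks_first(self, small_refs):
        rng = np.random.default_rng(0)
        regions = small_refs.regions_of("germcell_promoter")[:6]
        from spermpure.dmr import DMR

        dmrs = [
            DMR(region=r, n_cpg=10, mean_a=0.4, mean_b=0.1, diff=0.3,
                mean_cov_per_sample=[10.0], p=0.01, q=0.01, direction="a_hyper")
            for r in regions
        ]
        ref = [rng.uniform(0.1, 0.2, size=10) for _ in regions]
        test = [rng.uniform(0.1, 0.2, size=20) for _ in regions]
        test[3] = rng.uniform(0.4, 0.6, size=20)  # planted shifted DMR
        ranked = rank_for_validation(dmrs, ref, test, top_k=2)
        assert ranked[0][0] is dmrs[3] and ranked[0][1] == 20
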