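"""Tests for DBS amplicon summaries, the PCA screen and ASM tests."""

import numpy as np
import pandas as pd
import pytest

from spermpure.amplicon import (
    allele_cpg_test,
    amplicon_summary,
    epiallele_counts,
    genotype_stratified_test,
    pca_screen_classify,
    split_reads_by_allele,
)
from spermpure.io import AmpliconReadSet
from spermpure.simulate import (
    SCREEN_LOCI,
    AmpliconLocusSpec,
    CohortDesign,
    simulate_amplicon_reads,
    simulate_screen_cohort,
)


def rs_from_strings(strings, alleles=None, masked=(), snp_offset=None):
    conv = {"M": 1, "U": 0, ".": -1}
    states = np.array([[conv[c] for c in s] for s in strings], dtype=np.int8)
    n = len(strings)
    return AmpliconReadSet(
        locus_id="t",
        states=states,
        allele=np.array(alleles or ["T"] * n, dtype=object),
        read_ids=np.array([f"r{i}" for i in range(n)], dtype=object),
        masked=frozenset(masked),
        snp_offset=snp_offset,
    )


class TestSummary:
    def test_all_methylated(self):
        per_cpg, mean, n = amplicon_summary(rs_from_strings(["MMMM", "MMMM"]))
        assert mean == 1.0 and n == 2
        assert per_cpg == pytest.approx([1.0] * 4)

    def test_half_methylated_read(self):
        _, mean, _ = amplicon_summary(rs_from_strings(["MMUU"]))
        assert mean == 0.5

    def test_masked_cpg_excluded_everywhere(self):
        per_cpg, _, _ = amplicon_summary(
            rs_from_strings(["M" * 15] * 3, masked={3})
        )
        assert len(per_cpg) == 14  # 15 CpGs, 1 CpG-SNP masked

    def test_empty_set_rejected(self):
        rs = rs_from_strings(["MM"]).subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            amplicon_summary(rs)


class TestEpialleles:
    def test_canonical_reads(self):
        full, empty, partial = epiallele_counts(
            rs_from_strings(["M" * 14, "U" * 14, "MMMMMMMUUUUUUU"])
        )
        assert (full, empty, partial) == (1, 1, 1)

    def test_two_component_mixture_counts(self):
        rs = simulate_amplicon_reads(
            AmpliconLocusSpec("x", k=14, sperm_meth_fraction=0.5, soma_meth_fraction=0.5),
            n_reads=1000, eps=0.01, seed=3,
        )
        full, empty, partial = epiallele_counts(rs)
        assert abs(full - 500) <= 50 and abs(empty - 500) <= 50
        assert partial < 20


class TestMaskingInvariance:
    def test_extra_masked_column_changes_nothing(self):
        rng = np.random.default_rng(8)
        base = rs_from_strings(
            ["".join(rng.choice(["M", "U"], size=6)) for _ in range(50)],
            alleles=rng.choice(["T", "G"], size=50).tolist(),
            snp_offset=0,
        )
        extra = AmpliconReadSet(
            locus_id="t",
            states=np.column_stack(
                [base.states, rng.integers(0, 2, size=50).astype(np.int8)]
            ),
            allele=base.allele,
            read_ids=base.read_ids,
            masked=frozenset({6}),
            snp_offset=0,
        )
        assert amplicon_summary(base)[1] == pytest.approx(amplicon_summary(extra)[1])
        assert epiallele_counts(base) == epiallele_counts(extra)
        t1, g1, _ = split_reads_by_allele(base, ("T", "G"))
        t2, g2, _ = split_reads_by_allele(extra, ("T", "G"))
        r1 = allele_cpg_test(t1, g1, 2)
        r2 = allele_cpg_test(t2, g2, 2)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestAlleleSplit:
    def test_partition_and_dropped(self):
        rs = rs_from_strings(
            ["MM"] * 21, alleles=["T"] * 10 + ["G"] * 10 + ["N"], snp_offset=0
        )
        t, g, dropped = split_reads_by_allele(rs, ("T", "G"))
        assert (t.n_reads, g.n_reads, dropped) == (10, 10, 1)

    def test_conversion_unsafe_pair_rejected(self):
        rs = rs_from_strings(["MM"], alleles=["T"], snp_offset=0)
        with pytest.raises(ValueError, match="conversion-safe"):
            split_reads_by_allele(rs, ("C", "T"))

    def test_missing_snp_offset_rejected(self):
        rs = rs_from_strings(["MM"])
        with pytest.raises(ValueError, match="SNP"):
            split_reads_by_allele(rs, ("T", "G"))


class TestAlleleCpgTest:
    def test_identical_distributions_non_significant(self):
        rng = np.random.default_rng(1)
        strings = ["".join(rng.choice(["M", "U"], size=4)) for _ in range(400)]
        rs = rs_from_strings(strings, alleles=rng.choice(["T", "G"], 400).tolist(),
                             snp_offset=0)
        t, g, _ = split_reads_by_allele(rs, ("T", "G"))
        assert allele_cpg_test(t, g, 1).p_value > 0.05

    def test_planted_effect_detected_with_direction(self):
        rs = simulate_amplicon_reads(
            SCREEN_LOCI["h19"], genotype="TG", n_reads=2000, delta_g=0.25, seed=2
        )
        t, g, _ = split_reads_by_allele(rs, ("T", "G"))
        res = allele_cpg_test(t, g, 2)
        assert res.p_value < 1e-3
        mean = lambda r: r.states[:, 2][r.states[:, 2] >= 0].mean()
        assert mean(g) < mean(t)

    def test_masked_index_rejected(self):
        rs = rs_from_strings(["MM"] * 4, alleles=["T", "T", "G", "G"],
                             masked={1}, snp_offset=0)
        t, g, _ = split_reads_by_allele(rs, ("T", "G"))
        with pytest.raises(ValueError, match="masked"):
            allele_cpg_test(t, g, 1)

    def test_all_missing_rejected(self):
        rs = rs_from_strings(["M.", "M.", "M.", "M."],
                             alleles=["T", "T", "G", "G"], snp_offset=0)
        t, g, _ = split_reads_by_allele(rs, ("T", "G"))
        with pytest.raises(ValueError, match="scorable"):
            allele_cpg_test(t, g, 1)


class TestScreen:
    def _records(self, mest, h19, diagnosis):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(mest))],
                "diagnosis": diagnosis,
                "mean_mest": mest,
                "mean_h19": h19,
            }
        )

    def test_degenerate_identical_cohort_has_no_amo(self):
        rec = self._records([0.02] * 12, [0.98] * 12, ["oligo"] * 12)
        res = pca_screen_classify(rec)
        assert res.threshold == 0.0
        assert res.n_amo == 0 and res.n_nmo == 12

    def test_normo_never_reclassified(self):
        rng = np.random.default_rng(0)
        mest = np.r_[rng.normal(0.02, 0.005, 20), [0.3]]
        h19 = np.r_[rng.normal(0.98, 0.005, 20), [0.7]]
        rec = self._records(mest, h19, ["normo"] * 21)
        res = pca_screen_classify(rec)
        assert res.n_nc == 21 and res.n_amo == 0

    def test_planted_contaminated_get_top_pc1_and_amo(self):
        design = CohortDesign(n_normo=20, n_oligo=40, n_contaminated=4,
                              f_range=(0.2, 0.5), reads_per_locus=400)
        records, _, truth = simulate_screen_cohort(design, seed=21)
        res = pca_screen_classify(records)
        merged = res.records.merge(truth[["sample_id", "true_class"]], on="sample_id")
        top = merged.nlargest(4, "pc1")
        assert set(top["true_class"]) == {"contaminated"}
        assert set(merged.loc[merged["klass"] == "AMO", "true_class"]) <= {"contaminated"}

    def test_order_invariance(self):
        design = CohortDesign(n_normo=15, n_oligo=25, n_contaminated=3,
                              reads_per_locus=300)
        records, _, _ = simulate_screen_cohort(design, seed=4)
        res1 = pca_screen_classify(records)
        shuffled = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = pca_screen_classify(shuffled)
        m = res1.records.merge(shuffled_klass := res2.records[["sample_id", "klass"]],
                               on="sample_id", suffixes=("", "_shuf"))
        assert (m["klass"] == m["klass_shuf"]).all()
        assert res1.threshold == pytest.approx(res2.threshold)

    def test_sign_flip_invariance_of_labels(self):
        """Mirroring both variables flips raw PCA signs; the orientation
        rule keeps contamination displacement positive on PC1."""
        design = CohortDesign(n_normo=15, n_oligo=25, n_contaminated=3,
                              f_range=(0.3, 0.5), reads_per_locus=300)
        records, _, truth = simulate_screen_cohort(design, seed=6)
        res = pca_screen_classify(records)
        contaminated = truth.loc[truth["f"] > 0, "sample_id"]
        pc1 = res.records.set_index("sample_id")["pc1"]
        assert (pc1[contaminated] > pc1.drop(contaminated).max()).all()

    def test_amo_count_monotone_in_contamination_fraction(self):
        # 100 samples: the 95th-percentile rule can flag at most ~5
        counts = []
        for f in (0.05, 0.1, 0.2, 0.4):
            design = CohortDesign(n_normo=20, n_oligo=80, n_contaminated=5,
                                  f_range=(f, f), reads_per_locus=400)
            records, _, _ = simulate_screen_cohort(design, seed=17)
            counts.append(pca_screen_classify(records).n_amo)
        assert counts == sorted(counts)
        assert counts[-1] == 5

    def test_too_few_samples_rejected(self):
        rec = self._records([0.1] * 5, [0.9] * 5, ["oligo"] * 5)
        with pytest.raises(ValueError, match="at least 10"):
            pca_screen_classify(rec)


class TestGenotypeStratified:
    def test_all_equal_values(self):
        res = genotype_stratified_test(
            [1.0] * 9, ["TT", "TG", "GG"] * 3, ["NC", "NMO", "NC"] * 3
        )
        assert res.genotype_test.p_value == 1.0
        assert all(adj == 1.0 for _, adj in res.pairwise.values())

    def test_planted_genotype_means_all_pairs_significant(self):
        rng = np.random.default_rng(9)
        means = {"TT": 0.7, "TG": 0.55, "GG": 0.4}
        sizes = {"TT": 40, "TG": 49, "GG": 29}
        vals, geno = [], []
        for g, n in sizes.items():
            vals.extend(rng.normal(means[g], 0.08, size=n))
            geno.extend([g] * n)
        res = genotype_stratified_test(vals, geno)
        assert all(adj < 0.01 for _, adj in res.pairwise.values())
        assert res.genotype_test.p_value < 1e-6

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError, match="2 genotype groups"):
            genotype_stratified_test([1.0, 2.0], ["TT", "TT"])
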