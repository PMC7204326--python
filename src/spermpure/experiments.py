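"""Benchmark experiments on synthetic data with known ground truth.

Each function runs one self-contained validation study — contamination
recovery, purity-classification operating characteristics, DMR-caller
recovery and null behavior, allele-specific-methylation detection and
calibration, and the screening-cohort structure — and returns its
headline numbers. The test suite and the reproduction script both call
these, so the published numbers are always recomputed from scratch.

Problem sizes follow the validation designs described in
docs/methods.md (e.g. 500-marker panels at 15x coverage, a 50,000-CpG
genome with 50 planted regions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .amplicon import (
    allele_cpg_test,
    genotype_stratified_test,
    pca_screen_classify,
    split_reads_by_allele,
)
from .dmr import call_dmrs, soma_germ_params
from .io import AmpliconReadSet
from .purity import classify_purity, estimate_contamination, panel_from_regions
from .simulate import (
    CLASS_LEVELS,
    SCREEN_LOCI,
    GenomeSpec,
    build_references,
    simulate_amplicon_reads,
    simulate_screen_cohort,
    simulate_wgbs_sample,
    study_design,
    xist_ddx4_clean,
)
from .stats import bonferroni_adjust, mann_whitney_u

F_GRID = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)


def _panel_spec(n_markers: int = 500) -> GenomeSpec:
    """Genome whose marker-class regions number exactly ``n_markers``."""
    return GenomeSpec(
        n_background_cpgs=2000,
        n_germcell_promoters=n_markers - 34 - 16 - 10 - 2,
        n_reverse_promoters=10,
        n_decoy_promoters=0,
        n_orphan_diffs=0,
        spikein_cpgs=300,
    )


def _recovery_spec(n_background: int = 50_000, n_planted: int = 50) -> GenomeSpec:
    """Genome with planted soma-germ regions whose observed-scale
    difference (~0.85) genuinely exceeds the 0.80 calling threshold."""
    return GenomeSpec(
        n_background_cpgs=n_background,
        n_oocyte_icrs=0,
        n_sperm_icrs=0,
        n_germcell_promoters=n_planted,
        n_reverse_promoters=0,
        n_decoy_promoters=0,
        n_orphan_diffs=0,
        n_xist_ddx4=0,
        spikein_cpgs=100,
        region_jitter=0.0,
        levels={**CLASS_LEVELS, "germcell_promoter": (0.04, 0.90)},
    )


def _reference_panel(seed: int, n_markers: int = 500, ref_coverage: float = 30.0):
    refs = build_references(_panel_spec(n_markers), seed=seed)
    sperm = [
        simulate_wgbs_sample(refs, 0.0, f"SP{i}", coverage_lambda=ref_coverage,
                             seed=seed + 11 + i)
        for i in range(2)
    ]
    soma = [
        simulate_wgbs_sample(refs, 0.0, f"BL{i}", coverage_lambda=ref_coverage,
                             seed=seed + 31 + i, tissue="soma")
        for i in range(2)
    ]
    panel = panel_from_regions(refs.marker_regions, sperm, soma)
    return refs, panel


def contamination_recovery(seed: int, f_grid=F_GRID, n_seeds: int = 3) -> dict:
    """Recover the somatic fraction of samples simulated on an f grid.

    500-marker panel, samples at 15x coverage, ``n_seeds`` replicates
    per grid point. Returns the worst absolute error of the weighted
    least-squares estimator.
    """
    rng = np.random.default_rng(seed)
    refs, panel = _reference_panel(int(rng.integers(2**31)))
    errors = []
    for f in f_grid:
        for _ in range(n_seeds):
            sample = simulate_wgbs_sample(
                refs, f, "s", coverage_lambda=15, seed=int(rng.integers(2**31))
            )
            f_hat, _, _ = estimate_contamination(sample, panel)
            errors.append(abs(f_hat - f))
    return {
        "max_abs_error": float(max(errors)),
        "mean_abs_error": float(np.mean(errors)),
        "n_samples": len(errors),
        "panel_size": len(panel),
    }


def purity_classification(
    seed: int, n_cohorts: int = 50, f_positive=(0.05, 0.1, 0.2, 0.5)
) -> dict:
    """Operating characteristics of the contamination verdict.

    Per seeded cohort, one pure sample (f = 0) and one sample at each
    positive somatic fraction are classified under defaults (tau = 0.06,
    >= 2 aberrant markers). Returns the false-positive count among pure
    samples and the detection rate among contaminated ones.
    """
    rng = np.random.default_rng(seed)
    refs, panel = _reference_panel(int(rng.integers(2**31)))
    false_pos = 0
    detected = 0
    n_pos = 0
    for _ in range(n_cohorts):
        for f in (0.0, *f_positive):
            sample = simulate_wgbs_sample(
                refs, f, "s", coverage_lambda=15, seed=int(rng.integers(2**31))
            )
            verdict = classify_purity(sample, panel).verdict
            if f == 0.0:
                false_pos += verdict == "contaminated"
            else:
                n_pos += 1
                detected += verdict == "contaminated"
    return {
        "false_positive_calls": int(false_pos),
        "n_pure": n_cohorts,
        "detection_rate_pct": 100.0 * detected / n_pos,
        "n_contaminated": n_pos,
    }


def dmr_recovery(seed: int, n_background: int = 50_000, n_planted: int = 50) -> dict:
    """Sensitivity/precision of the caller on planted soma-germ regions.

    2 vs 2 samples at 15x on a ``n_background``-CpG genome with
    ``n_planted`` regions meeting the stringent thresholds. A planted
    region counts as recovered if any call overlaps it; a call is a true
    positive if it lies within 1 kb of a planted region.
    """
    rng = np.random.default_rng(seed)
    refs = build_references(_recovery_spec(n_background, n_planted),
                            seed=int(rng.integers(2**31)))
    planted = refs.regions_of("germcell_promoter")
    a = [simulate_wgbs_sample(refs, 0, f"sp{i}", seed=int(rng.integers(2**31)))
         for i in range(2)]
    b = [simulate_wgbs_sample(refs, 0, f"bl{i}", seed=int(rng.integers(2**31)),
                              tissue="soma") for i in range(2)]
    dmrs = call_dmrs(a, b, soma_germ_params())

    def overlaps(x, y, pad=0):
        return x.start < y.end + pad and y.start - pad < x.end

    sens = np.mean([any(overlaps(d.region, p) for d in dmrs) for p in planted])
    prec = (
        np.mean([any(overlaps(d.region, p, 1000) for p in planted) for d in dmrs])
        if dmrs
        else 1.0
    )
    return {
        "sensitivity": float(sens),
        "precision": float(prec),
        "n_planted": len(planted),
        "n_called": len(dmrs),
    }


def dmr_null(seed: int, n_runs: int = 20, n_background: int = 50_000) -> dict:
    """Fraction of null runs (5 vs 6 samples from one reference) with 0 DMRs."""
    rng = np.random.default_rng(seed)
    refs = build_references(_recovery_spec(n_background, 0),
                            seed=int(rng.integers(2**31)))
    zero_runs = 0
    total_dmrs = 0
    for _ in range(n_runs):
        a = [simulate_wgbs_sample(refs, 0, f"a{i}", seed=int(rng.integers(2**31)))
             for i in range(5)]
        b = [simulate_wgbs_sample(refs, 0, f"b{i}", seed=int(rng.integers(2**31)))
             for i in range(6)]
        n = len(call_dmrs(a, b, soma_germ_params()))
        zero_runs += n == 0
        total_dmrs += n
    return {
        "zero_dmr_run_fraction": zero_runs / n_runs,
        "total_false_dmrs": total_dmrs,
        "n_runs": n_runs,
    }


def asm_detection(seed: int, n_reads_per_allele: int = 1000, delta: float = 0.25) -> dict:
    """Detect a planted allele-specific effect at the H19-like CpG3.

    A TG-heterozygote amplicon with 1000 reads per allele and a
    methylated-epiallele shift of ``delta`` on G reads; per-CpG
    Mann-Whitney tests between alleles, Bonferroni-adjusted over the 14
    analyzed CpGs.
    """
    locus = SCREEN_LOCI["h19"]
    rs = simulate_amplicon_reads(
        locus, genotype="TG", n_reads=2 * n_reads_per_allele,
        delta_g=delta, seed=seed,
    )
    t_reads, g_reads, _ = split_reads_by_allele(rs, ("T", "G"))
    cols = rs.unmasked_columns
    pvals = [allele_cpg_test(t_reads, g_reads, int(c)).p_value for c in cols]
    adj = bonferroni_adjust(pvals)
    target = int(np.where(cols == locus.asm_cpg)[0][0])

    def col_mean(r):
        v = r.states[:, locus.asm_cpg]
        return float(v[v >= 0].mean())

    return {
        "adjusted_p": float(adj[target]),
        "g_lower_than_t": bool(col_mean(g_reads) < col_mean(t_reads)),
        "t_mean": col_mean(t_reads),
        "g_mean": col_mean(g_reads),
        "n_reads_per_allele": n_reads_per_allele,
    }


def asm_null_calibration(seed: int, n_reps: int = 1000, alpha: float = 0.05) -> dict:
    """Type-I error of within-genotype phenotype tests under permutation.

    Per-sample CpG3 methylation values are drawn once for a 118-sample
    cohort (40/49/29 TT/TG/GG with genotype-dependent means); phenotype
    labels are then permuted within genotype in each replicate and the
    within-genotype NC-vs-NMO Mann-Whitney tests recomputed. Reports the
    fraction of tests significant at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    sizes = {"TT": 40, "TG": 49, "GG": 29}
    means = {"TT": 0.99, "TG": 0.86, "GG": 0.74}
    geno = np.concatenate([[g] * n for g, n in sizes.items()])
    values = np.concatenate(
        [np.clip(rng.normal(means[g], 0.03, size=n), 0, 1) for g, n in sizes.items()]
    )
    pheno = rng.permutation(
        np.array(["NC"] * 40 + ["NMO"] * (len(values) - 40), dtype=object)
    )
    n_sig = 0
    n_tests = 0
    for _ in range(n_reps):
        permuted = pheno.copy()
        for g in sizes:
            mask = geno == g
            permuted[mask] = rng.permutation(permuted[mask])
        for g in sizes:
            mask = geno == g
            a = values[mask & (permuted == "NC")]
            b = values[mask & (permuted == "NMO")]
            if a.size and b.size:
                n_tests += 1
                n_sig += mann_whitney_u(a, b).p_value < alpha
    return {
        "rejection_rate_pct": 100.0 * n_sig / n_tests,
        "n_tests": n_tests,
        "alpha": alpha,
    }


def screen_study(seed: int) -> dict:
    """Screen and genotype-analyze the study-emulation cohort.

    133 samples (40 normo, 93 oligo; 6 heavily contaminated, 9 mildly,
    1 epimutation-like). Runs the PCA screen, the XIST/DDX4 6% purity
    rule and the genotype-stratified CpG3 analysis on the clean subset.
    """
    records, readsets, truth = simulate_screen_cohort(study_design(), seed=seed)
    screen = pca_screen_classify(records)
    rec = screen.records
    clean = xist_ddx4_clean(rec)
    clean_rec = rec[clean]

    # per-sample CpG3 means over the H19-like amplicon for the clean subset
    vals, geno, pheno = [], [], []
    for _, row in clean_rec.iterrows():
        s = readsets[row["sample_id"]]["h19"].states[:, SCREEN_LOCI["h19"].asm_cpg]
        s = s[s >= 0]
        vals.append(float(s.mean()))
        geno.append(row["genotype"])
        pheno.append("NC" if row["diagnosis"] == "normo" else "NMO")
    strat = genotype_stratified_test(vals, geno, pheno)

    # pooled T-vs-G read-level test over clean TG heterozygotes
    tg_ids = clean_rec.loc[clean_rec["genotype"] == "TG", "sample_id"]
    h19 = [readsets[s]["h19"] for s in tg_ids]
    merged = AmpliconReadSet(
        locus_id="h19",
        states=np.vstack([r.states for r in h19]),
        allele=np.concatenate([r.allele for r in h19]),
        read_ids=np.concatenate([r.read_ids for r in h19]),
        masked=h19[0].masked,
        snp_offset=h19[0].snp_offset,
    )
    t_reads, g_reads, _ = split_reads_by_allele(merged, ("T", "G"))
    pooled = allele_cpg_test(t_reads, g_reads, SCREEN_LOCI["h19"].asm_cpg)

    amo_ids = set(rec.loc[rec["klass"] == "AMO", "sample_id"])
    true_abnormal = set(
        truth.loc[truth["true_class"].isin(["contaminated", "epimutation"]), "sample_id"]
    )
    return {
        "pc1_threshold": screen.threshold,
        "n_nc": screen.n_nc,
        "n_amo": screen.n_amo,
        "n_nmo": screen.n_nmo,
        "amo_ids_match_truth": amo_ids == true_abnormal,
        "n_clean_nmo": int(((rec["klass"] == "NMO") & clean).sum()),
        "n_genotype_set": int(clean.sum()),
        "genotype_kw_p": strat.genotype_test.p_value,
        "pairwise_adjusted_p": {
            f"{a}_vs_{b}": adj for (a, b), (_, adj) in strat.pairwise.items()
        },
        "within_genotype_p": {g: r.p_value for g, r in strat.within_genotype.items()},
        "pooled_t_vs_g_p": pooled.p_value,
        "n_samples": len(records),
    }
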