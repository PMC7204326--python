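"""Deep bisulfite sequencing (DBS) amplicon analysis.

A DBS amplicon yields thousands of single-molecule reads over one locus;
each read's CpG pattern is an epiallele. Imprinted loci in pure sperm
show one canonical epiallele (fully methylated for a paternally
methylated locus like H19, fully unmethylated for a maternally
methylated one like MEST); somatic DNA contributes the other epiallele.

This module covers:

* per-sample and per-CpG summaries with CpG-SNP masking,
* epiallele counting (fully methylated / fully unmethylated / partial),
* the PCA screening classifier: PC1 of per-sample MEST and H19 means,
  oriented so displacement toward the somatic profile (higher MEST,
  lower H19) is positive; samples above the cohort's 95th PC1
  percentile are abnormally methylated, splitting oligozoospermic
  samples into AMO and NMO while normozoospermic controls stay NC,
* allele-specific methylation: splitting reads by the SNP base they
  carry and comparing per-read CpG states between alleles, plus
  genotype-stratified sample-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import STATE_MISSING, AmpliconReadSet
from .stats import (
    TestResult,
    bonferroni_adjust,
    kruskal_wallis,
    mann_whitney_u,
    pca,
)


def _read_means(rs: AmpliconReadSet) -> np.ndarray:
    """Per-read mean over non-missing unmasked CpGs; NaN if none scorable."""
    cols = rs.unmasked_columns
    if cols.size == 0:
        raise ValueError("no unmasked CpGs")
    sub = rs.states[:, cols].astype(float)
    sub[sub == STATE_MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub, axis=1)


def amplicon_summary(rs: AmpliconReadSet) -> tuple[np.ndarray, float, int]:
    """(per-CpG means over unmasked columns, per-sample mean, read count).

    The per-sample mean is the mean over reads of the per-read mean over
    non-missing unmasked CpGs; reads with no scorable CpG are ignored.
    """
    if rs.n_reads == 0:
        raise ValueError("empty read set")
    cols = rs.unmasked_columns
    sub = rs.states[:, cols].astype(float)
    sub[sub == STATE_MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        per_cpg = np.nanmean(sub, axis=0)
    rm = _read_means(rs)
    rm = rm[~np.isnan(rm)]
    return per_cpg, float(rm.mean()), int(rm.size)


def epiallele_counts(
    rs: AmpliconReadSet, hi: float = 0.9, lo: float = 0.1
) -> tuple[int, int, int]:
    """(n fully methylated, n fully unmethylated, n partial) reads.

    Classified on the per-read mean over non-missing unmasked CpGs:
    >= hi fully methylated, <= lo fully unmethylated, else partial.
    """
    if rs.n_reads == 0:
        raise ValueError("empty read set")
    rm = _read_means(rs)
    rm = rm[~np.isnan(rm)]
    full_meth = int((rm >= hi).sum())
    full_unmeth = int((rm <= lo).sum())
    return full_meth, full_unmeth, int(rm.size) - full_meth - full_unmeth


# ---------------------------------------------------------------------------
# PCA screening classifier
# ---------------------------------------------------------------------------

# PC1 orientation: displacement toward the somatic profile means higher
# MEST (maternally methylated, sperm ~0, soma ~0.5) and lower H19
# (paternally methylated, sperm ~1, soma ~0.5).
SCREEN_ORIENTATION = np.array([1.0, -1.0])


@dataclass
class ScreenResult:
    records: pd.DataFrame  # input plus pc1 and klass columns
    threshold: float
    loadings: np.ndarray
    variance_explained: np.ndarray

    @property
    def n_amo(self) -> int:
        return int((self.records["klass"] == "AMO").sum())

    @property
    def n_nmo(self) -> int:
        return int((self.records["klass"] == "NMO").sum())

    @property
    def n_nc(self) -> int:
        return int((self.records["klass"] == "NC").sum())


def pca_screen_classify(
    records: pd.DataFrame,
    percentile: float = 95.0,
    scale: bool = False,
) -> ScreenResult:
    """Classify a screening cohort from MEST and H19 DBS means.

    PCA over (mean_mest, mean_h19) of all samples; PC1 oriented so that
    displacement toward the somatic expectation is positive; the
    threshold is the given percentile of PC1 over all samples, and an
    oligozoospermic sample is AMO iff its PC1 lies strictly above it
    (else NMO). Normozoospermic samples are NC regardless.
    """
    required = {"sample_id", "diagnosis", "mean_mest", "mean_h19"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    if len(records) < 10:
        raise ValueError("need at least 10 samples for the percentile threshold")
    X = records[["mean_mest", "mean_h19"]].to_numpy(dtype=float)
    if np.any(np.isnan(X)):
        raise ValueError("missing MEST/H19 values")
    if np.allclose(X.var(axis=0), 0.0):
        pc1 = np.zeros(len(records))
        loadings = np.eye(2)
        varexp = np.array([0.0, 0.0])
    else:
        res = pca(X, scale=scale, orientation=SCREEN_ORIENTATION)
        pc1 = res.scores[:, 0]
        loadings = res.loadings
        varexp = res.variance_explained
    threshold = float(np.percentile(pc1, percentile))
    out = records.copy()
    out["pc1"] = pc1
    out["klass"] = np.where(
        out["diagnosis"] == "normo",
        "NC",
        np.where(pc1 > threshold, "AMO", "NMO"),
    )
    return ScreenResult(
        records=out, threshold=threshold, loadings=loadings, variance_explained=varexp
    )


# ---------------------------------------------------------------------------
# allele-specific methylation
# ---------------------------------------------------------------------------


def split_reads_by_allele(
    rs: AmpliconReadSet, alleles: tuple[str, str]
) -> tuple[AmpliconReadSet, AmpliconReadSet, int]:
    """Partition reads by the base at the amplicon's SNP position.

    Reads carrying neither expected base (including N) are dropped and
    counted. An allele pair containing C is rejected: on the
    bisulfite-converted strand an unmethylated C reads as T, so a C/T
    (or any C-containing) assay cannot distinguish allele from
    methylation state.
    """
    if rs.snp_offset is None:
        raise ValueError("read set has no SNP position")
    a1, a2 = (a.upper() for a in alleles)
    if "C" in (a1, a2):
        raise ValueError(
            f"allele pair ({a1}, {a2}) is not conversion-safe: "
            "C alleles are confounded by bisulfite conversion"
        )
    base = np.array([str(b).upper() for b in rs.allele], dtype=object)
    m1 = base == a1
    m2 = base == a2
    n_dropped = int((~(m1 | m2)).sum())
    return rs.subset(np.where(m1)[0]), rs.subset(np.where(m2)[0]), n_dropped


def allele_cpg_test(
    reads1: AmpliconReadSet, reads2: AmpliconReadSet, cpg_index: int
) -> TestResult:
    """Compare per-read methylation state at one CpG between allele groups.

    Binary states (missing reads excluded) compared by a two-sided
    Mann–Whitney U test.
    """
    for rs in (reads1, reads2):
        if cpg_index in rs.masked:
            raise ValueError(f"CpG {cpg_index} is masked")
        if not (0 <= cpg_index < rs.k):
            raise ValueError(f"CpG index {cpg_index} out of range")
    s1 = reads1.states[:, cpg_index]
    s2 = reads2.states[:, cpg_index]
    s1 = s1[s1 != STATE_MISSING].astype(float)
    s2 = s2[s2 != STATE_MISSING].astype(float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("no scorable reads at this CpG in at least one allele group")
    return mann_whitney_u(s1, s2, alternative="two_sided")


@dataclass
class GenotypeStratifiedResult:
    genotype_test: TestResult  # Kruskal-Wallis across genotype groups
    pairwise: dict  # (g1, g2) -> (raw TestResult, bonferroni-adjusted p)
    within_genotype: dict  # genotype -> TestResult (phenotype comparison)
    group_means: dict
    skipped_genotypes: list


def genotype_stratified_test(
    values: Sequence[float],
    genotype: Sequence[str],
    phenotype: Optional[Sequence[str]] = None,
) -> GenotypeStratifiedResult:
    """Genotype effect on a per-sample methylation value, phenotype-stratified.

    Kruskal–Wallis across genotype groups, pairwise Mann–Whitney U tests
    with Bonferroni adjustment, and — when phenotype labels are given —
    a Mann–Whitney U test between the two phenotypes within each
    genotype. Genotype groups with no samples are skipped.
    """
    values = np.asarray(values, dtype=float)
    genotype = np.asarray(genotype, dtype=object)
    order = [g for g in ("TT", "TG", "GG") if g in set(genotype)]
    order += sorted(set(genotype) - set(("TT", "TG", "GG")))
    groups = {g: values[genotype == g] for g in order}
    skipped = [g for g, v in groups.items() if v.size == 0]
    groups = {g: v for g, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("need at least 2 genotype groups represented")
    kw = kruskal_wallis(list(groups.values()))
    names = list(groups)
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    raw = {pair: mann_whitney_u(groups[pair[0]], groups[pair[1]]) for pair in pairs}
    adj = bonferroni_adjust([raw[pair].p_value for pair in pairs])
    pairwise = {pair: (raw[pair], float(a)) for pair, a in zip(pairs, adj)}
    within: dict[str, TestResult] = {}
    if phenotype is not None:
        phenotype = np.asarray(phenotype, dtype=object)
        for g in names:
            mask = genotype == g
            phenos = sorted(set(phenotype[mask]))
            if len(phenos) != 2:
                continue
            a = values[mask & (phenotype == phenos[0])]
            b = values[mask & (phenotype == phenos[1])]
            if a.size and b.size:
                within[g] = mann_whitney_u(a, b)
    return GenotypeStratifiedResult(
        genotype_test=kw,
        pairwise=pairwise,
        within_genotype=within,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        skipped_genotypes=skipped,
    )
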