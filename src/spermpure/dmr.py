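"""Differentially methylated region (DMR) calling, filtering and ranking.

The caller works on two groups of methylome tracks sharing a site
universe. It proceeds in the classical seed-and-extend style:

1. per-CpG group difference ``d_i`` over sites covered at >= min_cov in
   every sample of both groups;
2. maximal runs of consecutive usable CpGs with same-sign ``d_i`` and
   |d_i| >= seed_frac * min_diff, broken where the gap between
   consecutive usable CpGs exceeds max_gap bp; runs shorter than
   min_cpg CpGs are dropped;
3. candidate scoring: per-sample coverage-weighted region means, group
   difference, a Mann–Whitney U test on the pooled per-CpG-per-sample
   levels (the two groups contribute k*n_A vs k*n_B values — pooling
   CpGs is what makes small group sizes testable, at the price of
   treating CpGs within a region as replicates; see docs/methods.md),
   and Benjamini–Hochberg q-values across all candidates of the run;
4. filtering on n_cpg, |diff|, per-sample mean region coverage and q.

Two stringency presets mirror the two comparisons the procedures were
designed for: soma vs germline (>= 10 CpGs, >= 0.80 difference, coverage
>= 5, q <= 0.05) and case-control (>= 5 CpGs, >= 0.30, coverage >= 5,
q <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GeneModel, MethylomeTrack, Region
from .stats import bh_adjust, mann_whitney_u


@dataclass
class DMRParams:
    min_cpg: int = 10
    min_diff: float = 0.8
    min_cov: int = 5
    max_q: float = 0.05
    max_gap: int = 300
    seed_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.min_cpg < 1 or self.min_cov < 0 or self.max_gap < 1:
            raise ValueError("min_cpg, max_gap must be positive; min_cov non-negative")
        if not (0 < self.min_diff <= 1):
            raise ValueError("min_diff must be in (0, 1]")
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must be in (0, 1]")
        if not (0 < self.seed_frac <= 1):
            raise ValueError("seed_frac must be in (0, 1]")


def soma_germ_params() -> DMRParams:
    """Thresholds for the soma-vs-germline inventory: 10 CpGs / 0.80 / cov 5 / q 0.05."""
    return DMRParams(min_cpg=10, min_diff=0.8, min_cov=5, max_q=0.05)


def case_control_params() -> DMRParams:
    """Thresholds for the case-control comparison: 5 CpGs / 0.30 / cov 5 / q 0.05."""
    return DMRParams(min_cpg=5, min_diff=0.3, min_cov=5, max_q=0.05)


@dataclass
class DMR:
    region: Region
    n_cpg: int
    mean_a: float
    mean_b: float
    diff: float
    mean_cov_per_sample: list
    p: float
    q: float
    direction: str  # a_hyper | b_hyper


def _level_matrix(tracks: Sequence[MethylomeTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-sample levels and depths; asserts a shared site universe."""
    if not tracks:
        raise ValueError("empty group")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.same_sites(first):
            raise ValueError("tracks do not share a site universe")
    levels = np.vstack([t.levels for t in tracks])
    depths = np.vstack([t.depth for t in tracks])
    return levels, depths


def per_cpg_group_diff(
    group_a: Sequence[MethylomeTrack],
    group_b: Sequence[MethylomeTrack],
    min_cov: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site group difference d_i = mean(levels A) - mean(levels B).

    A site is usable iff its depth is >= min_cov in every sample of both
    groups; d_i is NaN at unusable sites.
    """
    la, da = _level_matrix(group_a)
    lb, db = _level_matrix(group_b)
    if la.shape[1] != lb.shape[1] or not group_a[0].same_sites(group_b[0]):
        raise ValueError("groups do not share a site universe")
    usable = (da >= min_cov).all(axis=0) & (db >= min_cov).all(axis=0)
    d = np.full(la.shape[1], np.nan)
    d[usable] = la[:, usable].mean(axis=0) - lb[:, usable].mean(axis=0)
    return d, usable


def segment_candidates(
    template: MethylomeTrack,
    diffs: np.ndarray,
    usable: np.ndarray,
    params: DMRParams,
) -> list[Region]:
    """Seed-and-extend candidate regions from per-CpG differences.

    Runs over consecutive usable CpGs with same-sign difference of
    magnitude >= seed_frac * min_diff; a bp gap > max_gap between
    consecutive run members splits the run. Runs with < min_cpg CpGs are
    dropped.
    """
    thr = params.seed_frac * params.min_diff
    out: list[Region] = []
    counter = 0
    for contig, (lo, hi) in template._blocks.items():
        idx = np.arange(lo, hi)[usable[lo:hi]]
        if idx.size == 0:
            continue
        d = diffs[idx]
        pos = template.pos[idx]
        run: list[int] = []
        run_sign = 0

        def flush(run_idx: list[int]) -> None:
            nonlocal counter
            if len(run_idx) >= params.min_cpg:
                counter += 1
                out.append(
                    Region(
                        contig,
                        int(template.pos[run_idx[0]]),
                        int(template.pos[run_idx[-1]]) + 1,
                        label=f"cand_{counter}",
                    )
                )

        for j in range(idx.size):
            sgn = 0 if abs(d[j]) < thr else (1 if d[j] > 0 else -1)
            if sgn == 0:
                flush(run)
                run, run_sign = [], 0
                continue
            if run and (sgn != run_sign or pos[j] - template.pos[run[-1]] > params.max_gap):
                flush(run)
                run = []
            run.append(int(idx[j]))
            run_sign = sgn
        flush(run)
    out.sort(key=lambda r: (r.contig, r.start))
    return out


def _score_region(
    region: Region,
    group_a: Sequence[MethylomeTrack],
    group_b: Sequence[MethylomeTrack],
    usable: np.ndarray,
) -> Optional[dict]:
    """Region summary statistics over usable CpGs; None if none usable."""
    sl = group_a[0].region_slice(region)
    site_idx = np.arange(sl.start, sl.stop)
    site_idx = site_idx[usable[sl.start : sl.stop]]
    if site_idx.size == 0:
        return None

    def sample_stats(tracks):
        means, covs, lv = [], [], []
        for t in tracks:
            nm = t.n_meth[site_idx]
            dp = t.depth[site_idx]
            means.append(nm.sum() / dp.sum())
            covs.append(float(dp.mean()))
            lv.append(nm / dp)
        return np.array(means), covs, np.concatenate(lv)

    means_a, cov_a, lv_a = sample_stats(group_a)
    means_b, cov_b, lv_b = sample_stats(group_b)
    p = mann_whitney_u(lv_a, lv_b, alternative="two_sided").p_value
    return {
        "n_cpg": int(site_idx.size),
        "mean_a": float(means_a.mean()),
        "mean_b": float(means_b.mean()),
        "mean_cov_per_sample": cov_a + cov_b,
        "p": float(p),
    }


def call_dmrs(
    group_a: Sequence[MethylomeTrack],
    group_b: Sequence[MethylomeTrack],
    params: DMRParams,
) -> list[DMR]:
    """Call DMRs between two groups of tracks sharing a site universe."""
    diffs, usable = per_cpg_group_diff(group_a, group_b, params.min_cov)
    candidates = segment_candidates(group_a[0], diffs, usable, params)
    scored = []
    for region in candidates:
        s = _score_region(region, group_a, group_b, usable)
        if s is not None:
            scored.append((region, s))
    if not scored:
        return []
    qvals = bh_adjust([s["p"] for _, s in scored])
    out = []
    for (region, s), q in zip(scored, qvals):
        diff = s["mean_a"] - s["mean_b"]
        if s["n_cpg"] < params.min_cpg:
            continue
        if abs(diff) < params.min_diff:
            continue
        if min(s["mean_cov_per_sample"]) < params.min_cov:
            continue
        if q > params.max_q:
            continue
        out.append(
            DMR(
                region=region,
                n_cpg=s["n_cpg"],
                mean_a=s["mean_a"],
                mean_b=s["mean_b"],
                diff=diff,
                mean_cov_per_sample=s["mean_cov_per_sample"],
                p=s["p"],
                q=float(q),
                direction="a_hyper" if diff > 0 else "b_hyper",
            )
        )
    out.sort(key=lambda d: (d.region.contig, d.region.start))
    return out


def merge_dmr_sets(
    set1: Sequence[DMR],
    set2: Sequence[DMR],
    tracks_a: Sequence[MethylomeTrack],
    tracks_b: Sequence[MethylomeTrack],
    min_cov: int = 5,
    mode: str = "union",
) -> list[DMR]:
    """Combine two DMR sets by interval union (GenomicRanges-style reduce).

    Overlapping or book-ended regions are merged; each merged record's
    statistics are recomputed from the tracks over the union region
    (q-values re-adjusted across the merged set). With
    ``mode="intersection"`` only merged regions supported by both input
    sets are kept.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    tagged = [(d.region, 1) for d in set1] + [(d.region, 2) for d in set2]
    if not tagged:
        return []
    tagged.sort(key=lambda t: (t[0].contig, t[0].start, t[0].end))
    merged: list[tuple[Region, set]] = []
    for region, tag in tagged:
        if (
            merged
            and merged[-1][0].contig == region.contig
            and region.start <= merged[-1][0].end  # overlap or book-ended
        ):
            prev, tags = merged[-1]
            merged[-1] = (
                Region(prev.contig, prev.start, max(prev.end, region.end), label=prev.label),
                tags | {tag},
            )
        else:
            merged.append((Region(region.contig, region.start, region.end, label=region.label), {tag}))
    if mode == "intersection":
        merged = [(r, t) for r, t in merged if t == {1, 2}]

    _, da = _level_matrix(tracks_a)
    _, db = _level_matrix(tracks_b)
    usable = (da >= min_cov).all(axis=0) & (db >= min_cov).all(axis=0)
    scored = []
    for i, (region, _) in enumerate(merged):
        s = _score_region(region, tracks_a, tracks_b, usable)
        if s is None:
            continue
        scored.append((replace(region, label=f"merged_{i + 1}"), s))
    if not scored:
        return []
    qvals = bh_adjust([s["p"] for _, s in scored])
    out = []
    for (region, s), q in zip(scored, qvals):
        diff = s["mean_a"] - s["mean_b"]
        out.append(
            DMR(
                region=region,
                n_cpg=s["n_cpg"],
                mean_a=s["mean_a"],
                mean_b=s["mean_b"],
                diff=diff,
                mean_cov_per_sample=s["mean_cov_per_sample"],
                p=s["p"],
                q=float(q),
                direction="a_hyper" if diff > 0 else "b_hyper",
            )
        )
    out.sort(key=lambda d: (d.region.contig, d.region.start))
    return out


ANNOTATABLE_BIOTYPES = frozenset({"protein_coding", "lncRNA", "miRNA"})


def annotate_promoters(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    window: int = 2000,
) -> list[list[str]]:
    """Gene ids whose promoter (TSS +/- window, clipped at 0) each DMR overlaps.

    Only protein-coding, lncRNA and miRNA genes are considered; overlap
    means >= 1 bp intersection of half-open intervals.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.biotype not in ANNOTATABLE_BIOTYPES:
            continue
        start = max(0, g.tss - window)
        end = g.tss + window
        if end > start:
            trees.setdefault(g.contig, IntervalTree()).addi(start, end, g.gene_id)
    out = []
    for d in dmrs:
        tree = trees.get(d.region.contig)
        if tree is None:
            out.append([])
        else:
            hits = sorted({iv.data for iv in tree.overlap(d.region.start, d.region.end)})
            out.append(hits)
    return out


def intersect_gene_list(
    dmrs: Sequence[DMR],
    annotations: Sequence[Sequence[str]],
    gene_set: set,
) -> tuple[list[DMR], list[list[str]], int]:
    """Keep DMRs annotated to at least one gene in ``gene_set``.

    Returns (subset, per-DMR genes restricted to the set, number of
    distinct genes hit).
    """
    subset, sub_ann, genes_hit = [], [], set()
    for d, ann in zip(dmrs, annotations):
        hit = [g for g in ann if g in gene_set]
        if hit:
            subset.append(d)
            sub_ann.append(hit)
            genes_hit.update(hit)
    return subset, sub_ann, len(genes_hit)


def region_sample_means(
    dmrs: Sequence[DMR],
    tracks: Sequence[MethylomeTrack],
    min_cov: int = 5,
) -> np.ndarray:
    """(n_dmrs, n_samples) coverage-weighted region means; NaN if unusable."""
    from .purity import region_mean_level

    out = np.full((len(dmrs), len(tracks)), np.nan)
    for i, d in enumerate(dmrs):
        for j, t in enumerate(tracks):
            out[i, j] = region_mean_level(t, d.region, min_cov=min_cov)
    return out


def range_filter(
    dmrs: Sequence[DMR],
    reference_tracks: Sequence[MethylomeTrack],
    max_range: float = 0.3,
    min_cov: int = 5,
) -> list[DMR]:
    """Keep DMRs whose reference-group per-sample means span < max_range.

    The within-group range (max - min of per-sample region means in the
    reference group) limits the influence of genetic background; the
    comparison is strict (< max_range), so a range of exactly max_range
    is dropped. DMRs with any missing reference mean are dropped.
    """
    means = region_sample_means(dmrs, reference_tracks, min_cov=min_cov)
    out = []
    for d, row in zip(dmrs, means):
        if np.any(np.isnan(row)):
            continue
        if row.max() - row.min() < max_range:
            out.append(d)
    return out


def rank_for_validation(
    dmrs: Sequence[DMR],
    reference_cohort_means: Sequence[Sequence[float]],
    test_cohort_means: Sequence[Sequence[float]],
    top_k: int = 10,
) -> list[tuple[DMR, int]]:
    """Rank DMRs by how many test-cohort values fall outside the reference range.

    Per DMR, the count of test-cohort region means strictly outside
    [min, max] of the reference cohort's means; ranking is by descending
    count, ties broken by larger |diff|, then by coordinate. Returns the
    top_k (DMR, count) pairs.
    """
    if not (len(dmrs) == len(reference_cohort_means) == len(test_cohort_means)):
        raise ValueError("per-DMR cohort value lists must align with dmrs")
    entries = []
    for d, ref, test in zip(dmrs, reference_cohort_means, test_cohort_means):
        ref = np.asarray(ref, dtype=float)
        test = np.asarray(test, dtype=float)
        ref = ref[~np.isnan(ref)]
        test = test[~np.isnan(test)]
        if ref.size == 0:
            count = 0
        else:
            count = int(((test < ref.min()) | (test > ref.max())).sum())
        entries.append((d, count))
    entries.sort(key=lambda e: (-e[1], -abs(e[0].diff), e[0].region.contig, e[0].region.start))
    return entries[:top_k]
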