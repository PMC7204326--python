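"""Somatic-contamination detection and quantification in sperm methylomes.

Sperm and somatic cells differ radically at imprinting control regions
(ICRs), germ-cell-specific gene promoters and X-linked loci such as
XIST, and at the DDX4 promoter. A sample whose DNA is a mixture of
sperm (fraction 1-f) and somatic DNA (fraction f, by DNA mass) shows,
at every such marker, the linearly displaced level

    m_i = (1 - f) * e_i + f * s_i

where e_i and s_i are the pure-sperm and pure-soma levels. This module

* builds marker panels from reference methylomes (via the DMR caller
  plus promoter/gene-list intersection, or directly from known regions),
* flags samples as contaminated when at least ``min_aberrant`` (default
  2) markers are displaced from the sperm expectation toward soma by
  more than ``tau`` (default 0.06, the "aberrant if above 6%" rule for
  unmethylated loci, applied symmetrically to methylated ones),
* estimates f by weighted least squares on the admixture model, and
* computes bisulfite conversion rates from an unmethylated spike-in.

f is a fraction of DNA mass (equivalently, of genome copies), not of
cells: sperm are haploid and somatic cells diploid, so the somatic cell
fraction is c = f / (2 - f) (see :func:`somatic_cell_fraction`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dmr import (
    DMRParams,
    annotate_promoters,
    call_dmrs,
    intersect_gene_list,
    soma_germ_params,
)
from .io import GeneModel, MethylomeTrack, Region

MARKER_CLASSES = (
    "germline_unmethylated",
    "germline_methylated",
    "oocyte_icr",
    "sperm_icr",
    "germcell_promoter",
)


@dataclass
class Marker:
    """A marker locus with expected sperm (e) and somatic (s) levels."""

    region: Region
    expected_sperm: float
    expected_soma: float
    klass: str

    def __post_init__(self) -> None:
        e, s = self.expected_sperm, self.expected_soma
        if not (0 <= e <= 1 and 0 <= s <= 1):
            raise ValueError("expected levels must lie in [0, 1]")
        if abs(s - e) < 0.3:
            raise ValueError(
                f"marker {self.region.label or self.region.contig}: "
                f"|soma - sperm| = {abs(s - e):.3f} < 0.3, not separable"
            )

    @property
    def separation(self) -> float:
        return self.expected_soma - self.expected_sperm


@dataclass
class PurityReport:
    sample_id: str
    marker_levels: list  # (marker, observed level or None, aberrant flag)
    n_aberrant: int
    f_hat: float
    f_hat_by_class: dict
    consistency: float
    verdict: str  # clean | contaminated | indeterminate


def region_mean_level(
    track: MethylomeTrack, region: Region, min_cov: int = 5
) -> float:
    """Coverage-weighted mean level over a region's CpGs with depth >= min_cov.

    Returns NaN when no CpG in the region is usable.
    """
    sl = track.region_slice(region)
    nm = track.n_meth[sl]
    dp = track.depth[sl]
    ok = dp >= min_cov
    if not ok.any():
        return float("nan")
    return float(nm[ok].sum() / dp[ok].sum())


def region_mean_depth(track: MethylomeTrack, region: Region) -> float:
    sl = track.region_slice(region)
    dp = track.depth[sl]
    return float(dp.mean()) if dp.size else 0.0


def panel_from_regions(
    regions: Sequence[Region],
    sperm_refs: Sequence[MethylomeTrack],
    soma_refs: Sequence[MethylomeTrack],
    min_cov: int = 5,
    min_separation: float = 0.3,
) -> list[Marker]:
    """Build markers over known regions with e, s from reference group means.

    Regions whose observed |s - e| falls below ``min_separation`` are
    skipped (the admixture fit needs separable markers).
    """
    if len(sperm_refs) < 1 or len(soma_refs) < 1:
        raise ValueError("need reference samples for both tissues")
    out = []
    for r in regions:
        e = float(np.nanmean([region_mean_level(t, r, min_cov) for t in sperm_refs]))
        s = float(np.nanmean([region_mean_level(t, r, min_cov) for t in soma_refs]))
        if np.isnan(e) or np.isnan(s) or abs(s - e) < min_separation:
            continue
        klass = r.klass if r.klass in MARKER_CLASSES else (
            "germline_unmethylated" if e < s else "germline_methylated"
        )
        out.append(Marker(region=r, expected_sperm=e, expected_soma=s, klass=klass))
    return out


def build_soma_germ_panel(
    sperm_refs: Sequence[MethylomeTrack],
    soma_refs: Sequence[MethylomeTrack],
    genes: Sequence[GeneModel],
    germcell_gene_set: set,
    params: Optional[DMRParams] = None,
    promoter_window: int = 2000,
) -> tuple[list[Marker], list]:
    """Discover a soma-germline marker panel from reference methylomes.

    Pipeline: call DMRs between sperm and soma references under the
    stringent soma-germ thresholds, keep DMRs overlapping a promoter
    (TSS +/- promoter_window) of a germ-cell-specific gene, and turn
    each into a marker with e, s set to the observed group means.
    Returns (markers, the retained DMR records).
    """
    if len(sperm_refs) < 2 or len(soma_refs) < 2:
        raise ValueError("need at least 2 reference samples per tissue")
    params = params or soma_germ_params()
    dmrs = call_dmrs(sperm_refs, soma_refs, params)
    ann = annotate_promoters(dmrs, genes, window=promoter_window)
    if not germcell_gene_set:
        warnings.warn("empty germ-cell gene set: panel will be empty", stacklevel=2)
        return [], []
    subset, _, _ = intersect_gene_list(dmrs, ann, germcell_gene_set)
    markers = []
    for d in subset:
        klass = "germline_unmethylated" if d.mean_a < d.mean_b else "germline_methylated"
        markers.append(
            Marker(
                region=d.region,
                expected_sperm=d.mean_a,
                expected_soma=d.mean_b,
                klass=klass,
            )
        )
    return markers, subset


def _observed_levels(
    sample: MethylomeTrack, markers: Sequence[Marker], min_cov: int
) -> list[Optional[float]]:
    out = []
    for m in markers:
        v = region_mean_level(sample, m.region, min_cov=min_cov)
        out.append(None if np.isnan(v) else v)
    return out


def estimate_contamination(
    sample: MethylomeTrack,
    panel: Sequence[Marker],
    weight_cap: float = 30.0,
    min_cov: int = 5,
    min_markers: int = 5,
) -> tuple[float, dict, float]:
    """Weighted least-squares somatic-fraction estimate on the admixture model.

    f_hat = sum w_i (m_i - e_i)(s_i - e_i) / sum w_i (s_i - e_i)^2 with
    w_i = min(region mean depth, weight_cap), clipped to [0, 1]. Also
    returns per-marker-class estimates and their consistency (maximum
    pairwise absolute difference among classes with >= 3 usable
    markers; 0 if fewer than two such classes).
    """
    obs = _observed_levels(sample, panel, min_cov)
    rows = [
        (m, v, min(region_mean_depth(sample, m.region), weight_cap))
        for m, v in zip(panel, obs)
        if v is not None
    ]
    if len(rows) < min_markers:
        raise ValueError(f"only {len(rows)} usable markers; need >= {min_markers}")

    def wls(rs):
        num = sum(w * (v - m.expected_sperm) * m.separation for m, v, w in rs)
        den = sum(w * m.separation ** 2 for m, v, w in rs)
        return float(np.clip(num / den, 0.0, 1.0))

    f_hat = wls(rows)
    by_class: dict[str, float] = {}
    for klass in sorted({m.klass for m, _, _ in rows}):
        rs = [r for r in rows if r[0].klass == klass]
        by_class[klass] = wls(rs)
    big = [f for klass, f in by_class.items() if sum(r[0].klass == klass for r in rows) >= 3]
    consistency = float(max(big) - min(big)) if len(big) >= 2 else 0.0
    return f_hat, by_class, consistency


def classify_purity(
    sample: MethylomeTrack,
    panel: Sequence[Marker],
    core_markers: Optional[Sequence[Marker]] = None,
    tau: float = 0.06,
    min_aberrant: int = 2,
    min_cov: int = 5,
    noise_z: float = 4.5,
) -> PurityReport:
    """Flag a sample as clean / indeterminate / contaminated.

    A marker is aberrant when its observed level is displaced from the
    sperm expectation toward the somatic level by more than ``tau``
    (markers unmethylated in sperm: m > e + tau, the ">= 6% is aberrant"
    rule; methylated in sperm: m < e - tau). The displacement must also
    exceed ``noise_z`` binomial standard errors at the marker's observed
    read count: the flat tau rule comes from deep amplicon sequencing
    where sampling noise is negligible, and the guard is what keeps it
    valid for sparsely covered WGBS region means (for thousands of reads
    it is inactive). Aberrance is counted over ``core_markers`` if given
    (e.g. the MEST/H19/XIST/DDX4 screening loci), else over the whole
    panel. Verdict: contaminated when n_aberrant >= min_aberrant,
    indeterminate when exactly one marker is aberrant (a single
    displaced locus cannot distinguish contamination from a genuine
    epimutation), clean otherwise.
    """
    markers = list(core_markers) if core_markers is not None else list(panel)
    obs = _observed_levels(sample, markers, min_cov)
    records = []
    n_aberrant = 0
    for m, v in zip(markers, obs):
        aberrant = False
        if v is not None:
            sl = sample.region_slice(m.region)
            dp = sample.depth[sl]
            n_reads = max(int(dp[dp >= min_cov].sum()), 1)
            e0 = float(np.clip(m.expected_sperm, 0.01, 0.99))
            cut = max(tau, noise_z * np.sqrt(e0 * (1 - e0) / n_reads))
            displacement = (v - m.expected_sperm) * np.sign(m.separation)
            aberrant = bool(displacement > cut)
        n_aberrant += aberrant
        records.append((m, v, aberrant))
    try:
        f_hat, by_class, consistency = estimate_contamination(
            sample, panel, min_cov=min_cov
        )
    except ValueError:
        f_hat, by_class, consistency = float("nan"), {}, float("nan")
    if n_aberrant >= min_aberrant:
        verdict = "contaminated"
    elif n_aberrant == 1:
        verdict = "indeterminate"
    else:
        verdict = "clean"
    return PurityReport(
        sample_id=sample.sample_id,
        marker_levels=records,
        n_aberrant=n_aberrant,
        f_hat=f_hat,
        f_hat_by_class=by_class,
        consistency=consistency,
        verdict=verdict,
    )


def somatic_cell_fraction(f: float) -> float:
    """Convert a somatic DNA-mass fraction to a somatic cell fraction.

    Sperm are haploid, somatic cells diploid: a cell fraction c of
    somatic cells contributes DNA mass fraction f = 2c / (1 + c), hence
    c = f / (2 - f).
    """
    if not (0 <= f <= 1):
        raise ValueError("f must lie in [0, 1]")
    return f / (2.0 - f)


def conversion_rate(track: MethylomeTrack, spikein_contig: str) -> float:
    """Bisulfite conversion rate from an unmethylated spike-in contig.

    1 - (sum methylated / sum depth) over the spike-in CpGs; every
    methylated call there is an under-conversion event.
    """
    lo, hi = track.contig_block(spikein_contig)
    if hi <= lo:
        raise ValueError(f"spike-in contig {spikein_contig!r} not present in track")
    nm = track.n_meth[lo:hi].sum()
    dp = track.depth[lo:hi].sum()
    if dp == 0:
        raise ValueError("spike-in contig has no coverage")
    return float(1.0 - nm / dp)
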