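"""Synthetic data generator with full ground truth.

Emulates the statistical structure of a sperm-methylome study of
oligozoospermia:

* a sperm and a blood (somatic) reference methylome sharing a mostly
  methylated background (~0.8) but differing at 34 oocyte-methylated
  and 16 sperm-methylated imprinting control regions (50 ICRs total),
  ~200 germ-cell-specific gene promoters (sperm ~0.02, soma ~0.9), a
  handful of reverse-direction promoters (sperm ~0.95, soma ~0.1) and
  two XIST/DDX4-like loci (sperm ~0, soma ~0.85);
* WGBS count data: per-CpG depth ~ Poisson(lambda, default 15, matching
  13-16x sequencing), methylated counts binomial around the true level
  after bisulfite-conversion error (under-conversion 0.005,
  over-conversion 0.002), with a fully unmethylated 1% spike-in contig;
* linear somatic admixture: a sample with somatic DNA-mass fraction f
  has true level (1-f)*p_sperm + f*p_soma at every CpG;
* DBS amplicon reads over MEST/H19/XIST/DDX4-like loci as two-component
  epiallele mixtures with a maskable CpG-SNP and a genotype-linked
  methylation shift at one CpG (the H19 "CpG3" effect);
* a screening cohort of 40 normozoospermic and 93 oligozoospermic
  samples, a configurable subset of which is contaminated.

Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import amplicon_summary
from .io import AmpliconReadSet, GeneModel, MethylomeTrack, Region

MAIN_CONTIG = "chr1"
SPIKEIN_CONTIG = "lambda_spikein"

# (sperm level, soma level) per region class
CLASS_LEVELS = {
    "background": (0.80, 0.80),
    "oocyte_icr": (0.02, 0.50),
    "sperm_icr": (0.98, 0.50),
    "germcell_promoter": (0.02, 0.90),
    "reverse_promoter": (0.95, 0.10),
    "xist_ddx4": (0.00, 0.85),
    "orphan_diff": (0.02, 0.90),
    "decoy_promoter": (0.80, 0.80),
    "case_dmr": (0.30, 0.30),
}


@dataclass
class GenomeSpec:
    """Layout and level parameters of the synthetic genome."""

    n_background_cpgs: int = 20_000
    n_oocyte_icrs: int = 34
    n_sperm_icrs: int = 16
    n_germcell_promoters: int = 200
    n_reverse_promoters: int = 10
    n_decoy_promoters: int = 20
    n_orphan_diffs: int = 5
    n_xist_ddx4: int = 2
    n_case_dmrs: int = 0
    case_dmr_delta: float = 0.3
    spikein_cpgs: int = 1000
    region_cpg_range: tuple = (12, 18)
    region_spacing_mean: int = 150
    region_spacing_cap: int = 280  # keeps planted regions below the caller's gap limit
    background_spacing_mean: int = 500
    inter_region_gap: int = 2500
    region_jitter: float = 0.02
    cpg_jitter: float = 0.01
    background_jitter: float = 0.05
    levels: dict = field(default_factory=lambda: dict(CLASS_LEVELS))

    @property
    def n_icrs(self) -> int:
        return self.n_oocyte_icrs + self.n_sperm_icrs


@dataclass
class ReferenceSet:
    """True per-CpG methylomes plus annotations and ground truth."""

    contigs: np.ndarray
    pos: np.ndarray
    p_sperm: np.ndarray
    p_soma: np.ndarray
    case_shift: np.ndarray  # added to sperm profile for "case" samples
    regions: list  # Region, klass set per class above
    genes: list  # GeneModel
    germcell_gene_set: set
    spec: GenomeSpec
    seed: int

    def regions_of(self, *klasses: str) -> list[Region]:
        return [r for r in self.regions if r.klass in klasses]

    @property
    def marker_regions(self) -> list[Region]:
        """Regions usable as soma-germline purity markers."""
        return self.regions_of(
            "oocyte_icr", "sperm_icr", "germcell_promoter", "reverse_promoter", "xist_ddx4"
        )


def build_references(spec: GenomeSpec, seed: int) -> ReferenceSet:
    """Construct true sperm/soma methylation profiles and annotations."""
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, int]] = []
    for klass, n in (
        ("oocyte_icr", spec.n_oocyte_icrs),
        ("sperm_icr", spec.n_sperm_icrs),
        ("germcell_promoter", spec.n_germcell_promoters),
        ("reverse_promoter", spec.n_reverse_promoters),
        ("decoy_promoter", spec.n_decoy_promoters),
        ("orphan_diff", spec.n_orphan_diffs),
        ("xist_ddx4", spec.n_xist_ddx4),
        ("case_dmr", spec.n_case_dmrs),
    ):
        lo, hi = spec.region_cpg_range
        for i in range(n):
            blocks.append((klass, int(rng.integers(lo, hi + 1))))
    rng.shuffle(blocks)

    n_regions = len(blocks)
    # split background CpGs into n_regions + 1 chunks
    bg_chunks = np.full(n_regions + 1, spec.n_background_cpgs // (n_regions + 1))
    bg_chunks[: spec.n_background_cpgs % (n_regions + 1)] += 1

    contigs, pos, p_sperm, p_soma, case_shift = [], [], [], [], []
    regions: list[Region] = []
    genes: list[GeneModel] = []
    germ_set: set = set()
    counters: dict[str, int] = {}
    cursor = 1000

    def emit_background(n: int) -> int:
        nonlocal cursor
        e_bg, _ = spec.levels["background"]
        for _ in range(n):
            cursor += 2 + int(rng.geometric(1.0 / spec.background_spacing_mean))
            lvl = float(np.clip(e_bg + rng.normal(0, spec.background_jitter), 0, 1))
            contigs.append(MAIN_CONTIG)
            pos.append(cursor)
            p_sperm.append(lvl)
            p_soma.append(lvl)
            case_shift.append(0.0)
        return n

    def emit_region(klass: str, n_cpg: int) -> None:
        nonlocal cursor
        counters[klass] = counters.get(klass, 0) + 1
        label = f"{klass}_{counters[klass]}"
        e0, s0 = spec.levels[klass]
        e = float(np.clip(e0 + rng.normal(0, spec.region_jitter), 0, 1))
        s = float(np.clip(s0 + rng.normal(0, spec.region_jitter), 0, 1))
        cursor += spec.inter_region_gap
        start = cursor
        for _ in range(n_cpg):
            contigs.append(MAIN_CONTIG)
            pos.append(cursor)
            p_sperm.append(float(np.clip(e + rng.normal(0, spec.cpg_jitter), 0, 1)))
            p_soma.append(float(np.clip(s + rng.normal(0, spec.cpg_jitter), 0, 1)))
            case_shift.append(spec.case_dmr_delta if klass == "case_dmr" else 0.0)
            cursor += 2 + min(
                int(rng.geometric(1.0 / spec.region_spacing_mean)), spec.region_spacing_cap
            )
        end = pos[-1] + 1
        regions.append(Region(MAIN_CONTIG, start, end, label=label, klass=klass))
        if klass in ("germcell_promoter", "reverse_promoter", "decoy_promoter"):
            gene_id = f"gene_{label}"
            tss = (start + end) // 2
            genes.append(GeneModel(gene_id, MAIN_CONTIG, tss, "+", "protein_coding"))
            if klass in ("germcell_promoter", "reverse_promoter"):
                germ_set.add(gene_id)
        cursor += spec.inter_region_gap

    i_bg = 0
    emit_background(int(bg_chunks[i_bg]))
    for klass, n_cpg in blocks:
        i_bg += 1
        emit_region(klass, n_cpg)
        emit_background(int(bg_chunks[i_bg]))

    # unmethylated spike-in contig
    sp_pos = 100 + 50 * np.arange(spec.spikein_cpgs)
    contigs.extend([SPIKEIN_CONTIG] * spec.spikein_cpgs)
    pos.extend(sp_pos.tolist())
    p_sperm.extend([0.0] * spec.spikein_cpgs)
    p_soma.extend([0.0] * spec.spikein_cpgs)
    case_shift.extend([0.0] * spec.spikein_cpgs)

    return ReferenceSet(
        contigs=np.array(contigs, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        p_sperm=np.array(p_sperm),
        p_soma=np.array(p_soma),
        case_shift=np.array(case_shift),
        regions=regions,
        genes=genes,
        germcell_gene_set=germ_set,
        spec=spec,
        seed=seed,
    )


def simulate_wgbs_sample(
    refs: ReferenceSet,
    f: float,
    sample_id: str,
    coverage_lambda: float = 15.0,
    eps_under: float = 0.005,
    eps_over: float = 0.002,
    seed: int = 0,
    group: str = "control",
    tissue: str = "sperm",
) -> MethylomeTrack:
    """Draw binomial WGBS counts for one sample.

    ``tissue="sperm"`` mixes sperm and soma profiles at somatic fraction
    f; ``tissue="soma"`` ignores f and uses the somatic profile (for
    blood reference samples). ``group="case"`` applies the planted
    case-control shifts to the sperm profile. The spike-in contig is
    unmethylated regardless of f, so its counts reflect conversion error
    only.
    """
    if not (0 <= f <= 1):
        raise ValueError("f must lie in [0, 1]")
    if group not in ("control", "case"):
        raise ValueError("group must be 'control' or 'case'")
    rng = np.random.default_rng(seed)
    if tissue == "sperm":
        p_g = refs.p_sperm + (refs.case_shift if group == "case" else 0.0)
        p_true = (1 - f) * np.clip(p_g, 0, 1) + f * refs.p_soma
    elif tissue == "soma":
        p_true = refs.p_soma.copy()
    else:
        raise ValueError("tissue must be 'sperm' or 'soma'")
    p_true[refs.contigs == SPIKEIN_CONTIG] = 0.0
    p_obs = p_true * (1 - eps_over) + (1 - p_true) * eps_under
    depth = rng.poisson(coverage_lambda, size=p_obs.size)
    n_meth = rng.binomial(depth, p_obs)
    return MethylomeTrack(
        sample_id=sample_id,
        contigs=refs.contigs,
        pos=refs.pos,
        n_meth=n_meth,
        n_unmeth=depth - n_meth,
    )


# ---------------------------------------------------------------------------
# DBS amplicons
# ---------------------------------------------------------------------------


@dataclass
class AmpliconLocusSpec:
    """One DBS amplicon's epiallele model.

    ``sperm_meth_fraction``/``soma_meth_fraction`` are the probabilities
    that a germline/somatic DNA molecule carries the methylated
    epiallele. ``masked`` marks CpG-SNP columns (for loci with a
    genotype-destroyed CpG, the masked column is missing on G-allele
    reads); ``asm_cpg`` is the column whose methylated-epiallele success
    probability is reduced by delta_g on G-allele reads.
    """

    locus_id: str
    k: int
    sperm_meth_fraction: float
    soma_meth_fraction: float
    masked: frozenset = frozenset()
    snp_offset: Optional[int] = None
    asm_cpg: Optional[int] = None


# Screening loci: MEST-like behaves as an oocyte-methylated ICR (sperm
# unmethylated), H19-like as a sperm-methylated ICR; XIST/DDX4-like are
# fully unmethylated in sperm and mostly methylated in soma. The
# H19-like amplicon has 15 CpGs of which one (a CpG-SNP) is masked,
# leaving 14 analyzed; its "CpG3" (column 2) carries the G-allele
# methylation shift.
SCREEN_LOCI = {
    "mest": AmpliconLocusSpec("mest", k=10, sperm_meth_fraction=0.0, soma_meth_fraction=0.5),
    "h19": AmpliconLocusSpec(
        "h19",
        k=15,
        sperm_meth_fraction=1.0,
        soma_meth_fraction=0.5,
        masked=frozenset({3}),
        snp_offset=3,
        asm_cpg=2,
    ),
    "xist": AmpliconLocusSpec("xist", k=8, sperm_meth_fraction=0.0, soma_meth_fraction=0.85),
    "ddx4": AmpliconLocusSpec("ddx4", k=8, sperm_meth_fraction=0.0, soma_meth_fraction=0.85),
}


def simulate_amplicon_reads(
    locus: AmpliconLocusSpec,
    genotype: str = "TT",
    n_reads: int = 2000,
    meth_allele_fraction: Optional[float] = None,
    delta_g: float = 0.0,
    eps: float = 0.01,
    f: float = 0.0,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> AmpliconReadSet:
    """Draw per-read CpG states from a two-epiallele mixture.

    Each read is somatic with probability f, else germline; it carries
    the methylated epiallele with probability soma_meth_fraction
    (somatic) or meth_allele_fraction (germline, default the locus's
    sperm_meth_fraction). CpG states are Bernoulli(1 - eps) on the
    methylated and Bernoulli(eps) on the unmethylated epiallele. For
    heterozygotes, reads carry the T or G allele base ~50/50; on
    G-allele reads the asm_cpg's methylated-epiallele success
    probability is reduced by delta_g, and masked CpG-SNP columns are
    missing.
    """
    if genotype not in ("TT", "TG", "GG"):
        raise ValueError(f"invalid genotype {genotype!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    base = meth_allele_fraction if meth_allele_fraction is not None else locus.sperm_meth_fraction
    somatic = rng.random(n_reads) < f
    meth_frac = np.where(somatic, locus.soma_meth_fraction, base)
    is_meth = rng.random(n_reads) < meth_frac
    if genotype == "TG":
        allele = np.where(rng.random(n_reads) < 0.5, "T", "G").astype(object)
    else:
        allele = np.full(n_reads, genotype[0], dtype=object)
    success = np.where(is_meth[:, None], 1.0 - eps, eps) * np.ones((1, locus.k))
    if locus.asm_cpg is not None and delta_g != 0.0:
        g_meth = (allele == "G") & is_meth
        success[g_meth, locus.asm_cpg] = np.clip(1.0 - eps - delta_g, 0.0, 1.0)
    states = (rng.random((n_reads, locus.k)) < success).astype(np.int8)
    if locus.snp_offset is not None:
        for col in locus.masked:
            states[allele == "G", col] = -1
    return AmpliconReadSet(
        locus_id=locus.locus_id,
        states=states,
        allele=allele,
        read_ids=np.array([f"{locus.locus_id}_r{i}" for i in range(n_reads)], dtype=object),
        masked=locus.masked,
        snp_offset=locus.snp_offset,
    )


# ---------------------------------------------------------------------------
# screening cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Composition of a simulated DBS screening cohort.

    The default mirrors the screening arm of the emulated study: 40
    normozoospermic (f = 0) and 93 oligozoospermic samples of which 7
    are contaminated with somatic fraction f ~ U(0.1, 0.6). The
    ``study_design`` preset refines this into 6 heavily contaminated
    samples, 9 mildly contaminated ones (detectable by the XIST/DDX4
    6% rule but below the PC1 screen) and one H19-epimutation-like
    sample, reproducing the downstream 77-clean-NMO / 118-sample
    structure.
    """

    n_normo: int = 40
    n_oligo: int = 93
    n_contaminated: int = 7
    f_range: tuple = (0.1, 0.6)
    n_mild: int = 0
    mild_f_range: tuple = (0.09, 0.11)
    n_epimutation: int = 0
    epimutation_h19_shift: float = 0.25
    reads_per_locus: int = 2000
    eps: float = 0.01
    delta_g: float = 0.25
    genotype_freqs: tuple = (0.34, 0.41, 0.25)  # TT, TG, GG
    sample_jitter: float = 0.008

    def __post_init__(self) -> None:
        if self.n_contaminated + self.n_mild + self.n_epimutation > self.n_oligo:
            raise ValueError("more special samples than oligozoospermic samples")


def study_design() -> CohortDesign:
    return CohortDesign(
        n_contaminated=6,
        f_range=(0.2, 0.6),
        n_mild=9,
        mild_f_range=(0.09, 0.11),
        n_epimutation=1,
    )


def simulate_screen_cohort(
    design: CohortDesign, seed: int
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Simulate a DBS screening cohort.

    Returns (records, readsets, truth): a cohort table with per-sample
    MEST/H19/XIST/DDX4 DBS means and genotype, the underlying amplicon
    read sets as ``readsets[sample_id][locus]``, and a truth table with
    each sample's somatic fraction and true class.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"VN{i + 1:02d}" for i in range(design.n_normo)] + [
        f"SO{i + 1:02d}" for i in range(design.n_oligo)
    ]
    diagnosis = ["normo"] * design.n_normo + ["oligo"] * design.n_oligo
    genotypes = rng.choice(["TT", "TG", "GG"], size=len(sample_ids), p=design.genotype_freqs)

    f = np.zeros(len(sample_ids))
    true_class = np.array(["clean"] * len(sample_ids), dtype=object)
    oligo_idx = np.arange(design.n_normo, len(sample_ids))
    special = rng.choice(
        oligo_idx,
        size=design.n_contaminated + design.n_mild + design.n_epimutation,
        replace=False,
    )
    heavy = special[: design.n_contaminated]
    mild = special[design.n_contaminated : design.n_contaminated + design.n_mild]
    epi = special[design.n_contaminated + design.n_mild :]
    f[heavy] = rng.uniform(*design.f_range, size=heavy.size)
    f[mild] = rng.uniform(*design.mild_f_range, size=mild.size)
    true_class[heavy] = "contaminated"
    true_class[mild] = "contaminated_mild"
    true_class[epi] = "epimutation"

    rows = []
    readsets: dict[str, dict[str, AmpliconReadSet]] = {}
    for i, sid in enumerate(sample_ids):
        per_locus = {}
        means = {}
        for name, locus in SCREEN_LOCI.items():
            maf = locus.sperm_meth_fraction
            if name == "h19" and true_class[i] == "epimutation":
                maf = 1.0 - design.epimutation_h19_shift
            maf = float(np.clip(maf + rng.normal(0, design.sample_jitter), 0, 1))
            rs = simulate_amplicon_reads(
                locus,
                genotype=str(genotypes[i]),
                n_reads=design.reads_per_locus,
                meth_allele_fraction=maf,
                delta_g=design.delta_g if name == "h19" else 0.0,
                eps=design.eps,
                f=float(f[i]),
                rng=rng,
            )
            per_locus[name] = rs
            means[name] = amplicon_summary(rs)[1]
        readsets[sid] = per_locus
        rows.append(
            {
                "sample_id": sid,
                "diagnosis": diagnosis[i],
                "mean_mest": means["mest"],
                "mean_h19": means["h19"],
                "mean_xist": means["xist"],
                "mean_ddx4": means["ddx4"],
                "genotype": str(genotypes[i]),
            }
        )
    records = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "diagnosis": diagnosis,
            "f": f,
            "genotype": genotypes,
            "true_class": true_class,
        }
    )
    return records, readsets, truth


def xist_ddx4_clean(records: pd.DataFrame, tau: float = 0.06) -> pd.Series:
    """True where both XIST-like and DDX4-like DBS means are below tau.

    The "expected methylation < 6%" purity rule for loci fully
    unmethylated in normal sperm.
    """
    return (records["mean_xist"] < tau) & (records["mean_ddx4"] < tau)
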