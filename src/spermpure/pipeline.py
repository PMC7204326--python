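"""End-to-end orchestration of the purity/DMR/screening analysis.

The full pipeline mirrors the study's flow:

1. build (or load) a soma-germline marker panel from reference
   methylomes;
2. score every sperm sample's purity and exclude contaminated samples
   (they are excluded, not corrected — an optional corrected-levels
   mode (m - f*s)/(1 - f) exists but is off by default);
3. call case-control DMRs on the clean samples, apply the
   reference-group range filter (< 0.3) and rank survivors for
   validation;
4. if DBS inputs are present, run the PCA screen and the
   allele-specific methylation tests.

Every threshold decision is logged and echoed into a run manifest so a
run is reproducible from its report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmrmod
from . import io as iomod
from . import simulate as simmod
from .amplicon import allele_cpg_test, pca_screen_classify, split_reads_by_allele
from .purity import build_soma_germ_panel, classify_purity
from .simulate import CohortDesign, GenomeSpec

logger = logging.getLogger("spermpure")


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline, YAML-loadable.

    Defaults reproduce the stated thresholds: soma-germ DMRs at
    10 CpGs / 0.80 / coverage 5 / q 0.05, case-control DMRs at
    5 / 0.30 / 5 / 0.05, reference range < 0.3, purity tau 0.06 with
    >= 2 aberrant loci, screening at the 95th PC1 percentile.
    """

    seed: int = 1
    genome: dict = field(default_factory=dict)
    n_reference_per_tissue: int = 2
    reference_coverage: float = 30.0  # pooled reference datasets run deeper
    n_nc: int = 5
    n_amo: int = 5
    n_nmo: int = 6
    amo_f_range: tuple = (0.1, 0.6)
    coverage_lambda: float = 15.0
    eps_under: float = 0.005
    eps_over: float = 0.002
    dmr_soma_germ: dict = field(default_factory=dict)
    dmr_case_control: dict = field(default_factory=dict)
    purity_tau: float = 0.06
    purity_min_aberrant: int = 2
    purity_weight_cap: float = 30.0
    min_cov: int = 5
    range_filter_max: float = 0.3
    validation_top_k: int = 10
    screen_percentile: float = 95.0
    screen_scale: bool = False
    screen_design: dict = field(default_factory=dict)
    run_screen: bool = True
    correct_levels: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "amo_f_range" in raw:
            raw["amo_f_range"] = tuple(raw["amo_f_range"])
        return cls(**raw)

    def soma_germ_params(self) -> dmrmod.DMRParams:
        return dataclasses.replace(dmrmod.soma_germ_params(), **self.dmr_soma_germ)

    def case_control_params(self) -> dmrmod.DMRParams:
        return dataclasses.replace(dmrmod.case_control_params(), **self.dmr_case_control)


def _simulate_wgbs_cohort(refs, config: PipelineConfig, rng: np.random.Generator):
    """Reference tracks plus the NC/AMO/NMO WGBS samples."""

    def draw(sample_id, f, tissue="sperm", coverage=None):
        return simmod.simulate_wgbs_sample(
            refs,
            f=f,
            sample_id=sample_id,
            coverage_lambda=coverage or config.coverage_lambda,
            eps_under=config.eps_under,
            eps_over=config.eps_over,
            seed=int(rng.integers(2**31)),
            tissue=tissue,
        )

    sperm_refs = [
        draw(f"SP{i + 1}", 0.0, coverage=config.reference_coverage)
        for i in range(config.n_reference_per_tissue)
    ]
    soma_refs = [
        draw(f"BL{i + 1}", 0.0, tissue="soma", coverage=config.reference_coverage)
        for i in range(config.n_reference_per_tissue)
    ]
    samples = {}
    truth = {}
    for i in range(config.n_nc):
        sid = f"NC{i + 1}"
        samples[sid] = draw(sid, 0.0)
        truth[sid] = {"f": 0.0, "group": "NC"}
    for i in range(config.n_amo):
        sid = f"AMO{i + 1}"
        fv = float(rng.uniform(*config.amo_f_range))
        samples[sid] = draw(sid, fv)
        truth[sid] = {"f": fv, "group": "AMO"}
    for i in range(config.n_nmo):
        sid = f"NMO{i + 1}"
        samples[sid] = draw(sid, 0.0)
        truth[sid] = {"f": 0.0, "group": "NMO"}
    return sperm_refs, soma_refs, samples, truth


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages on a simulated study; returns the report bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    logger.info("stage 1: building references and marker panel")
    spec = GenomeSpec(**config.genome)
    refs = simmod.build_references(spec, seed=int(rng.integers(2**31)))
    sperm_refs, soma_refs, samples, truth = _simulate_wgbs_cohort(refs, config, rng)
    sg_params = config.soma_germ_params()
    panel, panel_dmrs = build_soma_germ_panel(
        sperm_refs, soma_refs, refs.genes, refs.germcell_gene_set, params=sg_params
    )
    iomod.write_marker_panel_tsv(panel, outdir / "panel.tsv")
    iomod.write_dmrs_bed(panel_dmrs, outdir / "soma_germ_dmrs.bed")
    report["stages"]["panel"] = {
        "params": dataclasses.asdict(sg_params),
        "n_markers": len(panel),
    }
    logger.info("panel: %d markers under %s", len(panel), sg_params)

    logger.info("stage 2: purity classification of %d samples", len(samples))
    purity_rows = []
    clean, excluded = [], []
    for sid, track in samples.items():
        rep = classify_purity(
            track,
            panel,
            tau=config.purity_tau,
            min_aberrant=config.purity_min_aberrant,
            min_cov=config.min_cov,
        )
        purity_rows.append(
            {
                "sample_id": sid,
                "group": truth[sid]["group"],
                "true_f": truth[sid]["f"],
                "n_aberrant": rep.n_aberrant,
                "f_hat": rep.f_hat,
                "consistency": rep.consistency,
                "verdict": rep.verdict,
            }
        )
        (clean if rep.verdict == "clean" else excluded).append(sid)
        if rep.verdict != "clean":
            logger.info("excluding %s (%s, f_hat=%.3f)", sid, rep.verdict, rep.f_hat)
    purity_df = pd.DataFrame(purity_rows)
    purity_df.to_csv(outdir / "purity.tsv", sep="\t", index=False)
    report["stages"]["purity"] = {
        "tau": config.purity_tau,
        "min_aberrant": config.purity_min_aberrant,
        "excluded": excluded,
        "n_clean": len(clean),
    }

    logger.info("stage 3: case-control DMRs on clean samples")
    nc_tracks = [samples[s] for s in clean if truth[s]["group"] == "NC"]
    nmo_tracks = [samples[s] for s in clean if truth[s]["group"] == "NMO"]
    cc_params = config.case_control_params()
    stage3: dict = {"params": dataclasses.asdict(cc_params)}
    if nc_tracks and nmo_tracks:
        dmrs = dmrmod.call_dmrs(nc_tracks, nmo_tracks, cc_params)
        kept = dmrmod.range_filter(
            dmrs, nc_tracks, max_range=config.range_filter_max, min_cov=config.min_cov
        )
        iomod.write_dmrs_bed(dmrs, outdir / "case_control_dmrs.bed")
        iomod.write_dmrs_bed(kept, outdir / "case_control_dmrs_rangefilt.bed")
        ref_means = dmrmod.region_sample_means(kept, nc_tracks, min_cov=config.min_cov)
        test_means = dmrmod.region_sample_means(kept, nmo_tracks, min_cov=config.min_cov)
        ranked = dmrmod.rank_for_validation(
            kept, ref_means, test_means, top_k=config.validation_top_k
        )
        stage3.update(
            n_dmrs=len(dmrs),
            n_after_range_filter=len(kept),
            range_filter_max=config.range_filter_max,
            validation_ranking=[
                {
                    "region": f"{d.region.contig}:{d.region.start}-{d.region.end}",
                    "out_of_range_count": c,
                    "diff": d.diff,
                }
                for d, c in ranked
            ],
        )
        logger.info("case-control: %d DMRs, %d after range filter", len(dmrs), len(kept))
    else:
        stage3["skipped"] = "no clean samples in one of the groups"
    report["stages"]["case_control"] = stage3

    if config.run_screen:
        logger.info("stage 4: DBS screening and ASM")
        design = CohortDesign(**config.screen_design)
        records, readsets, screen_truth = simmod.simulate_screen_cohort(
            design, seed=int(rng.integers(2**31))
        )
        screen = pca_screen_classify(
            records, percentile=config.screen_percentile, scale=config.screen_scale
        )
        screen.records.to_csv(outdir / "screen.tsv", sep="\t", index=False)
        clean_dbs = simmod.xist_ddx4_clean(screen.records, tau=config.purity_tau)
        # pooled allele-specific test at the H19-like CpG3 over TG samples
        tg = screen.records["genotype"] == "TG"
        asm = None
        if tg.any():
            h19 = [readsets[s]["h19"] for s in screen.records.loc[tg, "sample_id"]]
            merged = iomod.AmpliconReadSet(
                locus_id="h19",
                states=np.vstack([r.states for r in h19]),
                allele=np.concatenate([r.allele for r in h19]),
                read_ids=np.concatenate([r.read_ids for r in h19]),
                masked=h19[0].masked,
                snp_offset=h19[0].snp_offset,
            )
            t_reads, g_reads, _ = split_reads_by_allele(merged, ("T", "G"))
            res = allele_cpg_test(t_reads, g_reads, simmod.SCREEN_LOCI["h19"].asm_cpg)
            asm = {"p": res.p_value, "n_t_reads": t_reads.n_reads, "n_g_reads": g_reads.n_reads}
        report["stages"]["screen"] = {
            "percentile": config.screen_percentile,
            "threshold": screen.threshold,
            "n_nc": screen.n_nc,
            "n_amo": screen.n_amo,
            "n_nmo": screen.n_nmo,
            "n_xist_ddx4_clean": int(clean_dbs.sum()),
            "asm_cpg3_t_vs_g": asm,
        }
        logger.info(
            "screen: %d NC / %d AMO / %d NMO, PC1 threshold %.4f",
            screen.n_nc, screen.n_amo, screen.n_nmo, screen.threshold,
        )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    logger.info("wrote %s", outdir / "manifest.json")
    return report


def correct_levels(m: float, f: float, s: float) -> float:
    """Back-correct an observed level for somatic admixture: (m - f*s)/(1 - f)."""
    if not (0 <= f < 1):
        raise ValueError("f must lie in [0, 1)")
    return float(np.clip((m - f * s) / (1.0 - f), 0.0, 1.0))
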