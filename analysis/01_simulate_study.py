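#!/usr/bin/env python
"""Materialize the synthetic study: genome, references, cohorts.

Writes the reference methylomes, annotations and WGBS samples as
bedGraph/BED/TSV under scratch/data/ (bulky, regenerable) and a compact
description of what was simulated under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from spermpure import io as iomod
from spermpure.simulate import (
    CohortDesign,
    GenomeSpec,
    build_references,
    simulate_screen_cohort,
    simulate_wgbs_sample,
    study_design,
)

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    data = ROOT / "scratch" / "data"
    results = ROOT / "results"
    data.mkdir(parents=True, exist_ok=True)
    results.mkdir(exist_ok=True)

    spec = GenomeSpec(n_background_cpgs=20_000)
    refs = build_references(spec, seed=int(rng.integers(2**31)))
    iomod.write_regions_bed(refs.regions, data / "regions.bed")
    iomod.write_gene_models_tsv(refs.genes, data / "genes.tsv")
    (data / "germcell_genes.txt").write_text(
        "\n".join(sorted(refs.germcell_gene_set)) + "\n"
    )

    # pooled reference methylomes (2 sperm, 2 blood) and the WGBS cohort:
    # 5 normal controls, 5 contaminated samples, 6 clean oligozoospermic
    manifest = {"seed": args.seed, "n_cpgs": int(refs.pos.size),
                "n_regions": len(refs.regions), "samples": {}}
    for i in range(2):
        for tissue, tag in (("sperm", "sperm_ref"), ("soma", "blood_ref")):
            t = simulate_wgbs_sample(refs, 0.0, f"{tag}{i + 1}", coverage_lambda=30,
                                     seed=int(rng.integers(2**31)), tissue=tissue)
            iomod.write_methylation_bedgraph(t, data / f"{tag}{i + 1}.bedGraph")
    for group, n, f_range in (("NC", 5, None), ("AMO", 5, (0.1, 0.6)), ("NMO", 6, None)):
        for i in range(n):
            f = float(rng.uniform(*f_range)) if f_range else 0.0
            sid = f"{group}{i + 1}"
            t = simulate_wgbs_sample(refs, f, sid, seed=int(rng.integers(2**31)))
            iomod.write_methylation_bedgraph(t, data / f"{sid}.bedGraph")
            manifest["samples"][sid] = {"group": group, "true_f": f}

    # DBS screening cohort (133 samples, study-emulation design)
    records, _, truth = simulate_screen_cohort(study_design(), seed=int(rng.integers(2**31)))
    records.to_csv(data / "screen_cohort.tsv", sep="\t", index=False)
    truth.to_csv(results / "01_screen_truth.tsv", sep="\t", index=False)
    with open(results / "01_simulation_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    print(f"genome: {refs.pos.size} CpGs, {len(refs.regions)} regions")
    print(f"WGBS cohort: {len(manifest['samples'])} samples -> {data}")
    print(f"DBS cohort: {len(records)} samples "
          f"({(truth['f'] > 0).sum()} contaminated by design)")


if __name__ == "__main__":
    main()
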