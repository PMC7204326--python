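import numpy as np
import pytest

from spermpure.io import MethylomeTrack
from spermpure.simulate import (
    CLASS_LEVELS,
    GenomeSpec,
    build_references,
    simulate_wgbs_sample,
)


def make_track(counts, sample_id="s", contig="chr1", positions=None, spacing=10):
    """Build a small MethylomeTrack from (n_meth, n_unmeth) pairs."""
    counts = list(counts)
    if positions is None:
        positions = [100 + spacing * i for i in range(len(counts))]
    return MethylomeTrack(
        sample_id=sample_id,
        contigs=np.array([contig] * len(counts), dtype=object),
        pos=np.array(positions, dtype=np.int64),
        n_meth=np.array([c[0] for c in counts], dtype=np.int64),
        n_unmeth=np.array([c[1] for c in counts], dtype=np.int64),
    )


@pytest.fixture(scope="session")
def small_refs():
    """A compact synthetic genome shared across tests."""
    spec = GenomeSpec(
        n_background_cpgs=4000,
        n_oocyte_icrs=8,
        n_sperm_icrs=4,
        n_germcell_promoters=40,
        n_reverse_promoters=4,
        n_decoy_promoters=6,
        n_orphan_diffs=3,
        spikein_cpgs=300,
    )
    return build_references(spec, seed=42)


@pytest.fixture(scope="session")
def small_ref_tracks(small_refs):
    """Two sperm and two soma reference samples at pooled-reference depth."""
    sperm = [
        simulate_wgbs_sample(small_refs, 0.0, f"SP{i}", coverage_lambda=30, seed=300 + i)
        for i in range(2)
    ]
    soma = [
        simulate_wgbs_sample(
            small_refs, 0.0, f"BL{i}", coverage_lambda=30, seed=400 + i, tissue="soma"
        )
        for i in range(2)
    ]
    return sperm, soma


def recovery_genome_spec(n_background=50_000, n_planted=50):
    """Genome for caller-recovery experiments: planted regions whose
    observed-scale sperm-soma difference is ~0.85, guaranteed above the
    0.80 threshold (no between-region jitter)."""
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


def panel_genome_spec(n_markers=500, n_background=2000):
    """Genome whose marker-class regions number exactly n_markers."""
    n_prom = n_markers - 34 - 16 - 10 - 2
    return GenomeSpec(
        n_background_cpgs=n_background,
        n_germcell_promoters=n_prom,
        n_reverse_promoters=10,
        n_decoy_promoters=0,
        n_orphan_diffs=0,
        spikein_cpgs=300,
    )
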