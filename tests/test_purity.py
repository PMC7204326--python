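"""Tests for contamination detection, admixture estimation and conversion rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermpure.io import Region
from spermpure.purity import (
    Marker,
    build_soma_germ_panel,
    classify_purity,
    conversion_rate,
    estimate_contamination,
    panel_from_regions,
    region_mean_level,
    somatic_cell_fraction,
)
from spermpure.simulate import SPIKEIN_CONTIG, simulate_wgbs_sample

from .conftest import make_track


class TestRegionMean:
    def test_fully_methylated(self):
        t = make_track([(10, 0), (10, 0)])
        assert region_mean_level(t, Region("chr1", 50, 200)) == 1.0

    def test_coverage_weighted(self):
        t = make_track([(5, 5), (0, 10)])
        assert region_mean_level(t, Region("chr1", 50, 200)) == pytest.approx(0.25)

    def test_all_below_min_cov_missing(self):
        t = make_track([(2, 1), (1, 2)])
        assert np.isnan(region_mean_level(t, Region("chr1", 50, 200), min_cov=5))


def _panel_and_track(levels, e=0.0, s=0.85, depth=100, klass="germline_unmethylated"):
    """Markers at consecutive single-CpG regions; track observes `levels`."""
    markers, counts, positions = [], [], []
    for i, m in enumerate(levels):
        pos = 100 + 50 * i
        positions.append(pos)
        markers.append(
            Marker(Region("chr1", pos, pos + 1, label=f"m{i}"), e, s, klass)
        )
        counts.append((round(m * depth), depth - round(m * depth)))
    return markers, make_track(counts, positions=positions)


class TestClassification:
    def test_all_expected_is_clean(self):
        markers, track = _panel_and_track([0.0] * 6)
        rep = classify_purity(track, markers)
        assert rep.verdict == "clean" and rep.n_aberrant == 0

    def test_two_displaced_loci_contaminated(self):
        # XIST-like at 0.20 and DDX4-like at 0.15 with e = 0: both > 6%
        markers, track = _panel_and_track([0.20, 0.15, 0.0, 0.0, 0.0, 0.0])
        rep = classify_purity(track, markers)
        assert rep.n_aberrant == 2 and rep.verdict == "contaminated"

    def test_single_aberrant_locus_is_indeterminate(self):
        markers, track = _panel_and_track([0.20, 0.0, 0.0, 0.0, 0.0, 0.0])
        rep = classify_purity(track, markers)
        assert rep.verdict == "indeterminate"

    def test_methylated_marker_aberrant_downward(self):
        # sperm-methylated marker displaced toward soma (0.5): m < e - tau
        markers, track = _panel_and_track(
            [0.80, 0.80, 0.97, 0.97, 0.97], e=0.97, s=0.5, klass="germline_methylated"
        )
        rep = classify_purity(track, markers)
        assert rep.n_aberrant == 2 and rep.verdict == "contaminated"

    def test_core_marker_restriction(self):
        markers, track = _panel_and_track([0.20, 0.15, 0.30, 0.0, 0.0, 0.0])
        rep = classify_purity(track, markers, core_markers=markers[3:])
        assert rep.n_aberrant == 0 and rep.verdict == "clean"


class TestEstimator:
    def test_exact_at_endpoints_and_linear_mixtures(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(0, 0.2, size=20)
        s = rng.uniform(0.5, 1.0, size=20)
        for f in [0.0, 0.25, 1.0]:
            m = (1 - f) * e + f * s
            markers, track = zip(
                *[
                    (
                        Marker(Region("chr1", 100 + 50 * i, 101 + 50 * i), e[i], s[i],
                               "germline_unmethylated"),
                        (round(m[i] * 1000), 1000 - round(m[i] * 1000)),
                    )
                    for i in range(20)
                ]
            )
            track = make_track(list(track), positions=[100 + 50 * i for i in range(20)])
            f_hat, by_class, cons = estimate_contamination(track, list(markers))
            assert f_hat == pytest.approx(f, abs=2e-3)  # count rounding only
            assert cons <= 2e-3 + 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        f=st.floats(min_value=0, max_value=1),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_exact_on_noise_free_mixtures_property(self, f, seed):
        """WLS recovers f exactly when levels follow the model exactly."""
        rng = np.random.default_rng(seed)
        n = 10
        e = rng.uniform(0, 0.3, size=n)
        s = np.clip(e + np.where(rng.random(n) < 0.5, 1, -1) * rng.uniform(0.4, 0.7, n), 0, 1)
        keep = np.abs(s - e) >= 0.3
        e, s = e[keep], s[keep]
        if len(e) < 5:
            return
        markers = [
            Marker(Region("chr1", 100 + 50 * i, 101 + 50 * i), e[i], s[i], "oocyte_icr")
            for i in range(len(e))
        ]
        m = (1 - f) * e + f * s
        big = 10_000  # large counts so rounding is negligible
        track = make_track(
            [(round(v * big), big - round(v * big)) for v in m],
            positions=[100 + 50 * i for i in range(len(e))],
        )
        f_hat, _, _ = estimate_contamination(track, markers)
        assert f_hat == pytest.approx(f, abs=5e-4)

    def test_too_few_markers_rejected(self):
        markers, track = _panel_and_track([0.0, 0.0])
        with pytest.raises(ValueError, match="usable markers"):
            estimate_contamination(track, markers)

    def test_recovery_from_simulated_sample(self, small_refs, small_ref_tracks):
        sperm, soma = small_ref_tracks
        panel = panel_from_regions(small_refs.marker_regions, sperm, soma)
        sample = simulate_wgbs_sample(small_refs, 0.10, "c10", seed=77)
        f_hat, _, cons = estimate_contamination(sample, panel)
        assert abs(f_hat - 0.10) <= 0.02
        assert cons < 0.05  # aberration degree consistent across marker classes


class TestPanelBuild:
    def test_panel_covers_planted_promoters(self, small_refs, small_ref_tracks):
        sperm, soma = small_ref_tracks
        panel, dmrs = build_soma_germ_panel(
            sperm, soma, small_refs.genes, small_refs.germcell_gene_set
        )
        n_expected = len(small_refs.regions_of("germcell_promoter", "reverse_promoter"))
        assert len(panel) >= 0.9 * n_expected
        assert all(abs(m.separation) >= 0.8 for m in panel)
        # both directions present: soma-hypermethylated and sperm-hypermethylated
        klasses = {m.klass for m in panel}
        assert klasses == {"germline_unmethylated", "germline_methylated"}

    def test_panel_excludes_non_promoter_differences(self, small_refs, small_ref_tracks):
        sperm, soma = small_ref_tracks
        panel, _ = build_soma_germ_panel(
            sperm, soma, small_refs.genes, small_refs.germcell_gene_set
        )
        orphans = small_refs.regions_of("orphan_diff")
        for m in panel:
            for o in orphans:
                assert not (m.region.start < o.end and o.start < m.region.end)

    def test_empty_gene_set_warns_and_returns_empty(self, small_ref_tracks, small_refs):
        sperm, soma = small_ref_tracks
        with pytest.warns(UserWarning, match="empty"):
            panel, _ = build_soma_germ_panel(sperm, soma, small_refs.genes, set())
        assert panel == []


class TestConversionRate:
    def test_fully_converted(self):
        t = make_track([(0, 10)] * 5, contig="lambda")
        assert conversion_rate(t, "lambda") == 1.0

    def test_partial_conversion_arithmetic(self):
        t = make_track([(10, 990)], contig="lambda")
        assert conversion_rate(t, "lambda") == pytest.approx(0.99)

    def test_missing_contig_rejected(self):
        t = make_track([(0, 10)])
        with pytest.raises(ValueError, match="not present"):
            conversion_rate(t, "lambda")

    def test_simulated_underconversion(self, small_refs):
        sample = simulate_wgbs_sample(small_refs, 0.0, "s", eps_under=0.005, seed=5)
        rate = conversion_rate(sample, SPIKEIN_CONTIG)
        n_obs = int(sample.depth[sample.contigs == SPIKEIN_CONTIG].sum())
        se = np.sqrt(0.005 * 0.995 / n_obs)
        assert abs(rate - 0.995) <= max(3 * se, 0.003)


def test_somatic_cell_fraction_convention():
    assert somatic_cell_fraction(0.0) == 0.0
    assert somatic_cell_fraction(1.0) == 1.0
    # a sample that is half somatic DNA by mass is one-third somatic cells
    assert somatic_cell_fraction(0.5) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        somatic_cell_fraction(1.5)
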