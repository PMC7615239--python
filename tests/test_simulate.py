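"""Synthetic-data generator: determinism, planted structure, sampling laws."""

import filecmp

import numpy as np
import pytest

from chipmeta import (
    SimulationConfig,
    filter_by_q,
    simulate_annotation,
    simulate_peaks,
    write_fixture,
)
from chipmeta.annotation import tss_tts
from chipmeta.simulate import gaussian_bump_track

SMALL = SimulationConfig(
    seed=11,
    n_genes=80,
    chrom_length=400_000,
    n_sites={"NV": 20, "6WT0": 30},
    factors=("VEL1", "VIN3"),
)


class TestConfig:
    def test_positional_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="p_tss"):
            SimulationConfig(p_tss=0.5, p_tts=0.2, p_intergenic=0.2)

    def test_probabilities_bounded(self):
        with pytest.raises(ValueError):
            SimulationConfig(reproducibility=1.5)

    def test_impossible_density_raises_helpful_error(self):
        cfg = SimulationConfig(n_genes=500, chrom_length=100_000, n_chroms=1)
        with pytest.raises(ValueError, match="reduce n_genes"):
            simulate_annotation(cfg)


class TestAnnotation:
    def test_same_seed_same_gff_bytes(self, tmp_path):
        d1 = write_fixture(SMALL, tmp_path / "a", coverage=False)
        d2 = write_fixture(SMALL, tmp_path / "b", coverage=False)
        assert (d1 / "genes.gff3").read_bytes() == (d2 / "genes.gff3").read_bytes()

    def test_min_spacing_respected(self):
        asm, genes = simulate_annotation(SMALL)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.region.chrom, []).append(g.region)
        for regions in by_chrom.values():
            regions.sort()
            for a, b in zip(regions, regions[1:]):
                assert b.start - a.end >= SMALL.gene_spacing

    def test_gene_lengths_within_configured_range(self):
        cfg = SMALL.replace(n_genes=200, chrom_length=1_500_000)
        _, genes = simulate_annotation(cfg)
        lo, hi = cfg.gene_length
        lens = [len(g.region) for g in genes]
        assert min(lens) >= lo and max(lens) <= hi


class TestPeaks:
    def test_full_sharing_full_reproducibility_sites_coincide(self):
        cfg = SMALL.replace(sharing=1.0, reproducibility=1.0, copy_jitter_sigma=0.0)
        asm, genes = simulate_annotation(cfg)
        _, truth = simulate_peaks(cfg, asm, genes)
        for cond in cfg.conditions:
            ref = truth[(truth.factor == "VEL1") & (truth.condition == cond)]
            dep = truth[(truth.factor == "VIN3") & (truth.condition == cond)]
            assert sorted(dep.summit) == sorted(ref.summit)
            assert dep.shared_with_reference.all()

    def test_zero_reproducibility_empty_replicates(self):
        cfg = SMALL.replace(reproducibility=0.0)
        asm, genes = simulate_annotation(cfg)
        peaksets, _ = simulate_peaks(cfg, asm, genes)
        assert all(len(ps) == 0 for reps in peaksets.values() for ps in reps)

    def test_weak_q_fraction_controls_filter_loss(self):
        """Post-filter count ~ (1-w) * total within 3 binomial SE."""
        cfg = SMALL.replace(
            n_sites={"NV": 400, "6WT0": 400},
            n_genes=900,
            chrom_length=3_000_000,
            factors=("VEL1",),
            reproducibility=1.0,
            weak_q_fraction=0.3,
        )
        asm, genes = simulate_annotation(cfg)
        peaksets, _ = simulate_peaks(cfg, asm, genes)
        total = kept = 0
        for reps in peaksets.values():
            for ps in reps:
                total += len(ps)
                kept += len(filter_by_q(ps))
        frac = kept / total
        se = np.sqrt(0.3 * 0.7 / total)
        assert abs(frac - 0.7) <= 3 * se

    def test_genic_sites_anchor_near_their_gene(self):
        asm, genes = simulate_annotation(SMALL)
        _, truth = simulate_peaks(SMALL, asm, genes)
        by_id = {g.gene_id: g for g in genes}
        genic = truth[truth.gene_id != "NA"]
        for row in genic.itertuples():
            g = by_id[row.gene_id]
            tss, tts = tss_tts(g)
            anchor = tss if row.mode == "tss" else tts
            assert abs(row.summit - anchor) <= SMALL.tts_offset + 6 * SMALL.jitter_sigma

    def test_intergenic_sites_clear_of_assignment_windows(self):
        asm, genes = simulate_annotation(SMALL)
        _, truth = simulate_peaks(SMALL, asm, genes)
        inter = truth[truth["mode"] == "intergenic"]
        for row in inter.itertuples():
            for g in genes:
                if g.region.chrom != row.chrom:
                    continue
                d = max(g.region.start - row.summit, row.summit - (g.region.end - 1), 0)
                assert d > 1000


class TestCoverage:
    def test_zero_amplitude_is_flat_background(self, asm10k):
        t = gaussian_bump_track(asm10k, [("chr1", 5000)], 1.0, 0.0, 200.0, 10)
        x = np.arange(0, 10_000, 37)
        assert np.allclose(t.value_at("chr1", x), 1.0)

    def test_track_maximum_at_summit(self, asm10k):
        t = gaussian_bump_track(asm10k, [("chr1", 5000)], 1.0, 8.0, 200.0, 10)
        x = np.arange(10_000)
        vals = t.value_at("chr1", x)
        assert abs(int(np.argmax(vals)) - 5000) <= 10

    def test_bump_integral_matches_gaussian_mass(self, asm10k):
        amp, sigma = 8.0, 200.0
        t = gaussian_bump_track(asm10k, [("chr1", 5000)], 0.0, amp, sigma, 5)
        integral = t.total_signal()
        expected = amp * sigma * np.sqrt(2 * np.pi)
        assert integral == pytest.approx(expected, rel=0.01)


class TestFixture:
    def test_fixture_directory_deterministic(self, tmp_path):
        cfg = SMALL.replace(n_sites={"NV": 10, "6WT0": 10})
        d1 = write_fixture(cfg, tmp_path / "a")
        d2 = write_fixture(cfg, tmp_path / "b")
        names1 = sorted(p.name for p in d1.iterdir())
        assert names1 == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names1, shallow=False)
        assert mismatch == [] and errors == []

    def test_fixture_contains_expected_files(self, tmp_path):
        d = write_fixture(SMALL.replace(n_sites={"NV": 5, "6WT0": 5}), tmp_path / "fx")
        names = {p.name for p in d.iterdir()}
        assert {"genome.tsv", "genes.gff3", "truth.tsv"} <= names
        assert "VEL1_NV_rep1.narrowPeak" in names
        assert "VEL1_NV_input.bedgraph" in names
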