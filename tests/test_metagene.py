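"""Coverage tracks, RPGC normalization and metagene binning.

The per-base oracle computes bin means on a dense per-base grid with
fractional-overlap weights — an independent route to the same integrals the
implementation evaluates through cumulative step sums.
"""

import numpy as np
import pytest

from chipmeta import (
    CoverageTrack,
    GeneModel,
    GeneSet,
    GenomeAssembly,
    GInterval,
    mean_profile,
    merge_tracks,
    metagene_matrix,
    read_bedgraph,
    rpgc_normalize,
    write_bedgraph,
)
from chipmeta.metagene import BedGraphFormatError


def track_from_steps(steps, chrom="chr1", assembly=None):
    s = np.array([x[0] for x in steps])
    e = np.array([x[1] for x in steps])
    v = np.array([x[2] for x in steps], dtype=float)
    return CoverageTrack({chrom: (s, e, v)}, assembly=assembly)


def dense(track, chrom, length):
    return np.asarray(track.value_at(chrom, np.arange(length)), dtype=float)


class TestBedGraphIO:
    def test_implicit_zero_off_steps(self, tmp_path, asm10k):
        f = tmp_path / "a.bedgraph"
        f.write_text("chr1\t0\t500\t2.0\n")
        t = read_bedgraph(f, assembly=asm10k)
        assert t.value_at("chr1", np.array([0, 499, 500])).tolist() == [2.0, 2.0, 0.0]

    def test_empty_file_is_all_zero(self, tmp_path, asm10k):
        f = tmp_path / "e.bedgraph"
        f.write_text("track type=bedGraph\n")
        t = read_bedgraph(f, assembly=asm10k)
        assert t.total_signal() == 0.0

    def test_overlapping_steps_report_lines(self, tmp_path):
        f = tmp_path / "bad.bedgraph"
        f.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\n")
        with pytest.raises(BedGraphFormatError, match="lines 1 and 2"):
            read_bedgraph(f)

    def test_round_trip_lossless(self, tmp_path, asm10k, rng):
        pos = np.sort(rng.choice(10_000, size=40, replace=False))
        steps = [
            (int(pos[i]), int(pos[i + 1]), round(float(rng.uniform(0, 5)), 4))
            for i in range(0, 38, 2)
        ]
        t = track_from_steps(steps, assembly=asm10k)
        f1, f2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        write_bedgraph(t, f1)
        write_bedgraph(read_bedgraph(f1, assembly=asm10k), f2)
        assert f1.read_text() == f2.read_text()


class TestRPGC:
    def test_uniform_half_coverage_scales_to_one(self, asm10k):
        t = track_from_steps([(0, 10_000, 0.5)], assembly=asm10k)
        n = rpgc_normalize(t)
        assert n.value_at("chr1", np.array([123]))[0] == pytest.approx(1.0)

    def test_already_mean_one_unchanged(self, asm10k):
        # value 2 over half the genome: mean already 1
        t = track_from_steps([(0, 5000, 2.0)], assembly=asm10k)
        n = rpgc_normalize(t)
        assert n.value_at("chr1", np.array([10]))[0] == pytest.approx(2.0)

    def test_genomewide_weighted_mean_exactly_one(self, asm2, rng):
        steps = {}
        for chrom, clen in asm2.chroms:
            pos = np.sort(rng.choice(clen, size=30, replace=False))
            s, e, v = [], [], []
            for i in range(0, 28, 2):
                s.append(int(pos[i]))
                e.append(int(pos[i + 1]))
                v.append(float(rng.uniform(0, 10)))
            steps[chrom] = (np.array(s), np.array(e), np.array(v))
        t = CoverageTrack(steps, assembly=asm2)
        n = rpgc_normalize(t)
        assert n.total_signal() / asm2.total_length == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_track_errors(self, asm10k):
        t = CoverageTrack({}, assembly=asm10k)
        with pytest.raises(ValueError, match="all-zero"):
            rpgc_normalize(t)

    def test_effective_genome_size_override(self, asm10k):
        t = track_from_steps([(0, 1000, 1.0)], assembly=asm10k)
        n = rpgc_normalize(t, effective_genome_size=2000)
        assert n.value_at("chr1", np.array([0]))[0] == pytest.approx(2.0)


class TestMerge:
    def test_stepwise_sum(self, asm10k):
        a = track_from_steps([(0, 100, 1.0)], assembly=asm10k)
        b = track_from_steps([(50, 150, 2.0)], assembly=asm10k)
        m = merge_tracks([a, b])
        assert m.value_at("chr1", np.array([10, 70, 120, 200])).tolist() == [1.0, 3.0, 2.0, 0.0]

    def test_merging_identical_tracks_leaves_rpgc_unchanged(self, asm10k, rng):
        steps = [(0, 3000, 2.0), (4000, 6000, 1.5)]
        t = track_from_steps(steps, assembly=asm10k)
        single = rpgc_normalize(t)
        tripled = rpgc_normalize(merge_tracks([t, t, t]))
        x = np.arange(0, 10_000, 97)
        assert np.allclose(single.value_at("chr1", x), tripled.value_at("chr1", x))


def per_base_oracle(track, gene, clen, flank=1000, body_bins=100, flank_bins=20):
    """Dense per-base binning with fractional overlap into continuous bin spans."""
    cov = dense(track, gene.region.chrom, clen)
    start, end = gene.region.start, gene.region.end
    L = end - start
    w = flank // flank_bins
    bounds = np.concatenate(
        [
            start - flank + w * np.arange(flank_bins + 1),
            (start + L * np.arange(1, body_bins + 1) / body_bins),
            end + w * np.arange(1, flank_bins + 1),
        ]
    ).astype(float)
    vals = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        if lo < 0 or hi > clen:
            vals.append(np.nan)
            continue
        total = 0.0
        for base in range(int(np.floor(lo)), int(np.ceil(hi))):
            ov = min(hi, base + 1) - max(lo, base)
            if ov > 0:
                total += cov[base] * ov
        vals.append(total / (hi - lo))
    vals = np.array(vals)
    return vals[::-1] if gene.strand == "-" else vals


class TestMetageneMatrix:
    def test_uniform_track_gives_all_ones(self, asm10k):
        t = track_from_steps([(0, 10_000, 1.0)], assembly=asm10k)
        genes = GeneSet(
            [GeneModel("G1", GInterval("chr1", 3000, 5000), "+")], assembly=asm10k
        )
        m, ids = metagene_matrix(t, genes)
        assert ids == ["G1"]
        assert np.allclose(m, 1.0)

    def test_strand_symmetry_under_mirrored_coverage(self, asm10k, rng):
        """A minus-strand gene over mirrored coverage gives the identical row."""
        clen = 10_000
        gstart, gend = 4000, 6437  # length not divisible by bin count on purpose
        pos = np.sort(rng.choice(clen - 1, size=30, replace=False))
        steps = [
            (int(pos[i]), int(pos[i + 1]), round(float(rng.uniform(0, 4)), 3))
            for i in range(0, 28, 2)
        ]
        fwd = track_from_steps(steps, assembly=asm10k)
        cov = dense(fwd, "chr1", clen)
        mirrored = cov[::-1].copy()  # base i maps to clen-1-i
        s = np.flatnonzero(np.diff(np.concatenate([[np.inf], mirrored])) != 0)
        e = np.append(s[1:], clen)
        rev = CoverageTrack(
            {"chr1": (s.astype(int), e.astype(int), mirrored[s])}, assembly=asm10k
        )
        g_fwd = GeneSet([GeneModel("G", GInterval("chr1", gstart, gend), "+")], assembly=asm10k)
        g_rev = GeneSet(
            [GeneModel("G", GInterval("chr1", clen - gend, clen - gstart), "-")],
            assembly=asm10k,
        )
        m1, _ = metagene_matrix(fwd, g_fwd)
        m2, _ = metagene_matrix(rev, g_rev)
        assert np.allclose(m1, m2, atol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_per_base_oracle(self, asm10k, rng, strand):
        clen = 10_000
        pos = np.sort(rng.choice(clen, size=50, replace=False))
        steps = [
            (int(pos[i]), int(pos[i + 1]), round(float(rng.uniform(0, 6)), 3))
            for i in range(0, 48, 2)
        ]
        t = track_from_steps(steps, assembly=asm10k)
        for gstart, glen in [(1500, 2437), (500, 1001), (7000, 1999)]:
            g = GeneModel("G", GInterval("chr1", gstart, gstart + glen), strand)
            genes = GeneSet([g], assembly=asm10k)
            m, _ = metagene_matrix(t, genes)
            oracle = per_base_oracle(t, g, clen)
            assert np.allclose(m[0], oracle, atol=1e-9, equal_nan=True)

    def test_off_chromosome_flank_bins_are_nan(self, asm10k):
        t = track_from_steps([(0, 10_000, 1.0)], assembly=asm10k)
        genes = GeneSet([GeneModel("G", GInterval("chr1", 400, 900), "+")], assembly=asm10k)
        m, _ = metagene_matrix(t, genes, min_gene_length=100)
        # upstream flank starts at -600: bins covering negative coordinates are NA
        assert np.isnan(m[0, :12]).all()
        assert np.isfinite(m[0, 12:]).all()

    def test_short_genes_excluded(self, asm10k):
        t = track_from_steps([(0, 10_000, 1.0)], assembly=asm10k)
        genes = GeneSet(
            [
                GeneModel("tiny", GInterval("chr1", 3000, 3050), "+"),
                GeneModel("ok", GInterval("chr1", 5000, 6000), "+"),
            ],
            assembly=asm10k,
        )
        m, ids = metagene_matrix(t, genes)
        assert ids == ["ok"]

    def test_translation_invariance(self, asm2, rng):
        steps = [(1000, 1500, 2.0), (2000, 2600, 0.5)]
        t1 = track_from_steps(steps, assembly=asm2)
        t2 = track_from_steps([(s + 3000, e + 3000, v) for s, e, v in steps], assembly=asm2)
        g1 = GeneSet([GeneModel("G", GInterval("chr1", 1200, 2400), "+")], assembly=asm2)
        g2 = GeneSet([GeneModel("G", GInterval("chr1", 4200, 5400), "+")], assembly=asm2)
        m1, _ = metagene_matrix(t1, g1)
        m2, _ = metagene_matrix(t2, g2)
        assert np.allclose(m1, m2, equal_nan=True)


class TestMeanProfile:
    def test_identical_rows_profile_equals_row(self):
        row = np.linspace(0, 2, 140)
        p = mean_profile(np.vstack([row, row]))
        assert np.allclose(p.values, row)
        assert p.n_genes == 2

    def test_mean_of_zero_and_two_is_one(self):
        m = np.vstack([np.zeros(140), np.full(140, 2.0)])
        assert np.allclose(mean_profile(m).values, 1.0)

    def test_nan_ignored_but_all_nan_column_stays_nan(self):
        m = np.ones((3, 140))
        m[0, 0] = np.nan
        m[:, 1] = np.nan
        p = mean_profile(m)
        assert p.values[0] == 1.0
        assert np.isnan(p.values[1])
        assert p.n_per_bin[0] == 2

    def test_roles_and_tsv(self, tmp_path):
        p = mean_profile(np.ones((1, 140)))
        assert p.roles[0] == "upstream" and p.roles[20] == "body" and p.roles[-1] == "downstream"
        f = tmp_path / "p.tsv"
        p.to_tsv(f)
        assert f.read_text().startswith("bin\trole\tmean\tn\n")

    def test_uniform_rpgc_coverage_profiles_at_one(self, asm10k, rng):
        t = rpgc_normalize(track_from_steps([(0, 10_000, 3.7)], assembly=asm10k))
        genes = GeneSet(
            [
                GeneModel(f"G{i}", GInterval("chr1", int(s), int(s) + 1200, ), "+" if i % 2 else "-")
                for i, s in enumerate(rng.integers(1000, 7800, size=5))
            ],
            assembly=asm10k,
        )
        m, _ = metagene_matrix(t, genes)
        assert np.allclose(mean_profile(m).values, 1.0, atol=1e-9)
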