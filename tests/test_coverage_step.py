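import numpy as np
import pytest

from leaderless_scan.coverage_step import (
    AlignmentInterval,
    CoverageTrack,
    aggregate_trends,
    depth_from_alignments,
    gene_profile,
    read_bedgraph,
    read_intervals_tsv,
    region_selection,
    step_statistic,
    write_bedgraph,
    write_intervals_tsv,
)
from leaderless_scan.genome_io import Contig, GeneRecord
from leaderless_scan._seq import revcomp


def contig(n=3000, name="c"):
    return Contig(name, "A" * n)


class TestDepth:
    def test_single_interval(self):
        track, counts = depth_from_alignments(
            [AlignmentInterval("c", 10, 20)], [contig(100)]
        )
        d = track.depth["c"]
        assert d[10:20].sum() == 10 and d.sum() == 10
        assert counts.kept == 1

    def test_gapped_and_inverted_excluded_and_counted(self):
        ivs = [
            AlignmentInterval("c", 0, 10),
            AlignmentInterval("c", 0, 10, has_gap=True),
            AlignmentInterval("c", 0, 10, is_inverted=True),
        ]
        track, counts = depth_from_alignments(ivs, [contig(100)])
        assert track.total_depth() == 10
        assert counts.gapped == 1 and counts.inverted == 1 and counts.excluded == 2

    def test_matches_brute_force_membership_count(self):
        rng = np.random.default_rng(0)
        c = contig(500)
        ivs = []
        for _ in range(500):
            s = int(rng.integers(0, 480))
            ivs.append(AlignmentInterval("c", s, s + int(rng.integers(1, 21))))
        track, _ = depth_from_alignments(ivs, [c])
        brute = np.zeros(500, dtype=int)
        for iv in ivs:
            brute[iv.start : iv.end] += 1
        assert (track.depth["c"] == brute).all()

    def test_out_of_bounds_interval_raises(self):
        with pytest.raises(ValueError, match="beyond contig"):
            depth_from_alignments([AlignmentInterval("c", 90, 120)], [contig(100)])

    def test_depth_mass_equals_retained_interval_length(self):
        rng = np.random.default_rng(1)
        ivs = [
            AlignmentInterval(
                "c",
                int(s := rng.integers(0, 2900)),
                int(s + rng.integers(1, 100)),
                has_gap=bool(rng.random() < 0.1),
            )
            for _ in range(400)
        ]
        track, counts = depth_from_alignments(ivs, [contig()])
        kept = sum(iv.length for iv in ivs if not iv.has_gap)
        assert track.total_depth() == kept


class TestRegionsAndProfiles:
    def test_region_arithmetic(self):
        g = GeneRecord("g", "c", "+", 1000, 1900, "ATG")
        name, lo, hi = region_selection(g, [contig()], up=400, down=400)
        assert hi - lo == 1700

    def test_edge_gene_dropped(self):
        g = GeneRecord("g", "c", "+", 100, 1000, "ATG")
        assert region_selection(g, [contig()], up=400, down=400) is None

    def test_minus_strand_region_flips_orientation(self):
        g = GeneRecord("g", "c", "-", 1000, 1900, "ATG")
        _, lo, hi = region_selection(g, [contig()], up=400, down=100)
        assert (lo, hi) == (900, 2300)

    def test_uniform_track_gives_constant_profile(self):
        track = CoverageTrack({"c": np.full(3000, 5)})
        g = GeneRecord("g", "c", "+", 1000, 1900, "ATG")
        profile = gene_profile(track, g, flank=100)
        assert (profile.depth == 5).all()
        assert len(profile.depth) == 900 + 200

    def test_minus_profile_is_reversed_forward_slice(self):
        arr = np.arange(3000)
        track = CoverageTrack({"c": arr})
        g = GeneRecord("g", "c", "-", 1000, 1900, "ATG")
        profile = gene_profile(track, g, flank=50)
        assert (profile.depth == arr[950:1950][::-1]).all()

    def test_strand_symmetry_of_profiles(self, small_genome):
        """Reverse-complementing the genome and flipping annotations leaves
        every gene profile unchanged."""
        from leaderless_scan import synthetic

        spec, contigs, genes, truth = small_genome
        intervals, track = synthetic.gen_coverage(spec, truth, genes, contigs)
        L = len(contigs[0].seq)
        flipped_track = CoverageTrack({"synth_1": track.depth["synth_1"][::-1].copy()})
        for g in genes[:20]:
            flipped = GeneRecord(
                g.gene_id, g.contig, "-" if g.strand == "+" else "+",
                L - g.end, L - g.start, g.start_codon,
            )
            a = gene_profile(track, g, 100)
            b = gene_profile(flipped_track, flipped, 100)
            if a is None or b is None:
                continue
            assert (a.depth == b.depth).all()

    def test_zoom_slice(self):
        track = CoverageTrack({"c": np.arange(3000)})
        g = GeneRecord("g", "c", "+", 1000, 1900, "ATG")
        z = gene_profile(track, g, flank=100).zoom(-20, 60)
        assert len(z) == 80
        assert z[0] == 980 and z[-1] == 1059


class TestStepStatistic:
    def profile_from(self, values):
        from leaderless_scan.coverage_step import GeneProfile

        return GeneProfile("g", np.asarray(values, float), flank=100)

    def test_flat_profile_is_flat(self):
        call = step_statistic(self.profile_from([5.0] * 500), motif_end_rel=-7)
        assert call.trend == "flat"
        assert call.ratio == pytest.approx(5 / 5.5)

    def test_all_zero_is_low_coverage(self):
        call = step_statistic(self.profile_from([0.0] * 500), motif_end_rel=-7)
        assert call.trend == "low-coverage"

    def test_decrease_detected(self):
        vals = [10.0] * 93 + [1.0] * 407
        call = step_statistic(self.profile_from(vals), motif_end_rel=-7)
        assert call.trend == "decrease"

    def test_poisson_step_detected_in_most_replicates(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 300
        for _ in range(reps):
            vals = np.concatenate(
                [rng.poisson(1.0, 94), rng.poisson(10.0, 406)]
            ).astype(float)
            call = step_statistic(self.profile_from(vals), motif_end_rel=-7)
            hits += call.trend == "step-increase"
        assert hits / reps >= 0.95

    def test_tau_monotonicity(self):
        rng = np.random.default_rng(4)
        profiles = [
            self.profile_from(
                np.concatenate([rng.poisson(1.0, 94), rng.poisson(t, 406)])
            )
            for t in np.linspace(1, 10, 40)
        ]
        counts = []
        for tau in (1.5, 2.0, 3.0, 5.0):
            calls = [step_statistic(p, -7, tau=tau) for p in profiles]
            counts.append(sum(c.trend == "step-increase" for c in calls))
        assert counts == sorted(counts, reverse=True)

    def test_windows_outside_profile_rejected(self):
        with pytest.raises(ValueError, match="profiled span"):
            step_statistic(self.profile_from([1.0] * 120), motif_end_rel=-90)


class TestAggregateTrends:
    def test_all_step_counts(self):
        from leaderless_scan.coverage_step import TrendCall

        calls = [TrendCall(f"g{i}", 1, 10, 6.7, "step-increase") for i in range(5)]
        counts, _ = aggregate_trends(calls)
        assert counts["step-increase"] == 5
        assert counts["flat"] == 0

    def test_mean_curve_of_identical_steps_keeps_shape(self):
        from leaderless_scan.coverage_step import GeneProfile, TrendCall

        vals = np.array([1.0] * 100 + [10.0] * 300)
        profiles = [GeneProfile(f"g{i}", vals.copy(), flank=50) for i in range(4)]
        calls = [TrendCall(f"g{i}", 1, 10, 6.7, "step-increase") for i in range(4)]
        counts, curve = aggregate_trends(calls, profiles, anchors=[49] * 4)
        grad = np.diff(curve["mean_depth"].to_numpy())
        assert curve is not None
        assert int(curve["position"][np.argmax(grad) + 1]) == 1


class TestRoundTrips:
    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        d = rng.poisson(2.0, 400)
        track = CoverageTrack({"c": d.astype(np.int64)})
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, str(path))
        back = read_bedgraph(str(path), {"c": 400})
        assert (back.depth["c"] == d).all()

    def test_intervals_tsv_round_trip(self, tmp_path):
        ivs = [
            AlignmentInterval("c", 0, 10),
            AlignmentInterval("c", 5, 25, has_gap=True),
            AlignmentInterval("c", 9, 12, is_inverted=True),
        ]
        path = tmp_path / "iv.tsv"
        write_intervals_tsv(ivs, str(path))
        assert read_intervals_tsv(str(path)) == ivs
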