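"""Proximity linking, signal-tier clustering, profile matrices, DE filter."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import per_base_signal, random_track
from quantepi.core import GenomicInterval, QuantTrack, ValidationError
from quantepi.integrate import (
    cluster_by_signal,
    filter_de,
    link_within,
    profile_matrix,
)


class TestLinkWithin:
    def test_linked_inside_window(self):
        a = [GenomicInterval("chr1", 900, 1100)]
        b = [GenomicInterval("chr1", 10_500, 10_600)]
        [pair] = link_within(a, b, window=10_000)
        assert pair.distance == 9_400

    def test_unlinked_outside_window(self):
        a = [GenomicInterval("chr1", 900, 1100)]
        b = [GenomicInterval("chr1", 11_200, 11_300)]
        assert link_within(a, b, window=10_000) == []

    def test_overlap_distance_zero(self):
        a = [GenomicInterval("chr1", 100, 300)]
        b = [GenomicInterval("chr1", 250, 400)]
        [pair] = link_within(a, b, window=10_000)
        assert pair.distance == 0

    def test_upstream_negative_distance(self):
        a = [GenomicInterval("chr1", 5000, 5200)]
        b = [GenomicInterval("chr1", 1000, 2000)]
        [pair] = link_within(a, b, window=10_000)
        assert pair.distance == -3000

    def test_nearest_wins_and_ties_go_left(self):
        a = [GenomicInterval("chr1", 1000, 1100)]
        b = [
            GenomicInterval("chr1", 700, 900),  # gap 100, smaller start
            GenomicInterval("chr1", 1200, 1400),  # gap 100
            GenomicInterval("chr1", 2000, 2100),  # gap 900
        ]
        [pair] = link_within(a, b, window=10_000)
        assert pair.peak_b.start == 700

    def test_translation_invariant(self):
        rng = np.random.default_rng(1)
        a = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 100_000, 20) * 10
        ]
        b = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 100_000, 20) * 10
        ]
        shift = 12_345
        pairs = link_within(a, b, 10_000)
        shifted = link_within(
            [GenomicInterval(p.chrom, p.start + shift, p.end + shift) for p in a],
            [GenomicInterval(p.chrom, p.start + shift, p.end + shift) for p in b],
            10_000,
        )
        assert [p.distance for p in pairs] == [p.distance for p in shifted]
        assert [p.peak_a.start + shift for p in pairs] == [
            p.peak_a.start for p in shifted
        ]

    def test_different_chromosomes_never_link(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr2", 0, 100)]
        assert link_within(a, b, 10_000) == []


def tiered_setup(seed=5, n_per_tier=20, window=10_000):
    rng = np.random.default_rng(seed)
    levels = {"low": 0.1, "intermediate": 1.0, "high": 5.0}
    tiers, a_peaks, b_peaks, records = [], [], [], []
    for i, tier in enumerate(
        [t for t in ("low", "intermediate", "high") for _ in range(n_per_tier)]
    ):
        center = 50_000 + i * 40_000
        tiers.append(tier)
        a_peaks.append(GenomicInterval("chr1", center - 500, center + 500))
        b_peaks.append(GenomicInterval("chr1", center + 2000, center + 2500))
        value = levels[tier] * float(rng.uniform(0.9, 1.1))
        records.append(("chr1", center - window, center + window, value))
    track = QuantTrack.from_records(records, chrom_lengths={"chr1": 10_000_000})
    return tiers, a_peaks, b_peaks, track


class TestClusterBySignal:
    def test_recovers_planted_tiers(self):
        tiers, a, b, track = tiered_setup()
        pairs = link_within(a, b, 10_000)
        assignment = cluster_by_signal(pairs, track, window=10_000, seed=0)
        assert adjusted_rand_score(tiers, assignment.tiers) >= 0.9
        assert assignment.centroids == sorted(assignment.centroids)

    def test_tier_labels_follow_centroid_order(self):
        tiers, a, b, track = tiered_setup(seed=8)
        pairs = link_within(a, b, 10_000)
        assignment = cluster_by_signal(pairs, track, window=10_000, seed=0)
        by_tier = {
            t: np.mean(
                [f for f, lab in zip(assignment.features, assignment.tiers) if lab == t]
            )
            for t in ("low", "intermediate", "high")
        }
        assert by_tier["low"] < by_tier["intermediate"] < by_tier["high"]

    def test_deterministic(self):
        tiers, a, b, track = tiered_setup(seed=9)
        pairs = link_within(a, b, 10_000)
        a1 = cluster_by_signal(pairs, track, 10_000, seed=3)
        a2 = cluster_by_signal(pairs, track, 10_000, seed=99)
        assert a1.tiers == a2.tiers

    def test_degenerate_identical_signal_flagged(self):
        a = [GenomicInterval("chr1", s, s + 100) for s in (1000, 5000, 9000, 13_000)]
        b = a
        track = QuantTrack.from_records([("chr1", 0, 20_000, 2.0)])
        pairs = link_within(a, b, 1000)
        assignment = cluster_by_signal(pairs, track, window=500, seed=0)
        assert assignment.degenerate
        assert len(set(assignment.centroids)) == 1

    def test_fewer_pairs_than_k_errors(self):
        a = [GenomicInterval("chr1", 0, 100)]
        track = QuantTrack.from_records([("chr1", 0, 1000, 1.0)])
        pairs = link_within(a, a, 1000)
        with pytest.raises(ValidationError):
            cluster_by_signal(pairs, track, window=100, k=3)


class TestProfileMatrix:
    def test_constant_track_identity(self):
        track = QuantTrack.from_records(
            [("chr1", 0, 100_000, 1.7)], chrom_lengths={"chr1": 100_000}
        )
        regions = [GenomicInterval("chr1", 40_000, 41_000)]
        pm = profile_matrix(track, regions, flank=1000, bin_size=50)
        assert pm.n_columns == 40
        assert np.allclose(pm.matrix, 1.7)
        assert np.allclose(pm.profile, 1.7)

    def test_column_count_scale_mode(self):
        track = QuantTrack.from_records(
            [("chr1", 0, 100_000, 1.0)], chrom_lengths={"chr1": 100_000}
        )
        pm = profile_matrix(
            track,
            [GenomicInterval("chr1", 50_000, 53_000)],
            mode="scale_regions",
            flank=500,
            bin_size=50,
            body_bins=20,
        )
        assert pm.n_columns == 10 + 20 + 10
        assert np.allclose(pm.matrix, 1.0)

    def test_reference_point_matches_per_base_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            track = random_track(rng, length=1000)
            base = per_base_signal(track, "chr1", 1000)
            center = int(rng.integers(200, 800))
            region = GenomicInterval("chr1", center - 10, center + 10)
            flank, width = 100, 20
            pm = profile_matrix(track, [region], flank=flank, bin_size=width)
            left = region.center - flank
            for c in range(pm.n_columns):
                lo, hi = left + c * width, left + (c + 1) * width
                assert pm.matrix[0, c] == pytest.approx(base[lo:hi].mean())

    def test_out_of_bounds_bins_missing_and_excluded(self):
        track = QuantTrack.from_records(
            [("chr1", 0, 2000, 3.0)], chrom_lengths={"chr1": 2000}
        )
        region = GenomicInterval("chr1", 100, 300)  # center 200, flank 1000
        pm = profile_matrix(track, [region], flank=1000, bin_size=100)
        assert np.isnan(pm.matrix[0, :8]).all()  # bins before base 0
        assert np.isfinite(pm.matrix[0, 8:]).all()
        assert np.allclose(pm.profile[8:], 3.0)

    def test_flank_not_divisible_errors(self):
        track = QuantTrack.from_records([("chr1", 0, 100, 1.0)])
        with pytest.raises(ValidationError):
            profile_matrix(track, [], flank=1000, bin_size=300)


class TestFilterDE:
    def test_inclusive_bounds_and_exclusions(self):
        table = pd.DataFrame(
            {
                "gene": ["G1", "G2", "G3", "G4"],
                "log2FC": [1.0, 0.9, -2.0, -1.0],
                "FDR": [0.01, 0.001, 0.05, 0.01],
            }
        )
        up, down = filter_de(table)
        assert up == {"G1"}  # boundary values are included
        assert down == {"G4"}  # G3 fails the FDR gate

    def test_custom_thresholds(self):
        table = pd.DataFrame(
            {"gene": ["A", "B"], "log2FC": [0.7, -0.7], "FDR": [0.02, 0.02]}
        )
        up, down = filter_de(table, lfc_min=0.5, fdr_max=0.05)
        assert up == {"A"} and down == {"B"}
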