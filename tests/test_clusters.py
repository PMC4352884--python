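"""Cluster calling and cluster-level analyses."""

import numpy as np
import pytest

from replicomb import (
    ClusterParams,
    ClusteredPlacementParams,
    GenomeSpec,
    call_clusters,
    call_origins,
    cluster_extension,
    cluster_statistics,
    generate_two_regime_molecules,
    positional_overlap,
    transition_point_scan,
)
from replicomb.metrics import OriginCall

from conftest import make_molecule


def calls_at(positions, mid="m"):
    return [OriginCall(mid, float(p), 4.0) for p in positions]


class TestCallClusters:
    def test_five_origins_chain(self):
        out = call_clusters(calls_at([0, 30, 60, 90, 120]))
        assert len(out) == 1
        c = out[0]
        assert c.n_origins == 5
        assert c.size_kb == pytest.approx(120.0)
        assert c.mean_internal_iod_kb == pytest.approx(30.0)

    def test_four_origins_are_not_a_cluster(self):
        assert call_clusters(calls_at([0, 30, 60, 90])) == []

    def test_gap_over_d_max_splits(self):
        pos = [0, 30, 60, 90, 120, 161, 191, 221, 251, 281]  # 41-kb gap
        out = call_clusters(calls_at(pos))
        assert len(out) == 2
        assert [c.n_origins for c in out] == [5, 5]

    def test_d_max_is_inclusive(self):
        pos = [0, 40, 80, 120, 160]  # all gaps exactly 40
        assert len(call_clusters(calls_at(pos))) == 1

    def test_idempotent_and_order_independent(self):
        pos = [120, 0, 60, 30, 90]
        a = call_clusters(calls_at(pos))
        b = call_clusters(calls_at(sorted(pos)))
        assert a == b

    def test_monotonicity_in_parameters(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.uniform(0, 2000, size=120))
        origins = calls_at(pos)
        counts_min_n = [
            len(call_clusters(origins, ClusterParams(40.0, mn)))
            for mn in range(2, 11)
        ]
        assert all(a >= b for a, b in zip(counts_min_n, counts_min_n[1:]))
        counts_d_max = [
            len(call_clusters(origins, ClusterParams(d, 5)))
            for d in (10.0, 20.0, 40.0, 80.0)
        ]
        # raising d_max can merge clusters but never loses clustered origins;
        # with min_n fixed the count is not monotone, the spanned origins are
        spanned = [
            sum(c.n_origins for c in call_clusters(origins, ClusterParams(d, 5)))
            for d in (10.0, 20.0, 40.0, 80.0)
        ]
        assert all(a <= b for a, b in zip(spanned, spanned[1:]))


class TestTransitionScan:
    def test_planted_cluster_size_gives_elbow(self):
        # clusters of exactly 8 origins, 20-kb spacings, far apart
        pos = []
        for k in range(12):
            pos.extend(k * 1000.0 + 20.0 * np.arange(8))
        mols = [make_molecule(12000.0, [], "m")]
        scan = transition_point_scan(calls_at(pos), mols, genome_kb=12000.0)
        assert abs(scan.elbow - 8) <= 1

    def test_uniform_origins_have_weak_elbow(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.uniform(0, 13600.0, size=450))
        mols = [make_molecule(13600.0, [], "m")]
        scan = transition_point_scan(calls_at(pos), mols, genome_kb=13600.0)
        smooth = scan.improvement_ratio
        assert smooth < 2.0  # spurious-chain decay is one straight line (log scale)
        # planted-structure control shows a much sharper elbow
        pos2 = []
        for k in range(25):
            pos2.extend(k * 540.0 + 20.0 * np.arange(8))
        sharp = transition_point_scan(
            calls_at(pos2), mols, genome_kb=13600.0
        ).improvement_ratio
        assert sharp > 2 * smooth

    def test_calibrated_generator_transition_near_cluster_minimum(self, genome):
        """The calibrated generator's scan flattens where spurious sparse
        chains die out, one step below the five-origin cluster minimum."""
        params = ClusteredPlacementParams()
        elbows = []
        for seed in range(5):
            mols, _ = generate_two_regime_molecules(params, genome, seed=seed,
                                                    n_molecules=60)
            origins = [o for m in mols for o in call_origins(m)]
            scan = transition_point_scan(origins, mols, genome.total_kb)
            elbows.append(scan.elbow)
            assert scan.improvement_ratio > 2.0
        assert 3 <= np.median(elbows) <= 6


class TestClusterStatistics:
    def test_single_planted_cluster_arithmetic(self):
        origins = calls_at([100, 120, 140, 160, 180])
        clusters = call_clusters(origins)
        mols = [make_molecule(1000.0, [], "m")]
        stats = cluster_statistics(clusters, origins, mols, genome_kb=1000.0)
        assert stats.mean_within_iod_kb == pytest.approx(20.0)
        assert stats.sizes_kb[0] == pytest.approx(80.0)
        assert stats.fraction_origins_in_clusters == 1.0
        assert stats.clusters_per_genome == pytest.approx(1.0)

    def test_zero_clusters(self):
        origins = calls_at([100, 200])
        stats = cluster_statistics([], origins,
                                   [make_molecule(1000.0, [], "m")], 1000.0)
        assert stats.n_clusters == 0
        assert stats.fraction_origins_in_clusters == 0.0
        assert np.isnan(stats.mean_within_iod_kb)

    def test_foci_correspondence_table(self):
        origins = calls_at([100, 120, 140, 160, 180])
        clusters = call_clusters(origins)
        mols = [make_molecule(1000.0, [(100.0, 400.0, "BrdU")], "m")]
        stats = cluster_statistics(
            clusters, origins, mols, 1000.0, focus_counts={"20-50%": 26}
        )
        assert list(stats.foci_table["extent_bin"]) == ["20-50%"]
        assert stats.foci_table["foci_per_nucleus"].iloc[0] == 26


class TestClusterExtension:
    def _setup(self):
        origins = calls_at([100, 120, 140, 160, 180])
        clusters = call_clusters(origins)
        mol = make_molecule(
            2000.0, [(95.0 + 20 * i, 105.0 + 20 * i, "BrdU") for i in range(5)], "m"
        )
        return clusters, mol

    def test_edge_placed_new_origins_are_enriched(self):
        clusters, mol = self._setup()
        new = calls_at([195, 210, 72], "m")  # all within 40 kb of the span
        rep = cluster_extension(clusters, new, [mol], adjacency_kb=40.0,
                                n_mc=400, seed=0)
        assert rep.n_adjacent == 3
        assert rep.enrichment > 3
        assert rep.p_value < 0.05

    def test_uniform_new_origins_are_not_enriched(self):
        clusters, mol = self._setup()
        rng = np.random.default_rng(2)
        reps = []
        for i in range(30):
            new = calls_at(rng.uniform(200, 2000, size=6), "m")
            rep = cluster_extension(clusters, new, [mol], adjacency_kb=40.0,
                                    n_mc=200, seed=i)
            reps.append(rep.n_adjacent - rep.expected_adjacent)
        assert abs(np.mean(reps)) < 0.5

    def test_empty_chase_set(self):
        clusters, mol = self._setup()
        rep = cluster_extension(clusters, [], [mol], n_mc=100, seed=0)
        assert rep.n_new_origins == 0
        assert rep.n_adjacent == 0


class TestPositionalOverlap:
    def _aligned_cohort(self, cluster_starts_by_mol):
        mols, clusters = [], []
        for i, starts in enumerate(cluster_starts_by_mol):
            m = make_molecule(1000.0, [], f"m{i}")
            m.chromosome, m.offset_kb, m.orientation = "I", 2000.0, "+"
            mols.append(m)
            for s in starts:
                origins = calls_at(np.arange(s, s + 100.0, 20.0), f"m{i}")
                clusters.extend(call_clusters(origins))
        return mols, clusters

    def test_identical_clusters_give_fraction_one(self):
        mols, clusters = self._aligned_cohort([[400.0]] * 6)
        out = positional_overlap(mols, clusters, [2450.0], n_perm=50, seed=0)
        assert out[0].fraction == 1.0
        assert out[0].n_covering == 6

    def test_position_outside_molecules_flagged(self):
        mols, clusters = self._aligned_cohort([[400.0]] * 3)
        out = positional_overlap(mols, clusters, [9000.0], n_perm=10, seed=0)
        assert out[0].n_covering == 0
        assert np.isnan(out[0].fraction)

    def test_random_placement_matches_permutation_null(self):
        rng = np.random.default_rng(3)
        starts = [[float(rng.uniform(0, 900))] for _ in range(40)]
        mols, clusters = self._aligned_cohort(starts)
        out = positional_overlap(mols, clusters, [2500.0], n_perm=300, seed=4)
        r = out[0]
        # observed fraction consistent with the shuffled-cluster null
        binom_se = np.sqrt(max(r.null_fraction, 0.02) *
                           (1 - min(r.null_fraction, 0.98)) / r.n_covering)
        assert abs(r.fraction - r.null_fraction) < 4 * binom_se
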