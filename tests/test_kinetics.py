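"""Pulse/chase kinetics: replicon classification, velocities, rates, overlap."""

import numpy as np
import pandas as pd
import pytest

from replicomb import (
    GenomeSpec,
    classify_replicons,
    count_fork_ends,
    estimate_fork_velocities,
    firing_and_density_profiles,
    kinetic_point,
    memory_overlap,
    region_timing,
    total_origins_estimate,
    velocity_vs_density,
)
from replicomb.kinetics import ACTIVE, NEWLY_FIRED, TERMINATED, memory_overlap_scan

from conftest import make_molecule


class TestClassifyReplicons:
    def test_active_with_both_forks_progressive(self, pulse_chase_molecule):
        recs = classify_replicons(pulse_chase_molecule)
        assert len(recs) == 1
        r = recs[0]
        assert r.classification == ACTIVE
        assert r.left.status == r.right.status == "progressive"
        assert r.origin_kb == pytest.approx(55.0)

    def test_edu_only_block_is_newly_fired(self):
        m = make_molecule(200.0, [(100.0, 106.0, "EdU")])
        recs = classify_replicons(m)
        assert recs[0].classification == NEWLY_FIRED
        assert recs[0].n_progressive == 2

    def test_block_truncated_at_molecule_end_not_progressive(self):
        m = make_molecule(100.0, [(90.0, 95.0, "BrdU"), (95.0, 100.0, "EdU")])
        recs = classify_replicons(m)
        r = recs[0]
        assert r.right.status == "truncated"
        assert r.left.status == "merged/stalled"  # BrdU edge: fork gone by chase
        assert r.classification == TERMINATED

    def test_merged_neighbors_form_one_terminated_block(self):
        # two replicons whose EdU flanks met during the chase: one block whose
        # outer edges are BrdU against unlabeled DNA
        m = make_molecule(
            400.0,
            [
                (100.0, 120.0, "BrdU"),
                (120.0, 128.0, "EdU"),
                (128.0, 150.0, "BrdU"),
            ],
        )
        recs = classify_replicons(m)
        assert len(recs) == 1
        assert recs[0].classification == TERMINATED

    def test_unlabeled_molecule_has_no_records(self):
        assert classify_replicons(make_molecule(100.0, [])) == []


class TestForkVelocities:
    def test_edu_segment_over_chase(self, pulse_chase_molecule):
        vel = estimate_fork_velocities(
            classify_replicons(pulse_chase_molecule), chase_min=3.0
        )
        assert vel.n_forks == 2
        assert vel.velocities_kb_min == pytest.approx([8 / 3, 8 / 3])

    def test_known_lengths(self):
        m = make_molecule(
            200.0, [(50.0, 60.0, "BrdU"), (41.6, 50.0, "EdU"), (60.0, 66.0, "EdU")]
        )
        vel = estimate_fork_velocities(classify_replicons(m), chase_min=3.0)
        assert sorted(vel.velocities_kb_min) == pytest.approx([2.0, 2.8])

    def test_merged_forks_carry_no_velocity(self):
        m = make_molecule(
            400.0,
            [(100.0, 120.0, "BrdU"), (120.0, 128.0, "EdU"), (128.0, 150.0, "BrdU")],
        )
        vel = estimate_fork_velocities(classify_replicons(m), chase_min=3.0)
        assert vel.n_forks == 0

    def test_invalid_chase_rejected(self):
        with pytest.raises(ValueError):
            estimate_fork_velocities([], chase_min=0.0)

    def test_fork_end_consistency_identity(self):
        """Fork ends = 2 x active replicons when nothing merged or truncated."""
        tracks = []
        for k in range(4):
            c = 150.0 + 200.0 * k
            tracks += [(c - 5, c + 5, "BrdU"), (c - 13, c - 5, "EdU"), (c + 5, c + 13, "EdU")]
        m = make_molecule(1000.0, tracks)
        recs = classify_replicons(m)
        assert sum(r.classification == ACTIVE for r in recs) == 4
        assert count_fork_ends(m) == 8


class TestKineticPoint:
    def test_rate_arithmetic_without_corrections(self):
        # 6 newly fired origins, 3-min chase, 0.5 Mb unreplicated -> 4 /min/Mb
        tracks = [(0.0, 470.0, "BrdU")] + [
            (480.0 + 80.0 * k, 485.0 + 80.0 * k, "EdU") for k in range(6)
        ]
        m = make_molecule(1000.0, tracks)
        p = kinetic_point(m, genome_kb=13600.0, chase_min=3.0,
                         midpoint_correction=False)
        assert p.unreplicated_kb == pytest.approx(500.0)
        assert p.n_newly_fired == 6
        assert p.rate_per_min_mb == pytest.approx(4.0)

    def test_density_arithmetic(self):
        # 5 active replicons, 50 kb unreplicated -> 10 per 100 kb
        tracks = []
        for k in range(5):
            a = 190.0 * k
            tracks += [(a, a + 170.0, "BrdU"), (a + 170.0, a + 180.0, "EdU")]
        m = make_molecule(950.0, tracks)
        p = kinetic_point(m, genome_kb=13600.0, chase_min=3.0)
        assert p.n_active == 5
        assert p.unreplicated_kb == pytest.approx(50.0)
        assert p.density_per_100kb == pytest.approx(10.0)

    def test_genome_scaling(self):
        # 30 separated blocks on a 1.5-Mb molecule -> 272 per 13.6-Mb genome
        tracks = [(50.0 * k, 50.0 * k + 10.0, "BrdU") for k in range(30)]
        m = make_molecule(1500.0, tracks)
        p = kinetic_point(m, genome_kb=13600.0)
        assert p.genome_scaled_blocks == pytest.approx(272.0)

    def test_profiles_are_binned_means(self):
        tracks = [(0.0, 470.0, "BrdU")] + [
            (480.0 + 80.0 * k, 485.0 + 80.0 * k, "EdU") for k in range(6)
        ]
        pts = [
            kinetic_point(make_molecule(1000.0, tracks, f"m{i}"), 13600.0)
            for i in range(3)
        ]
        prof = firing_and_density_profiles(pts)
        assert prof["n_molecules"].sum() == 3


class TestVelocityVsDensity:
    def _molecule_with_density_gradient(self, coupled, seed=0):
        """Windows with 1..6 origins; velocities optionally rise with density."""
        rng = np.random.default_rng(seed)
        tracks = []
        L = 300.0 * 6
        for w in range(6):
            n = w + 1
            base = 1.0 + 0.5 * n if coupled else 2.8
            for j in range(n):
                v = base + rng.uniform(-0.2, 0.2)
                c = 300.0 * w + 40.0 + j * 40.0 + rng.uniform(-3, 3)
                e = 3.0 * v
                tracks += [
                    (c - 5, c + 5, "BrdU"),
                    (c - 5 - e, c - 5, "EdU"),
                    (c + 5, c + 5 + e, "EdU"),
                ]
        return make_molecule(L, tracks)

    def test_constructed_coupling_detected(self):
        mols = [self._molecule_with_density_gradient(True, s) for s in range(6)]
        res = velocity_vs_density(mols, chase_min=3.0, n_perm=300, seed=1)
        assert res.correlation > 0.9
        assert res.p_value < 0.05

    def test_constant_velocity_uncorrelated(self):
        mols = [self._molecule_with_density_gradient(False, s) for s in range(6)]
        res = velocity_vs_density(mols, chase_min=3.0, n_perm=300, seed=2)
        assert abs(res.correlation) < 0.2
        assert res.p_value > 0.05

    def test_empty_windows_skipped(self):
        m = make_molecule(900.0, [(50.0, 56.0, "EdU")])
        res = velocity_vs_density([m], chase_min=3.0, n_perm=10, seed=3)
        assert set(res.table["window"]) == {0}


class TestRegionTiming:
    REGIONS = pd.DataFrame(
        {"chrom": ["I"], "start_kb": [2300.0], "end_kb": [2400.0],
         "name": ["cen1"]}
    )

    def _aligned(self, tracks):
        m = make_molecule(1000.0, tracks)
        m.chromosome, m.offset_kb, m.orientation = "I", 2000.0, "+"
        return m

    def test_fully_replicated_region_plots_above_diagonal(self):
        m = self._aligned([(300.0, 400.0, "BrdU"), (600.0, 769.0, "BrdU")])
        df = region_timing([m], self.REGIONS)
        row = df.iloc[0]
        assert row["region_fraction"] == pytest.approx(1.0)
        assert row["rest_fraction"] == pytest.approx(169.0 / 900.0)
        assert row["region_fraction"] > row["rest_fraction"]

    def test_unreplicated_region_plots_below_diagonal(self):
        m = self._aligned([(600.0, 960.0, "BrdU")])
        df = region_timing([m], self.REGIONS)
        assert df.iloc[0]["region_fraction"] == 0.0
        assert df.iloc[0]["rest_fraction"] == pytest.approx(0.4)

    def test_unaligned_molecules_skipped(self):
        m = make_molecule(1000.0, [(0.0, 100.0, "BrdU")])
        assert region_timing([m], self.REGIONS).empty


class TestMemoryOverlap:
    def _positions(self, pos):
        return pd.DataFrame({"chromosome": "I", "position_kb": pos})

    def test_identical_sets_overlap_fully(self):
        first = self._positions([100.0, 500.0, 900.0])
        res = memory_overlap(first, first.copy(), match_kb=5.0, n_perm=50, seed=0)
        assert res.fraction == 1.0

    def test_printed_counts_arithmetic(self):
        """205 of 235 second-round origins not overlapping -> fraction 0.128."""
        rng = np.random.default_rng(1)
        first = self._positions(np.sort(rng.uniform(0, 5600.0, size=300)))
        hits = rng.choice(first["position_kb"], size=30, replace=False)
        misses = first["position_kb"].max() + 10 + np.arange(205) * 20.0
        second = self._positions(np.concatenate([hits, misses]))
        territory = {"I": [(0.0, float(misses.max() + 10))]}
        res = memory_overlap(first, second, match_kb=1.0, territory=territory,
                             n_perm=50, seed=2)
        assert res.n_second == 235
        assert res.n_overlapping == 30
        assert res.fraction == pytest.approx(30 / 235)

    def test_independent_placement_matches_expectation(self):
        rng = np.random.default_rng(3)
        first = self._positions(np.sort(rng.uniform(0, 10000.0, size=200)))
        second = self._positions(np.sort(rng.uniform(0, 10000.0, size=150)))
        territory = {"I": [(0.0, 10000.0)]}
        res = memory_overlap(first, second, match_kb=5.0, territory=territory,
                             n_perm=300, seed=4)
        assert res.p_value > 0.01
        assert res.fraction == pytest.approx(res.expected_fraction, abs=0.08)

    def test_sensitivity_scan_is_monotone(self):
        rng = np.random.default_rng(5)
        first = self._positions(np.sort(rng.uniform(0, 10000.0, size=200)))
        second = self._positions(np.sort(rng.uniform(0, 10000.0, size=100)))
        scan = memory_overlap_scan(first, second, match_grid_kb=(2, 5, 10),
                                   territory={"I": [(0.0, 10000.0)]},
                                   n_perm=50, seed=6)
        fr = scan["fraction"].to_numpy()
        assert np.all(np.diff(fr) >= 0)


class TestTotalOriginsEstimate:
    def test_fully_merged_molecule_counts_one(self):
        m = make_molecule(1000.0, [(0.0, 900.0, "BrdU")])
        est, n = total_origins_estimate([m], genome_kb=1000.0, min_fraction=0.85)
        assert (est, n) == (1.0, 1)

    def test_separated_blocks_scaled(self):
        tracks = [(100.0 * k, 100.0 * k + 90.0, "BrdU") for k in range(9)]
        m = make_molecule(1000.0, tracks + [(900.0, 960.0, "BrdU")])
        est, n = total_origins_estimate([m], genome_kb=13600.0, min_fraction=0.85)
        assert n == 1
        assert est == pytest.approx(10 * 13.6)

    def test_below_threshold_excluded(self):
        m = make_molecule(1000.0, [(0.0, 500.0, "BrdU")])
        est, n = total_origins_estimate([m], genome_kb=1000.0)
        assert n == 0 and np.isnan(est)
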