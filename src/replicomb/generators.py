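"""Static molecule generators: clustered, uniform, and rDNA origin placements.

These generators plant origins with known ground truth and dress them as
labeled molecules, emulating combed single molecules at a chosen replication
extent.  They provide the clustered alternative (two spacing regimes), the
uniform null (also the histone-modification-mutant-like condition, where
clustering is lost), and tandem rDNA repeat arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import GenomeSpec
from .molecule import Molecule, Track
from .noise import CombingNoise
from .simulate import KineticProfile, simulate_genome_sphase


def _truncated_exp_rate(median: float, upper: float) -> float:
    """Rate of an exponential truncated at ``upper`` whose median is ``median``.

    As the rate tends to 0 the truncated law tends to uniform on [0, upper]
    (median upper/2), so a solution requires ``median < upper / 2``; for
    ``median >= upper / 2`` there is none and a plain exponential would also
    violate the truncation bound, so we reject.
    """
    if not (0 < median < upper / 2):
        raise ValueError("need 0 < median < upper/2 for a truncated-exponential fit")

    def gap(lam):
        return (1 - np.exp(-lam * median)) - 0.5 * (1 - np.exp(-lam * upper))

    return brentq(gap, 1e-9, 50.0 / median)


@dataclass(frozen=True)
class ClusteredPlacementParams:
    """Parameters of the clustered origin placement.

    Origins come in clusters (count per cluster = ``origins_per_cluster_min``
    plus a Poisson excess, mean ``origins_per_cluster_mean``) whose internal
    spacings follow an exponential of median ``within_median_kb`` truncated
    at ``within_max_kb``; the territory between clusters carries sparse
    origins with exponential spacings of median ``between_median_kb``.
    ``target_in_cluster_fraction`` records the nominal fraction of origins
    inside clusters; the achieved fraction is an emergent property of the
    spacing laws and is returned with the planted truth.
    """

    clusters_per_genome: float = 25.0
    origins_per_cluster_mean: float = 12.0
    origins_per_cluster_min: int = 5
    within_median_kb: float = 17.0
    within_max_kb: float = 40.0
    between_median_kb: float = 160.0
    target_in_cluster_fraction: float = 0.60

    def __post_init__(self):
        if self.origins_per_cluster_min < 5:
            raise ValueError("clusters are defined by at least five origins")
        if self.within_max_kb < self.within_median_kb:
            raise ValueError("truncation bound below the within-cluster median")
        if self.origins_per_cluster_mean < self.origins_per_cluster_min:
            raise ValueError("mean origins per cluster below the minimum")

    @property
    def within_rate(self) -> float:
        return _truncated_exp_rate(self.within_median_kb, self.within_max_kb)

    @property
    def between_rate(self) -> float:
        return np.log(2) / self.between_median_kb

    @property
    def mean_within_gap_kb(self) -> float:
        lam, U = self.within_rate, self.within_max_kb
        return 1.0 / lam - U * np.exp(-lam * U) / (1.0 - np.exp(-lam * U))

    @property
    def mean_span_kb(self) -> float:
        """Expected first-to-last extent of one planted cluster."""
        return (self.origins_per_cluster_mean - 1) * self.mean_within_gap_kb

    def draw_within_gap(self, rng: np.random.Generator) -> float:
        while True:
            g = rng.exponential(1.0 / self.within_rate)
            if g <= self.within_max_kb:
                return g

    def draw_cluster_size(self, rng: np.random.Generator) -> int:
        return self.origins_per_cluster_min + int(
            rng.poisson(self.origins_per_cluster_mean - self.origins_per_cluster_min)
        )


def molecule_lengths(
    rng: np.random.Generator,
    n: int,
    mean_kb: float = 1800.0,
    min_kb: float = 200.0,
) -> np.ndarray:
    """Combed-fragment length law: shifted exponential with the given mean."""
    return min_kb + rng.exponential(mean_kb - min_kb, size=n)


def tracks_from_origins(
    positions: np.ndarray,
    length_kb: float,
    replication_extent: float,
    channel: str = "BrdU",
    resolution_kb: float = 2.0,
    min_track_kb: float = 2.0,
) -> List[Track]:
    """Expand origins into equal tracks totalling the requested extent.

    Each origin becomes a track of ``extent * length / n_origins`` centred on
    it; overlapping tracks merge (as they would on a real molecule).  Rejects
    extents whose tracks would not fit on the molecule, or whose per-origin
    track falls below the detection minimum.
    """
    positions = np.sort(np.asarray(positions, dtype=float))
    n = len(positions)
    if n == 0:
        return []
    track = replication_extent * length_kb / n
    if track > length_kb:
        raise ValueError("infeasible replication extent: tracks exceed molecule")
    # origin-dense molecules would need sub-detection tracks; clamp at the
    # detection minimum (their achieved fraction ends slightly high)
    track = max(track, min_track_kb)
    res = resolution_kb
    raw = [(max(0.0, x - track / 2), min(length_kb, x + track / 2)) for x in positions]
    snapped = [
        (max(0.0, round(a / res) * res), min(length_kb, round(b / res) * res))
        for a, b in raw
    ]
    merged: List[List[float]] = []
    for a, b in snapped:
        if b - a <= 1e-9:
            continue
        if merged and a <= merged[-1][1] + 1e-9:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [Track(a, b, channel) for a, b in merged]


def generate_two_regime_molecules(
    params: ClusteredPlacementParams,
    genome: GenomeSpec,
    replication_extent: float = 0.15,
    seed: int = 0,
    n_molecules: int = 131,
    mean_length_kb: float = 1800.0,
    min_length_kb: float = 200.0,
) -> Tuple[List[Molecule], pd.DataFrame]:
    """Molecules with planted clustered origins and two spacing regimes.

    Cluster anchors follow a renewal process whose density matches
    ``clusters_per_genome`` (scaled by molecule length) and whose exclusion
    gap keeps planted clusters distinct under the cluster definition;
    cluster origins extend from each anchor with truncated-exponential
    spacings, sparse origins fill the remaining territory with the
    between-cluster spacing law, and every origin is expanded into a track
    so the molecule reaches ``replication_extent``.

    Returns the molecules and the planted truth: one row per origin with
    ``molecule_id``, ``position_kb``, ``in_cluster``, and ``cluster_id``.
    """
    if not (0 < replication_extent <= 0.5):
        raise ValueError("replication_extent must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    lengths = molecule_lengths(rng, n_molecules, mean_length_kb, min_length_kb)
    molecules: List[Molecule] = []
    truth_rows = []
    for m, L in enumerate(lengths):
        mid = f"tworeg{m:04d}"
        # Anchors follow a renewal process with an exclusion gap of one
        # cluster span plus d_max, so planted clusters stay distinct under
        # the cluster definition; the mean anchor period preserves the
        # requested clusters-per-genome density.
        period = genome.total_kb / params.clusters_per_genome
        exclusion = params.mean_span_kb + params.within_max_kb
        tail_mean = max(period - exclusion, 0.05 * period)
        anchors = []
        pos = rng.uniform(0, period)
        while pos < L:
            anchors.append(pos)
            pos += exclusion + rng.exponential(tail_mean)
        anchors = np.array(anchors)
        cluster_spans = []
        cluster_pts = []  # (position, cluster index)
        for c, a in enumerate(anchors):
            n_c = params.draw_cluster_size(rng)
            pos = a
            pts = [pos]
            for _ in range(n_c - 1):
                pos += params.draw_within_gap(rng)
                pts.append(pos)
            pts = [p for p in pts if p <= L]
            if len(pts) >= 2:
                cluster_spans.append((pts[0], pts[-1]))
                cluster_pts.extend((p, c) for p in pts)
        # sparse backbone over the whole molecule, carved out of cluster spans
        sparse = []
        pos = rng.exponential(1.0 / params.between_rate)
        while pos < L:
            if not any(a <= pos <= b for a, b in cluster_spans):
                sparse.append(pos)
            pos += rng.exponential(1.0 / params.between_rate)

        pts = [(p, True, c) for p, c in cluster_pts] + [
            (p, False, -1) for p in sparse
        ]
        pts.sort()
        positions = np.array([p for p, _, _ in pts])
        if len(positions) == 0:
            molecules.append(Molecule(mid, float(L), []))
            continue
        tracks = tracks_from_origins(positions, L, replication_extent)
        molecules.append(Molecule(mid, float(L), tracks))
        for p, in_cl, c in pts:
            truth_rows.append((mid, p, in_cl, f"{mid}.c{c}" if in_cl else ""))
    truth = pd.DataFrame(
        truth_rows, columns=["molecule_id", "position_kb", "in_cluster", "cluster_id"]
    )
    return molecules, truth


def generate_uniform_molecules(
    n_origins: int,
    genome: GenomeSpec,
    replication_extent: float = 0.15,
    seed: int = 0,
    n_molecules: int = 131,
    mean_length_kb: float = 1800.0,
    min_length_kb: float = 200.0,
) -> Tuple[List[Molecule], pd.DataFrame]:
    """Molecules with origins placed i.i.d. uniformly (the stochastic null).

    ``n_origins`` is the genome-wide count; each molecule receives a Poisson
    number with mean scaled by its length.  Spacings are uniform
    order-statistic gaps (asymptotically exponential).  Molecules drawing
    fewer than two origins yield no IODs and are flagged in the truth table
    (``n_origins < 2``).
    """
    rng = np.random.default_rng(seed)
    lengths = molecule_lengths(rng, n_molecules, mean_length_kb, min_length_kb)
    molecules, rows = [], []
    for m, L in enumerate(lengths):
        mid = f"unif{m:04d}"
        n = rng.poisson(n_origins * L / genome.total_kb)
        positions = np.sort(rng.uniform(0, L, size=n))
        tracks = (
            tracks_from_origins(positions, L, replication_extent) if n else []
        )
        molecules.append(Molecule(mid, float(L), tracks))
        for p in positions:
            rows.append((mid, p, n))
    truth = pd.DataFrame(rows, columns=["molecule_id", "position_kb", "n_origins"])
    return molecules, truth


def place_uniform_origins(
    genome: GenomeSpec, n_origins: int, seed: int
) -> pd.DataFrame:
    """``n_origins`` positions i.i.d. uniform over the genome, as a frame."""
    rng = np.random.default_rng(seed)
    lengths = np.array(genome.lengths_kb, dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_origins, p=lengths / lengths.sum())
    rows = [
        (genome.names[c], rng.uniform(0, lengths[c])) for c in chrom_idx
    ]
    df = pd.DataFrame(rows, columns=["chromosome", "position_kb"])
    return df.sort_values(["chromosome", "position_kb"]).reset_index(drop=True)


def generate_rdna_array(
    n_repeats: int = 100,
    repeat_kb: float = 10.0,
    firing_prob: float = 0.2,
    pulse_min: float = 1.0,
    v_kb_min: float = 2.8,
    seed: int = 0,
    n_molecules: int = 1,
    noise: Optional[CombingNoise] = None,
) -> List[Molecule]:
    """Tandem rDNA repeat arrays with one potential origin per repeat.

    Each repeat's origin (at the repeat midpoint) fires independently with
    ``firing_prob``; a fired origin produces a bidirectional track of
    ``2 * v * pulse`` centred on it.  With firing probability ``p`` the mean
    measured IOD is ``repeat_kb / p`` (geometric spacing of fired repeats).
    """
    if not (0.0 <= firing_prob <= 1.0):
        raise ValueError("firing_prob must lie in [0, 1]")
    noise = noise or CombingNoise()
    rng = np.random.default_rng(seed)
    L = n_repeats * repeat_kb
    track = 2.0 * v_kb_min * pulse_min
    molecules = []
    for m in range(n_molecules):
        fired = rng.random(n_repeats) < firing_prob
        positions = (np.flatnonzero(fired) + 0.5) * repeat_kb
        tracks = []
        res = noise.resolution_kb
        for x in positions:
            a = round(max(0.0, x - track / 2) / res) * res
            b = round(min(L, x + track / 2) / res) * res
            if b - a >= noise.min_track_kb - 1e-9:
                tracks.append(Track(a, b, "BrdU"))
        merged: List[List] = []
        for t in sorted(tracks, key=lambda t: t.start_kb):
            if merged and t.start_kb <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], t.end_kb)
            else:
                merged.append([t.start_kb, t.end_kb])
        molecules.append(
            Molecule(
                f"rdna{m:04d}", L, [Track(a, b, "BrdU") for a, b in merged]
            )
        )
    return molecules


@dataclass
class SuccessiveSPhases:
    """Early-firing origin sets of two consecutive S-phases."""

    first_early: pd.DataFrame   # chromosome, position_kb, time_min
    second_early: pd.DataFrame
    refire_model: str
    inherited_mask: Optional[np.ndarray]  # per second-round origin (inherited model)

    def overlap_fraction(self, match_kb: float) -> float:
        """Fraction of second-round early origins within ``match_kb`` of a
        first-round early origin on the same chromosome."""
        if len(self.second_early) == 0:
            return float("nan")
        hits = 0
        for chrom, grp in self.second_early.groupby("chromosome"):
            ref = self.first_early.loc[
                self.first_early["chromosome"] == chrom, "position_kb"
            ].to_numpy()
            if len(ref) == 0:
                continue
            ref = np.sort(ref)
            pos = grp["position_kb"].to_numpy()
            idx = np.searchsorted(ref, pos)
            left = np.abs(pos - ref[np.clip(idx - 1, 0, len(ref) - 1)])
            right = np.abs(pos - ref[np.clip(idx, 0, len(ref) - 1)])
            hits += int(np.sum(np.minimum(left, right) <= match_kb))
        return hits / len(self.second_early)


def generate_successive_sphases(
    genome: GenomeSpec,
    profile: KineticProfile,
    early_window: float = 3.0,
    refire_model: str = "independent",
    refire_prob: float = 1.0,
    seed: int = 0,
    time_step: float = 0.1,
) -> SuccessiveSPhases:
    """Early-firing origins of two simulated consecutive S-phases.

    Under ``independent`` the second S-phase is a fresh simulation; under
    ``inherited`` each first-round early origin re-fires early in the second
    round with probability ``refire_prob`` and the remainder are drawn fresh.
    """
    if early_window <= 0:
        raise ValueError("early_window must be positive")
    if refire_model not in ("independent", "inherited"):
        raise ValueError("refire_model must be 'independent' or 'inherited'")
    rng = np.random.default_rng(seed)
    s1, s2 = int(rng.integers(2**31 - 1)), int(rng.integers(2**31 - 1))

    def early(sim):
        rows = [
            (e.chromosome, e.position_kb, e.time_min)
            for e in sim.events
            if e.time_min < early_window
        ]
        return pd.DataFrame(rows, columns=["chromosome", "position_kb", "time_min"])

    first = early(simulate_genome_sphase(genome, profile, s1, time_step))
    fresh = early(simulate_genome_sphase(genome, profile, s2, time_step))
    if refire_model == "independent":
        return SuccessiveSPhases(first, fresh, refire_model, None)
    keep = rng.random(len(first)) < refire_prob
    inherited = first.loc[keep].reset_index(drop=True)
    n_extra = int(round((1.0 - refire_prob) * len(first)))
    extra = fresh.iloc[:n_extra].reset_index(drop=True)
    second = pd.concat([inherited, extra], ignore_index=True)
    mask = np.concatenate([np.ones(len(inherited), bool), np.zeros(len(extra), bool)])
    return SuccessiveSPhases(first, second, refire_model, mask)
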