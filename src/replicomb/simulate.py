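"""Stochastic whole-genome S-phase simulator.

The model is one-dimensional nucleation-and-growth (KJMA): origins fire at a
rate ``r(f)`` expressed per minute per Mb of *unreplicated* DNA, are placed
uniformly on unreplicated territory (no phantom origins), and send out two
forks moving at a constant velocity ``v`` that annihilate pairwise when they
meet.  For a constant rate ``I`` per kb per min the replicated fraction
follows the closed form ``f(t) = 1 - exp(-I v t^2)``, which the simulator is
tested against.

The replication-timing map follows from the event list alone: because forks
move at constant speed and annihilate on meeting, position ``x`` is
replicated at ``T(x) = min_i (t_i + |x - x_i| / v)`` over the origins fired
on its chromosome, provided no origin ever fires in replicated territory
(which the simulation guarantees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .molecule import Molecule, Track


@dataclass(frozen=True)
class KineticProfile:
    """Firing-rate and fork-speed parameters of S-phase.

    The firing rate ramps linearly from ``r0`` at ``f = 0`` to ``r_mid`` at
    ``f = f_knee`` and stays constant afterwards, in origins per minute per
    Mb of unreplicated DNA (defaults 2 -> 8 over the first half of S-phase).
    ``v_kb_min`` is the fork velocity (default 2.8 kb/min); ``chase_min`` is
    the default chase duration of the pulse/chase labeling (3 min).
    """

    r0: float = 2.0
    r_mid: float = 8.0
    f_knee: float = 0.5
    v_kb_min: float = 2.8
    pulse_min: Optional[float] = None
    chase_min: float = 3.0

    def __post_init__(self):
        if self.v_kb_min <= 0:
            raise ValueError("fork velocity must be positive")
        if not (0 < self.f_knee <= 1):
            raise ValueError("f_knee must be in (0, 1]")
        if self.chase_min < 0 or (self.pulse_min is not None and self.pulse_min < 0):
            raise ValueError("durations must be non-negative")
        f = np.linspace(0, 1, 101)
        if np.any(self.rate(f) < 0):
            raise ValueError("firing rate must be non-negative on [0, 1]")

    def rate(self, f):
        """Firing rate r(f) in origins / min / Mb unreplicated."""
        f = np.asarray(f, dtype=float)
        ramp = self.r0 + (self.r_mid - self.r0) * np.minimum(f, self.f_knee) / self.f_knee
        return ramp if ramp.ndim else float(ramp)


def constant_rate_profile(rate_per_kb_min: float, v_kb_min: float = 2.8,
                          chase_min: float = 3.0) -> KineticProfile:
    """A flat r(f), specified per kb (converted to the per-Mb convention)."""
    r = rate_per_kb_min * 1000.0
    return KineticProfile(r0=r, r_mid=r, f_knee=0.5, v_kb_min=v_kb_min,
                          chase_min=chase_min)


@dataclass(frozen=True)
class FiringEvent:
    chromosome: str
    position_kb: float
    time_min: float


@dataclass
class TimingMap:
    """Replication time on a regular grid per chromosome.

    ``times[name][i]`` is the replication time (min) of the grid cell
    centred at ``(i + 1/2) * resolution_kb``.
    """

    genome: GenomeSpec
    resolution_kb: float
    times: Dict[str, np.ndarray]

    @property
    def duration_min(self) -> float:
        return max(
            (float(np.max(t[np.isfinite(t)])) if np.any(np.isfinite(t)) else 0.0)
            for t in self.times.values()
        )

    def fraction_at(self, t: float) -> float:
        done = sum(int(np.sum(tm <= t)) for tm in self.times.values())
        total = sum(len(tm) for tm in self.times.values())
        return done / total


@dataclass
class SPhaseSimulation:
    """Complete record of one simulated S-phase."""

    genome: GenomeSpec
    profile: KineticProfile
    time_step_min: float
    seed: int
    events: List[FiringEvent]
    trajectory: pd.DataFrame  # time_min, f, active_forks, cum_origins
    duration_min: float

    def timing_map(self, resolution_kb: float = 2.0) -> TimingMap:
        """Replication-timing map from the first-arrival formula."""
        v = self.profile.v_kb_min
        times: Dict[str, np.ndarray] = {}
        for name, L in self.genome.items():
            centers = (np.arange(int(round(L / resolution_kb))) + 0.5) * resolution_kb
            ev = [(e.position_kb, e.time_min) for e in self.events
                  if e.chromosome == name]
            if not ev:
                times[name] = np.full(centers.shape, np.inf)
                continue
            pos = np.array([p for p, _ in ev])
            t0 = np.array([t for _, t in ev])
            # min over events of t_i + |x - x_i| / v, chunked over events
            T = np.full(centers.shape, np.inf)
            for k in range(0, len(pos), 256):
                cand = t0[k:k + 256, None] + np.abs(centers[None, :] -
                                                    pos[k:k + 256, None]) / v
                T = np.minimum(T, cand.min(axis=0))
            times[name] = T
        return TimingMap(self.genome, resolution_kb, times)


def simulate_genome_sphase(
    genome: GenomeSpec,
    profile: KineticProfile,
    seed: int,
    time_step: float = 0.1,
    max_time: float = 10000.0,
) -> SPhaseSimulation:
    """Simulate one S-phase over the whole genome.

    Per step of ``time_step`` minutes, the number of new origins is a Poisson
    draw with mean ``r(f) * (unreplicated Mb) * dt``; their positions are
    uniform on the unreplicated gaps.  Forks advance ``v * dt`` bidirectionally
    and annihilate pairwise on meeting.  With any positive rate, ``f`` is
    non-decreasing and reaches 1 in finite time.
    """
    if time_step <= 0:
        raise ValueError("time_step must be positive")
    rng = np.random.default_rng(seed)
    v = profile.v_kb_min
    total = genome.total_kb

    # Unreplicated gaps: per chromosome, list of [left, right, lmov, rmov]
    # where lmov/rmov flag whether that boundary is a fork (moves inward).
    holes = {name: [[0.0, L, False, False]] for name, L in genome.items()}
    events: List[FiringEvent] = []
    rows = []
    t = 0.0
    while t <= max_time:
        U = sum(h[1] - h[0] for hs in holes.values() for h in hs)
        f = 1.0 - U / total
        n_forks = sum(h[2] + h[3] for hs in holes.values() for h in hs)
        rows.append((t, f, n_forks, len(events)))
        if U <= 0:
            break
        lam = float(profile.rate(f)) * (U / 1000.0) * time_step
        if lam <= 0 and n_forks == 0:
            break  # nothing can ever happen (zero rate, no forks)
        n_new = rng.poisson(lam) if lam > 0 else 0
        if n_new:
            flat = [(name, i, h[1] - h[0])
                    for name, hs in holes.items() for i, h in enumerate(hs)]
            lengths = np.array([w for _, _, w in flat])
            edges = np.concatenate([[0.0], np.cumsum(lengths)])
            # uniform over unreplicated territory; process left to right per
            # hole so that splits stay consistent within the step
            u = np.sort(rng.uniform(0.0, edges[-1], size=n_new))
            idx = np.searchsorted(edges, u, side="right") - 1
            for j, ui in zip(idx[::-1], u[::-1]):  # right-to-left: stable indices
                name, i, _ = flat[j]
                h = holes[name][i]
                x = h[0] + (ui - edges[j])
                if not (h[0] < x < h[1]):
                    continue  # boundary draw at grid edge; negligible measure
                events.append(FiringEvent(name, float(x), t))
                holes[name][i:i + 1] = [
                    [h[0], x, h[2], True],
                    [x, h[1], True, h[3]],
                ]

        for hs in holes.values():
            for h in hs:
                if h[2]:
                    h[0] += v * time_step
                if h[3]:
                    h[1] -= v * time_step
            hs[:] = [h for h in hs if h[1] - h[0] > 1e-12]
        t += time_step
    else:
        raise RuntimeError("simulation did not complete within max_time")

    traj = pd.DataFrame(rows, columns=["time_min", "f", "active_forks",
                                       "cum_origins"])
    return SPhaseSimulation(genome, profile, time_step, seed, events, traj,
                            duration_min=float(traj["time_min"].iloc[-1]))


def label_pulse_chase(
    timing: TimingMap,
    t0: float,
    pulse: float,
    chase: float,
    noise: "CombingNoise | None" = None,
) -> List[Molecule]:
    """Label the timing map with a BrdU pulse followed by an EdU chase.

    Grid cells replicated during ``[t0, t0 + pulse)`` become BrdU; cells
    replicated during ``[t0 + pulse, t0 + pulse + chase)`` become EdU;
    anything replicated before ``t0`` or still unreplicated at the end of the
    chase is unlabeled.  Maximal labeled runs become tracks and tracks
    shorter than the detection minimum are dropped.  Returns one whole
    chromosome per molecule (apply :func:`replicomb.noise.fragment_and_stretch`
    for combed fragments).
    """
    from .noise import CombingNoise  # local import to avoid a cycle

    if pulse < 0 or chase < 0:
        raise ValueError("pulse and chase must be non-negative")
    if t0 < 0 or t0 > timing.duration_min:
        raise ValueError("t0 outside the simulated S-phase")
    noise = noise or CombingNoise()
    res = timing.resolution_kb
    molecules = []
    for name, L in timing.genome.items():
        T = timing.times[name]
        label = np.zeros(T.shape, dtype=np.int8)
        label[(T >= t0) & (T < t0 + pulse)] = 1  # BrdU
        label[(T >= t0 + pulse) & (T < t0 + pulse + chase)] = 2  # EdU
        tracks = []
        for code, channel in ((1, "BrdU"), (2, "EdU")):
            mask = label == code
            if not mask.any():
                continue
            d = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
            starts = np.flatnonzero(d == 1) * res
            ends = np.flatnonzero(d == -1) * res
            for a, b in zip(starts, ends):
                if b - a >= noise.min_track_kb - 1e-9:
                    tracks.append(Track(float(a), float(b), channel))
        molecules.append(Molecule(f"chr{name}", float(len(T) * res), tracks,
                                  chromosome=name, offset_kb=0.0,
                                  orientation="+"))
    return molecules
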