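"""Per-molecule primary measurements.

Origin calls are placed at the midpoints of labeled tracks; adjacent-midpoint
distances are the inter-origin distances (IODs).  The measurement filters of
the single-molecule analysis are applied here: IODs are eligible only when
both flanking tracks are shorter than 20 kb and the molecule is less than 50%
replicated (strict inequalities), and molecule-end intervals are censored and
never counted as IODs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .molecule import CHANNELS, Molecule, Track, merge_intervals

EXTENT_EDGES = (0.05, 0.20, 0.50)
EXTENT_LABELS = ("0-5%", "5-20%", "20-50%", ">50%")


@dataclass(frozen=True)
class OriginCall:
    """A putative origin at the midpoint of a (merged) labeled block."""

    molecule_id: str
    position_kb: float
    track_length_kb: float


@dataclass(frozen=True)
class IODRecord:
    molecule_id: str
    left_kb: float
    right_kb: float
    distance_kb: float
    left_track_kb: float
    right_track_kb: float
    molecule_fraction: float
    eligible: bool
    extent_bin: str


def call_origins(
    molecule: Molecule, channels: Iterable = CHANNELS
) -> List[OriginCall]:
    """One origin call per contiguous labeled block.

    For pulse/chase molecules a contiguous BrdU+EdU block counts as a single
    track (one origin) unless the segments are separated by unlabeled DNA.
    The call sits at the block midpoint.
    """
    blocks = molecule.labeled_intervals(channels)
    return [
        OriginCall(molecule.molecule_id, 0.5 * (a + b), b - a) for a, b in blocks
    ]


def replication_fraction(molecule: Molecule) -> float:
    """Labeled length over molecule length, overlaps counted once."""
    return molecule.replicated_fraction


def bin_by_extent(
    fraction: float, edges: Sequence[float] = EXTENT_EDGES
) -> str:
    """Replication-extent bin label; bins are closed on the right.

    A molecule exactly 5% replicated falls in the 0-5% bin; molecules over
    the last edge (default 50%) are tagged ``'>50%'`` and excluded from IOD
    statistics downstream.
    """
    labels = EXTENT_LABELS if tuple(edges) == EXTENT_EDGES else None
    prev = 0.0
    for k, e in enumerate(edges):
        if fraction <= e:
            return labels[k] if labels else f"{prev:g}-{e:g}"
        prev = e
    return labels[-1] if labels else f">{edges[-1]:g}"


def measure_iods(
    molecules: Iterable[Molecule],
    max_track_kb: float = 20.0,
    max_fraction: float = 0.5,
    channels: Iterable = CHANNELS,
) -> List[IODRecord]:
    """Adjacent-midpoint distances with the eligibility filters.

    Intervals from a molecule end to the first or last origin are censored
    and never produce records.  A record is eligible only if the molecule is
    strictly less than ``max_fraction`` replicated and *both* flanking tracks
    are strictly shorter than ``max_track_kb``.
    """
    out: List[IODRecord] = []
    for mol in molecules:
        calls = call_origins(mol, channels)
        if len(calls) < 2:
            continue
        frac = mol.replicated_fraction
        binlab = bin_by_extent(frac)
        for left, right in zip(calls[:-1], calls[1:]):
            eligible = (
                frac < max_fraction
                and left.track_length_kb < max_track_kb
                and right.track_length_kb < max_track_kb
            )
            out.append(
                IODRecord(
                    mol.molecule_id,
                    left.position_kb,
                    right.position_kb,
                    right.position_kb - left.position_kb,
                    left.track_length_kb,
                    right.track_length_kb,
                    frac,
                    eligible,
                    binlab,
                )
            )
    return out


def eligible_distances(records: Iterable[IODRecord]) -> np.ndarray:
    return np.array([r.distance_kb for r in records if r.eligible], dtype=float)


def iods_to_frame(records: Iterable[IODRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _coverage_cum(molecule: Molecule, channels: Iterable = CHANNELS):
    """Breakpoints and cumulative labeled length, for window integrals."""
    ivs = molecule.labeled_intervals(channels)
    xs = [0.0]
    cum = [0.0]
    for a, b in ivs:
        xs.extend([a, b])
        cum.extend([cum[-1], cum[-1] + (b - a)])
    xs.append(molecule.length_kb)
    cum.append(cum[-1])
    return np.array(xs), np.array(cum)


def moving_average_profile(
    molecule: Molecule,
    window_kb: float = 200.0,
    step_kb: float = 2.0,
    channels: Iterable = CHANNELS,
) -> pd.DataFrame:
    """Replicated fraction in a sliding window along the molecule.

    Returns a frame with window ``center_kb`` and the labeled ``fraction``
    within the window; the window slides in ``step_kb`` steps (default 200-kb
    window in 2-kb steps, the combing resolution).
    """
    if window_kb > molecule.length_kb:
        raise ValueError("window larger than molecule")
    if window_kb <= 0 or step_kb <= 0:
        raise ValueError("window and step must be positive")
    xs, cum = _coverage_cum(molecule, channels)
    centers = np.arange(
        window_kb / 2, molecule.length_kb - window_kb / 2 + 1e-9, step_kb
    )
    lo = np.interp(centers - window_kb / 2, xs, cum)
    hi = np.interp(centers + window_kb / 2, xs, cum)
    return pd.DataFrame(
        {"center_kb": centers, "fraction": (hi - lo) / window_kb}
    )


def count_fork_ends(molecule: Molecule, channels: Iterable = CHANNELS) -> int:
    """Track ends not truncated by the molecule ends (two per internal track)."""
    n = 0
    eps = 1e-9
    for a, b in molecule.labeled_intervals(channels):
        n += int(a > eps) + int(b < molecule.length_kb - eps)
    return n


def cut_in_silico(
    molecules: Iterable[Molecule], piece_kb: float = 500.0
) -> List[Molecule]:
    """Partition molecules into consecutive pieces of ``piece_kb``.

    Tracks are split at the piece boundaries, so IODs spanning a boundary are
    lost at the piece level — emulating the analysis of short combed
    molecules.  A shorter terminal remainder piece is kept.
    """
    if piece_kb <= 0:
        raise ValueError("piece_kb must be positive")
    out: List[Molecule] = []
    for mol in molecules:
        n_pieces = int(np.ceil(mol.length_kb / piece_kb - 1e-9))
        for k in range(n_pieces):
            lo = k * piece_kb
            hi = min((k + 1) * piece_kb, mol.length_kb)
            tracks = []
            for t in mol.tracks:
                a, b = max(t.start_kb, lo), min(t.end_kb, hi)
                if b - a > 1e-9:
                    tracks.append(Track(a - lo, b - lo, t.channel))
            out.append(
                Molecule(
                    f"{mol.molecule_id}#{k}",
                    hi - lo,
                    tracks,
                    mol.chromosome,
                    None if mol.offset_kb is None else mol.offset_kb + lo,
                    mol.orientation,
                )
            )
    return out
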