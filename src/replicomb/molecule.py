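"""Core data model: labeled tracks on combed single DNA molecules.

Coordinates are kb, 0-based, half-open ``[start, end)``.  Two label channels
exist: ``BrdU`` (pulse) and ``EdU`` (chase); single-label experiments use
``BrdU`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional

import numpy as np

CHANNELS = ("BrdU", "EdU")


@dataclass(frozen=True)
class Track:
    """A maximal labeled segment on a molecule."""

    start_kb: float
    end_kb: float
    channel: str = "BrdU"

    def __post_init__(self):
        if not (0 <= self.start_kb < self.end_kb):
            raise ValueError(
                f"invalid track [{self.start_kb}, {self.end_kb}): need 0 <= start < end"
            )
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def length_kb(self) -> float:
        return self.end_kb - self.start_kb

    @property
    def midpoint_kb(self) -> float:
        return 0.5 * (self.start_kb + self.end_kb)


def merge_intervals(intervals: Iterable) -> List:
    """Union of ``(start, end)`` intervals; touching intervals are merged."""
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out: List = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def union_length(intervals: Iterable) -> float:
    return sum(b - a for a, b in merge_intervals(intervals))


@dataclass
class Molecule:
    """A combed DNA fragment carrying labeled replication tracks.

    Parameters
    ----------
    molecule_id : str
        Unique identifier.
    length_kb : float
        Physical length of the molecule.
    tracks : list of Track
        Labeled segments; same-channel tracks must be non-overlapping.
    chromosome, offset_kb, orientation :
        Optional genomic placement (chromosome name, chromosomal coordinate
        of molecule position 0, and '+'/'-' strand of the molecule frame).
    """

    molecule_id: str
    length_kb: float
    tracks: List[Track] = field(default_factory=list)
    chromosome: Optional[str] = None
    offset_kb: Optional[float] = None
    orientation: Optional[str] = None

    def __post_init__(self):
        if self.length_kb <= 0:
            raise ValueError(f"molecule {self.molecule_id}: non-positive length")
        self.tracks = sorted(self.tracks, key=lambda t: (t.start_kb, t.channel))
        self.validate()

    def validate(self) -> None:
        prev_end = {}
        for t in self.tracks:
            if t.start_kb < 0 or t.end_kb > self.length_kb + 1e-9:
                raise ValueError(
                    f"molecule {self.molecule_id}: track [{t.start_kb}, {t.end_kb}) "
                    f"outside molecule of length {self.length_kb}"
                )
            if t.channel in prev_end and t.start_kb < prev_end[t.channel] - 1e-9:
                raise ValueError(
                    f"molecule {self.molecule_id}: overlapping {t.channel} tracks "
                    f"near {t.start_kb} kb"
                )
            prev_end[t.channel] = t.end_kb

    def tracks_in(self, channels: Iterable = CHANNELS) -> List[Track]:
        chans = set(channels)
        return [t for t in self.tracks if t.channel in chans]

    def labeled_intervals(self, channels: Iterable = CHANNELS) -> List:
        """Union of labeled intervals over the requested channels."""
        return merge_intervals(
            (t.start_kb, t.end_kb) for t in self.tracks_in(channels)
        )

    @property
    def replicated_fraction(self) -> float:
        """Labeled proportion of the molecule (overlaps counted once)."""
        return union_length((t.start_kb, t.end_kb) for t in self.tracks) / self.length_kb

    def flipped(self) -> "Molecule":
        """The same molecule read end-for-end."""
        L = self.length_kb
        tracks = [
            Track(L - t.end_kb, L - t.start_kb, t.channel) for t in self.tracks
        ]
        orient = {"+": "-", "-": "+"}.get(self.orientation, self.orientation)
        return Molecule(
            self.molecule_id, L, tracks, self.chromosome, self.offset_kb, orient
        )


@dataclass(frozen=True)
class ProbeSignature:
    """A FISH landmark: two probes of distinct lengths separated by a gap.

    The pair of probe lengths and the gap between them form a signature that
    identifies a chromosomal position in either reading direction.
    """

    signature_id: str
    chromosome: str
    position_kb: float  # chromosomal coordinate of the start of probe 1
    probe1_kb: float
    gap_kb: float
    probe2_kb: float

    def __post_init__(self):
        if self.probe1_kb <= 0 or self.probe2_kb <= 0:
            raise ValueError("probe lengths must be positive")
        if self.gap_kb < 0:
            raise ValueError("gap must be non-negative")

    @property
    def triple(self):
        return (self.probe1_kb, self.gap_kb, self.probe2_kb)

    @property
    def reversed_triple(self):
        return (self.probe2_kb, self.gap_kb, self.probe1_kb)

    @property
    def span_kb(self) -> float:
        return self.probe1_kb + self.gap_kb + self.probe2_kb
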