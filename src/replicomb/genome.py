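"""Genome description for the fission-yeast-like three-chromosome genome."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """A genome as a set of named linear chromosomes.

    Defaults describe the 13.6-Mb fission yeast genome: three chromosomes of
    5.6, 4.5 and 3.5 Mb.

    Attributes
    ----------
    names : tuple of str
        Chromosome names.
    lengths_kb : tuple of float
        Chromosome lengths in kb, matching ``names``.
    """

    names: tuple = ("I", "II", "III")
    lengths_kb: tuple = (5600.0, 4500.0, 3500.0)

    def __post_init__(self):
        if len(self.names) != len(self.lengths_kb):
            raise ValueError("names and lengths_kb must have equal length")
        if len(self.names) == 0:
            raise ValueError("genome needs at least one chromosome")
        if any(l <= 0 for l in self.lengths_kb):
            raise ValueError("chromosome lengths must be positive")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")

    @property
    def total_kb(self) -> float:
        """Total genome length in kb (13600 for the default genome)."""
        return float(sum(self.lengths_kb))

    def length_of(self, name: str) -> float:
        return float(self.lengths_kb[self.names.index(name)])

    def items(self):
        return zip(self.names, self.lengths_kb)
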