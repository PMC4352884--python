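"""Reading and writing single-molecule track tables, and FISH-probe alignment.

The molecule-track dialect is a TSV with header
``molecule_id  mol_length_kb  track_start_kb  track_end_kb  channel`` and one
row per track.  A molecule without tracks is represented by a single row with
empty track fields, so that round-tripping preserves the molecule set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .molecule import CHANNELS, Molecule, ProbeSignature, Track

MOLECULE_COLUMNS = [
    "molecule_id",
    "mol_length_kb",
    "track_start_kb",
    "track_end_kb",
    "channel",
]


class MoleculeTableError(ValueError):
    """Raised when a molecule table contains invalid rows; lists offenders."""


def _is_blank(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x == ""


def read_molecules(path, dialect: str = "tsv") -> List[Molecule]:
    """Read a molecule-track table, validating every row.

    Malformed rows (track outside molecule, overlapping same-channel tracks,
    unknown channel) are reported together with their line numbers in a
    single :class:`MoleculeTableError`.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"molecule_id": str, "channel": str})
    missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise MoleculeTableError(f"{path}: missing columns {missing}")

    errors: List[str] = []
    by_mol: dict = {}
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        mid = row["molecule_id"]
        length = row["mol_length_kb"]
        rec = by_mol.setdefault(mid, {"length": float(length), "tracks": []})
        if float(length) != rec["length"]:
            errors.append(f"line {line}: inconsistent length for molecule {mid}")
            continue
        if _is_blank(row["track_start_kb"]) and _is_blank(row["track_end_kb"]):
            continue  # track-less molecule row
        try:
            track = Track(
                float(row["track_start_kb"]),
                float(row["track_end_kb"]),
                str(row["channel"]),
            )
            if track.end_kb > rec["length"] + 1e-9 or track.start_kb < 0:
                raise ValueError(
                    f"track [{track.start_kb}, {track.end_kb}) outside molecule "
                    f"of length {rec['length']}"
                )
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        rec["tracks"].append(track)

    molecules = []
    for mid, rec in by_mol.items():
        try:
            molecules.append(Molecule(str(mid), rec["length"], rec["tracks"]))
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise MoleculeTableError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return molecules


def write_molecules(molecules: Sequence[Molecule], path) -> None:
    """Write molecules in the track-table dialect (0.1-kb precision)."""
    rows = []
    for m in sorted(molecules, key=lambda m: m.molecule_id):
        if not m.tracks:
            rows.append((m.molecule_id, round(m.length_kb, 1), "", "", ""))
        for t in m.tracks:
            rows.append(
                (
                    m.molecule_id,
                    round(m.length_kb, 1),
                    round(t.start_kb, 1),
                    round(t.end_kb, 1),
                    t.channel,
                )
            )
    pd.DataFrame(rows, columns=MOLECULE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_signatures(path) -> List[ProbeSignature]:
    """Read a BED-like probe table (chrom, start, end, probe_id, pair_id).

    Each ``pair_id`` must occur exactly twice; the two probes of a pair are
    combined into one :class:`ProbeSignature`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start_kb", "end_kb", "probe_id", "pair_id"],
        comment="#",
    )
    sigs = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"pair {pair_id}: expected 2 probes, got {len(grp)}")
        grp = grp.sort_values("start_kb")
        (c1, s1, e1), (c2, s2, e2) = grp[["chrom", "start_kb", "end_kb"]].itertuples(
            index=False
        )
        if c1 != c2:
            raise ValueError(f"pair {pair_id}: probes on different chromosomes")
        if s2 < e1:
            raise ValueError(f"pair {pair_id}: overlapping probes")
        sigs.append(
            ProbeSignature(str(pair_id), str(c1), float(s1), e1 - s1, s2 - e1, e2 - s2)
        )
    return sigs


def read_regions(path) -> pd.DataFrame:
    """Read a BED-like region annotation (chrom, start_kb, end_kb, name)."""
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start_kb", "end_kb", "name"], comment="#"
    )


@dataclass(frozen=True)
class AlignmentResult:
    status: str  # "unique", "none", or "ambiguous"
    chromosome: Optional[str] = None
    offset_kb: Optional[float] = None
    orientation: Optional[str] = None
    signature_id: Optional[str] = None
    candidates: Tuple = ()


def _rel_err(observed, expected) -> float:
    return max(
        abs(o - e) / e if e > 0 else (0.0 if o == 0 else math.inf)
        for o, e in zip(observed, expected)
    )


def align_by_probes(
    molecule: Molecule,
    detected_probes: Sequence[Tuple[float, float]],
    library: Sequence[ProbeSignature],
    tolerance: float = 0.12,
) -> AlignmentResult:
    """Assign genomic coordinates to a molecule from detected FISH probes.

    The consecutive probe intervals detected on the molecule are summarised
    as (length1, gap, length2) triples and matched against the signature
    library in both reading directions, allowing a relative error of at most
    ``tolerance`` on each of the three measurements (default 0.12, roughly
    twice the combing stretch CV).  A unique best match assigns chromosome,
    offset and orientation; a reversed match means the molecule was combed
    end-for-end, so its frame is flipped.

    Returns an :class:`AlignmentResult` with status ``"none"`` when nothing
    matches and ``"ambiguous"`` (no assignment) when two or more library
    signatures match within tolerance.
    """
    if len(detected_probes) < 2:
        raise ValueError("need at least two detected probe intervals")
    probes = sorted((float(a), float(b)) for a, b in detected_probes)

    matches = []
    for i in range(len(probes) - 1):
        (s1, e1), (s2, e2) = probes[i], probes[i + 1]
        obs = (e1 - s1, s2 - e1, e2 - s2)
        for sig in library:
            for orient, expected in (("+", sig.triple), ("-", sig.reversed_triple)):
                err = _rel_err(obs, expected)
                if err <= tolerance:
                    if orient == "+":
                        # molecule coordinate s1 sits at chromosomal position_kb
                        offset = sig.position_kb - s1
                    else:
                        # flipped frame: chromosomal(x) = offset - x, with the
                        # detected second probe's *end* mapping to position_kb
                        offset = sig.position_kb + e2
                    matches.append((err, sig, orient, offset))

    if not matches:
        return AlignmentResult("none")
    # one signature may match several probe pairs; keep the best per signature
    best: dict = {}
    for err, sig, orient, offset in matches:
        key = sig.signature_id
        if key not in best or err < best[key][0]:
            best[key] = (err, sig, orient, offset)
    if len(best) > 1:
        return AlignmentResult(
            "ambiguous", candidates=tuple(sorted(best.keys()))
        )
    err, sig, orient, offset = next(iter(best.values()))
    return AlignmentResult("unique", sig.chromosome, offset, orient, sig.signature_id)


def apply_alignment(molecule: Molecule, result: AlignmentResult) -> Molecule:
    """Return a copy of the molecule carrying the alignment assignment.

    For a reversed match the molecule is flipped end-for-end so that its
    local coordinates increase with chromosomal position, and the stored
    offset refers to the flipped frame.
    """
    if result.status != "unique":
        raise ValueError(f"cannot apply alignment with status {result.status!r}")
    if result.orientation == "-":
        flipped = molecule.flipped()
        flipped.chromosome = result.chromosome
        flipped.offset_kb = result.offset_kb - molecule.length_kb
        flipped.orientation = "-"
        return flipped
    out = Molecule(
        molecule.molecule_id,
        molecule.length_kb,
        list(molecule.tracks),
        result.chromosome,
        result.offset_kb,
        "+",
    )
    return out
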