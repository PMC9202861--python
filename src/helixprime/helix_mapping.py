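"""Alignment-based residue mapping onto the GFP reference numbering.

The central α-helix of avGFP-like proteins is defined by residues 60-74 of
the S65T GFP crystal structure (1EMA). Every target sequence is related to
that window through a multiple sequence alignment containing the reference;
this module converts alignment columns into per-target residue numbers and
runs the sequence-level check for the chromophore-forming residue triad
(cyclizing glycine, aromatic at 66, catalytic arginine 96).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import AlignIO

__all__ = [
    "Alignment",
    "ResidueMap",
    "TriadReport",
    "MappingError",
    "read_alignment",
    "map_reference_window",
    "triad_check",
    "DEFAULT_WINDOW",
    "DEFAULT_TRIAD_POSITIONS",
    "AROMATIC_RESIDUES",
]

#: Reference positions of the central helix window (1EMA author numbering).
DEFAULT_WINDOW = tuple(range(60, 75))

#: Chromophore triad, GFP numbering. The cyclizing glycine is position 67
#: (the triad is 65-T/S, 66-Y, 67-G); see triad_check for the rationale.
DEFAULT_TRIAD_POSITIONS = {"triad_gly": 67, "aromatic": 66, "arg": 96}

#: Residues accepted as "aromatic at position 66". Histidine is included:
#: it is aromatic and supports chromophore formation (blue variants).
AROMATIC_RESIDUES = frozenset("FYWH")

GAP_CHARS = frozenset("-.")


class MappingError(ValueError):
    """Raised for malformed alignments or unmappable windows."""


@dataclass
class Alignment:
    """Equal-length gapped sequences with a designated reference record."""

    records: dict[str, str]  # id -> gapped sequence (preserves file order)
    reference_id: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise MappingError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        if self.reference_id not in self.records:
            raise MappingError(
                f"reference id {self.reference_id!r} not among alignment records"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))


@dataclass
class ResidueMap:
    """Reference-window correspondence for one target."""

    target_id: str
    #: (reference_position, target_residue_number) pairs, both increasing.
    window: list[tuple[int, int]]
    #: triad/catalytic anchors; absent where the target is gapped.
    anchors: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        refs = [p for p, _ in self.window]
        tgts = [t for _, t in self.window]
        if refs != sorted(refs) or len(set(refs)) != len(refs):
            raise MappingError("reference positions must be strictly increasing")
        if tgts != sorted(tgts) or len(set(tgts)) != len(tgts):
            raise MappingError("target residue numbers must be strictly increasing")
        if len(self.window) > 15:
            raise MappingError("window exceeds 15 residues")

    @property
    def reference_positions(self) -> list[int]:
        return [p for p, _ in self.window]

    @property
    def target_numbers(self) -> list[int]:
        return [t for _, t in self.window]


@dataclass
class TriadReport:
    """Sequence-level verdict on chromophore-forming capability."""

    target_id: str
    gly_at_triad_gly: bool
    aromatic_at_66: bool
    arg_at_96: bool
    detail: dict[str, str]

    @property
    def verdict(self) -> str:
        ok = self.gly_at_triad_gly and self.aromatic_at_66 and self.arg_at_96
        return "can_form" if ok else "cannot_form"


def read_alignment(path: str | Path, reference_id: str) -> Alignment:
    """Read a FASTA or Clustal multiple alignment and locate the reference.

    Format is sniffed from the first non-blank line ('>' means FASTA).
    Duplicate ids, ragged rows and a missing reference are all errors.
    """
    path = Path(path)
    if not path.exists():
        raise MappingError(f"no such alignment file: {path}")
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    fmt = "fasta" if first.startswith(">") else "clustal"
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise MappingError(f"cannot parse {path} as {fmt} alignment: {exc}") from exc
    records: dict[str, str] = {}
    for rec in msa:
        if rec.id in records:
            raise MappingError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return Alignment(records=records, reference_id=reference_id)


def _column_of_reference_position(
    alignment: Alignment, position: int, reference_start: int
) -> int | None:
    """Alignment column (0-based) holding the given reference position."""
    seq = alignment.records[alignment.reference_id]
    count = reference_start - 1
    for col, ch in enumerate(seq):
        if ch not in GAP_CHARS:
            count += 1
            if count == position:
                return col
    return None


def _target_number_at_column(seq: str, col: int, target_start: int) -> int | None:
    if seq[col] in GAP_CHARS:
        return None
    non_gap = sum(1 for ch in seq[: col + 1] if ch not in GAP_CHARS)
    return target_start + non_gap - 1


def map_reference_window(
    alignment: Alignment,
    target_id: str,
    reference_start: int = 1,
    target_start: int = 1,
    window: tuple[int, ...] = DEFAULT_WINDOW,
    anchor_positions: tuple[int, ...] = (65, 66, 67, 96),
    strict: bool = True,
) -> ResidueMap:
    """Map reference helix-window positions onto a target's residue numbers.

    ``reference_start`` is the residue number of the reference's first
    non-gap character, converting alignment columns to author numbering;
    ``target_start`` plays the same role for the target (default 1).

    In strict mode (default) a target gapped at any window column is an
    error, because superposition requires a complete equal-count atom
    pairing. Permissive mode keeps only the mapped positions.
    """
    if target_id not in alignment.records:
        raise MappingError(f"target id {target_id!r} not in alignment")
    target_seq = alignment.records[target_id]

    pairs: list[tuple[int, int]] = []
    missing: list[int] = []
    for pos in window:
        col = _column_of_reference_position(alignment, pos, reference_start)
        if col is None:
            missing.append(pos)
            continue
        num = _target_number_at_column(target_seq, col, target_start)
        if num is None:
            missing.append(pos)
        else:
            pairs.append((pos, num))
    if strict and missing:
        raise MappingError(
            f"{target_id}: window positions {missing} are gapped or absent "
            "(strict mapping requires the complete window)"
        )

    anchors: dict[int, int] = {}
    for pos in anchor_positions:
        col = _column_of_reference_position(alignment, pos, reference_start)
        if col is None:
            continue
        num = _target_number_at_column(target_seq, col, target_start)
        if num is not None:
            anchors[pos] = num
    return ResidueMap(target_id=target_id, window=pairs, anchors=anchors)


def triad_check(
    alignment: Alignment,
    target_id: str,
    reference_start: int = 1,
    positions: Mapping[str, int] = DEFAULT_TRIAD_POSITIONS,
    aromatic_residues: frozenset[str] = AROMATIC_RESIDUES,
) -> TriadReport:
    """Check the chromophore-forming residue requirements on the sequence.

    A chromophore needs a glycine as the cyclizing residue of the triad, an
    aromatic residue at position 66, and the catalytic arginine 96. The
    glycine position defaults to 67: the triad is 65-X, 66-aromatic, 67-Gly
    and it is residue 67 whose amide nitrogen attacks in cyclization. (GFP
    literature sometimes writes "Gly65" for the same residue because of
    alternative numbering conventions; the position is configurable.)

    A gap at a checked position fails that check rather than raising.
    """
    if target_id not in alignment.records:
        raise MappingError(f"target id {target_id!r} not in alignment")
    target_seq = alignment.records[target_id]

    observed: dict[str, str] = {}
    for name, pos in positions.items():
        col = _column_of_reference_position(alignment, pos, reference_start)
        observed[name] = "-" if col is None else target_seq[col]

    return TriadReport(
        target_id=target_id,
        gly_at_triad_gly=observed["triad_gly"] == "G",
        aromatic_at_66=observed["aromatic"] in aromatic_residues,
        arg_at_96=observed["arg"] == "R",
        detail=observed,
    )
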