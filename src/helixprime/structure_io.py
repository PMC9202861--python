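"""PDB reading/writing and backbone extraction.

All downstream geometry operates on :class:`BackboneSegment` objects: ordered
residue windows carrying the four non-hydrogen main-chain atoms N, CA, C, O.
Parsing is delegated to gemmi; this module enforces the atom contract the
geometry layer relies on (single conformer per atom, complete backbones,
chain continuity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "BackboneResidue",
    "BackboneSegment",
    "StructureError",
    "read_pdb",
    "write_pdb",
    "extract_backbone",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Plausible range for consecutive CA-CA distances (trans and cis peptides,
#: with headroom for coordinate noise); used as a chain-continuity check.
CA_CA_RANGE = (2.7, 4.3)


class StructureError(ValueError):
    """Raised for malformed or incomplete structural input."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom after alternate-location resolution."""

    atom_name: str
    residue_name: str
    chain_id: str
    residue_number: int
    position: np.ndarray  # shape (3,), Angstrom
    element: str = ""
    occupancy: float = 1.0
    insertion_code: str = ""
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(
                f"atom {self.atom_name} of {self.residue_name}"
                f"{self.residue_number}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(
                f"atom {self.atom_name}: occupancy {self.occupancy} outside [0, 1]"
            )

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """Ordered heavy-atom collection for one model of one protein."""

    id: str
    atoms: list[AtomRecord]
    model_number: int = 1

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for atom in self.atoms:
            key = (*atom.residue_key, atom.atom_name)
            if key in seen:
                raise StructureError(f"duplicate atom after altloc resolution: {key}")
            seen.add(key)

    def residue_numbers(self, chain_id: str | None = None) -> list[int]:
        out: list[int] = []
        for atom in self.atoms:
            if chain_id is not None and atom.chain_id != chain_id:
                continue
            if not out or out[-1] != atom.residue_number:
                if atom.residue_number not in out:
                    out.append(atom.residue_number)
        return out

    def atom(
        self, residue_number: int, atom_name: str, chain_id: str | None = None
    ) -> AtomRecord:
        """Look up a single atom; raises StructureError when absent."""
        for a in self.atoms:
            if (
                a.residue_number == residue_number
                and a.atom_name == atom_name
                and (chain_id is None or a.chain_id == chain_id)
            ):
                return a
        raise StructureError(
            f"{self.id}: atom {atom_name} of residue {residue_number} not found"
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every position mapped to R @ x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atoms = [
            AtomRecord(
                atom_name=a.atom_name,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                residue_number=a.residue_number,
                position=R @ a.position + t,
                element=a.element,
                occupancy=a.occupancy,
                insertion_code=a.insertion_code,
                altloc=a.altloc,
            )
            for a in self.atoms
        ]
        return Structure(id=self.id, atoms=atoms, model_number=self.model_number)


@dataclass(frozen=True)
class BackboneResidue:
    """Backbone heavy atoms of one residue inside the helix window."""

    residue_number: int
    residue_name: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    reference_position: int | None = None

    def atom_coords(self) -> np.ndarray:
        return np.vstack([self.n, self.ca, self.c, self.o])


@dataclass
class BackboneSegment:
    """Ordered residue window; the unit of all geometric measurements."""

    residues: list[BackboneResidue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def reference_positions(self) -> list[int | None]:
        return [r.reference_position for r in self.residues]

    def coords(self) -> np.ndarray:
        """(4n, 3) array, atoms ordered N, CA, C, O within each residue."""
        return np.vstack([r.atom_coords() for r in self.residues])

    def ca_coords(self) -> np.ndarray:
        return np.vstack([r.ca for r in self.residues])

    def subset(self, reference_positions: Iterable[int]) -> "BackboneSegment":
        """Restrict to the given reference positions (order preserved)."""
        wanted = set(reference_positions)
        picked = [r for r in self.residues if r.reference_position in wanted]
        missing = wanted - {r.reference_position for r in picked}
        if missing:
            raise StructureError(
                f"segment lacks reference positions {sorted(missing)}"
            )
        return BackboneSegment(picked)

    def check_continuity(self) -> None:
        ca = self.ca_coords()
        gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        lo, hi = CA_CA_RANGE
        bad = [
            (self.residues[i].residue_number, float(d))
            for i, d in enumerate(gaps)
            if not (lo <= d <= hi)
        ]
        if bad:
            raise StructureError(
                "chain continuity violated (CA-CA distance outside "
                f"[{lo}, {hi}] A) after residues {bad}"
            )


def _resolve_altlocs(group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by lexicographically lowest altloc
    return sorted(group, key=lambda a: (-a.occ, a.altloc or ""))[0]


def read_pdb(
    path: str | Path,
    model_number: int = 1,
    chain_id: str | None = None,
    structure_id: str | None = None,
) -> Structure:
    """Read one model (optionally one chain) of a PDB file into a Structure.

    Hydrogens, HETATM records and waters are dropped; alternate locations are
    resolved by keeping the highest-occupancy conformer (ties: lowest altloc
    label). Gzip-compressed files are accepted transparently.

    Raises
    ------
    StructureError
        If the file is unreadable, the requested model or chain is absent, or
        no ATOM records survive filtering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    model = None
    for m in st:
        if m.num == model_number:
            model = m
            break
    if model is None:
        raise StructureError(
            f"{path}: model {model_number} not present "
            f"(models: {[m.num for m in st]})"
        )

    chains = [c for c in model if chain_id is None or c.name == chain_id]
    if chain_id is not None and not chains:
        raise StructureError(
            f"{path}: chain {chain_id!r} not in model {model_number} "
            f"(chains: {[c.name for c in model]})"
        )

    atoms: list[AtomRecord] = []
    for chain in chains:
        for res in chain:
            if res.het_flag == "H" or res.is_water():
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.is_hydrogen():
                    continue
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                at = _resolve_altlocs(group)
                atoms.append(
                    AtomRecord(
                        atom_name=name,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=at.element.name,
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=(at.altloc or "").strip("\x00"),
                    )
                )
    if not atoms:
        raise StructureError(f"{path}: zero ATOM records after filtering")
    return Structure(
        id=structure_id or path.name.removesuffix(".gz").removesuffix(".pdb"),
        atoms=atoms,
        model_number=model_number,
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a single-model PDB file (fixed-column ATOM records)."""
    # gemmi add_* methods copy their argument, so assemble bottom-up
    grouped: dict[str, dict[tuple, list[AtomRecord]]] = {}
    for a in structure.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(a.residue_key, []).append(a)

    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model(structure.model_number)
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for key, atoms in residues.items():
            res = gemmi.Residue()
            res.name = atoms[0].residue_name
            res.seqid = gemmi.SeqId(atoms[0].residue_number, atoms[0].insertion_code or " ")
            res.het_flag = "A"
            for a in atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                at.pos = gemmi.Position(*a.position)
                at.element = gemmi.Element(a.element or a.atom_name[0])
                at.occ = a.occupancy
                if a.altloc:
                    at.altloc = a.altloc
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def extract_backbone(
    structure: Structure,
    residue_numbers: Sequence[int],
    chain_id: str | None = None,
    reference_positions: Sequence[int] | None = None,
    check_continuity: bool = True,
) -> BackboneSegment:
    """Extract an ordered backbone window with a strict completeness contract.

    Every requested residue must exist and carry all of N, CA, C, O; a missing
    residue or atom raises rather than silently shrinking the window (an
    incomplete model would otherwise corrupt superposition pairing).
    """
    if reference_positions is not None and len(reference_positions) != len(
        residue_numbers
    ):
        raise StructureError("reference_positions length != residue_numbers length")

    index: dict[tuple[int, str], AtomRecord] = {}
    names: dict[int, str] = {}
    for a in structure.atoms:
        if chain_id is not None and a.chain_id != chain_id:
            continue
        index[(a.residue_number, a.atom_name)] = a
        names.setdefault(a.residue_number, a.residue_name)

    residues: list[BackboneResidue] = []
    for i, num in enumerate(residue_numbers):
        if num not in names:
            raise StructureError(f"{structure.id}: residue {num} not in structure")
        coords = {}
        for name in BACKBONE_ATOMS:
            atom = index.get((num, name))
            if atom is None:
                raise StructureError(
                    f"{structure.id}: residue {num} is missing backbone atom {name}"
                )
            coords[name] = atom.position
        residues.append(
            BackboneResidue(
                residue_number=num,
                residue_name=names[num],
                n=coords["N"],
                ca=coords["CA"],
                c=coords["C"],
                o=coords["O"],
                reference_position=(
                    reference_positions[i] if reference_positions is not None else None
                ),
            )
        )
    segment = BackboneSegment(residues)
    if check_continuity and len(segment) > 1:
        segment.check_continuity()
    return segment
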