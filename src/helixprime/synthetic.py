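"""Synthetic helical backbones in two conformational classes.

The generator emulates the two conformations of the GFP central helix that
the geometry layer has to tell apart:

* ``ideal_helix`` — a canonical α-helix (φ = −57°, ψ = −47°, ω = 180°) with
  the full ladder of i→i+4 main-chain hydrogen bonds; the "cannot form a
  chromophore" class (regular helix, as in the nidogen G2 domain).
* ``kinked_helix`` — the same helix with a contiguous block of non-helical
  torsions around the chromophore triad, reproducing the tight-turn kink of
  the immature precyclized protein that breaks the i→i+4 bonds; the
  "can form a chromophore" class.

Backbones are built from internal coordinates (torsions + fixed Engh-Huber
bond lengths/angles) by the natural-extension construction, then optionally
perturbed with isotropic Gaussian coordinate noise. Everything is seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .helix_mapping import Alignment
from .structure_io import AtomRecord, Structure, write_pdb

__all__ = [
    "BackboneGeometry",
    "TorsionProfile",
    "CohortSpec",
    "Cohort",
    "build_backbone",
    "perturb",
    "generate_cohort",
    "measure_torsions",
    "ideal_helix_profile",
    "kinked_helix_profile",
    "IDEAL_TORSIONS",
    "KINK_TORSIONS",
    "MATURE_TORSIONS",
]

#: Canonical α-helix torsions, degrees.
IDEAL_TORSIONS = (-57.0, -47.0)

#: Tight-turn kink torsions applied to the kink block. Chosen so the turn
#: qualitatively reproduces the broken i→i+4 pattern of the precyclized
#: conformation; only the qualitative kink matters.
KINK_TORSIONS = (-80.0, 10.0)

#: Torsions for the synthetic "mature helix" reference: a damped
#: (70%-amplitude) kink. The formed chromophore keeps most of the
#: tight-turn distortion in the mature helix, so the precyclized
#: conformation must sit much closer to the mature reference than the
#: regular helix does — as observed between the corresponding crystal
#: structures.
MATURE_TORSIONS = (-73.1, -7.1)

#: Kink block in reference numbering: the triad plus its N-terminal
#: neighbour, where the precyclized structure deviates from a helix.
DEFAULT_KINK_POSITIONS = (64, 65, 66, 67)


@dataclass(frozen=True)
class BackboneGeometry:
    """Fixed stereochemistry (Engh-Huber) used for chain construction, Å/deg."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_ca_c: float = 111.2
    ca_c_n: float = 116.2
    c_n_ca: float = 121.7
    ca_c_o: float = 120.8

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o"):
            v = getattr(self, name)
            if not 1.0 < v < 2.0:
                raise ValueError(f"bond length {name}={v} outside (1, 2) Å")
        for name in ("n_ca_c", "ca_c_n", "c_n_ca", "ca_c_o"):
            v = getattr(self, name)
            if not 100.0 < v < 130.0:
                raise ValueError(f"bond angle {name}={v} outside (100, 130) deg")


@dataclass(frozen=True)
class TorsionProfile:
    """Per-residue (φ, ψ, ω) in degrees plus a class label."""

    phi: tuple[float, ...]
    psi: tuple[float, ...]
    omega: tuple[float, ...]
    class_label: str = "custom"

    def __post_init__(self) -> None:
        if not len(self.phi) == len(self.psi) == len(self.omega):
            raise ValueError("phi, psi, omega must have equal lengths")

    def __len__(self) -> int:
        return len(self.phi)


def _uniform_profile(n_residues: int, phi: float, psi: float, label: str) -> TorsionProfile:
    return TorsionProfile(
        phi=(phi,) * n_residues,
        psi=(psi,) * n_residues,
        omega=(180.0,) * n_residues,
        class_label=label,
    )


def ideal_helix_profile(n_residues: int = 15) -> TorsionProfile:
    return _uniform_profile(n_residues, *IDEAL_TORSIONS, "ideal_helix")


def kinked_helix_profile(
    n_residues: int = 15,
    kink_positions: tuple[int, ...] = DEFAULT_KINK_POSITIONS,
    start_number: int = 60,
    kink_torsions: tuple[float, float] = KINK_TORSIONS,
) -> TorsionProfile:
    """Canonical helix with a tight-turn block at the given positions."""
    phi = [IDEAL_TORSIONS[0]] * n_residues
    psi = [IDEAL_TORSIONS[1]] * n_residues
    for pos in kink_positions:
        i = pos - start_number
        if 0 <= i < n_residues:
            phi[i], psi[i] = kink_torsions
    return TorsionProfile(
        phi=tuple(phi), psi=tuple(psi), omega=(180.0,) * n_residues,
        class_label="kinked_helix",
    )


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    length: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from frame A-B-C.

    D is at the given bond length from C, with angle B-C-D and torsion
    A-B-C-D.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = length * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    profile: TorsionProfile,
    geometry: BackboneGeometry = BackboneGeometry(),
    n_residues: int | None = None,
    start_number: int = 60,
    structure_id: str = "synthetic",
    chain_id: str = "A",
) -> Structure:
    """Build an all-alanine-named backbone (N, CA, C, O) from torsions.

    Atoms are placed sequentially by the natural-extension construction;
    φ(i) sets the position of C(i), ψ(i) the position of N(i+1), ω(i) the
    position of CA(i+1). Carbonyl oxygens lie in the peptide plane opposite
    the next residue's nitrogen; the C-terminal oxygen uses the ψ + 180°
    convention.
    """
    n = n_residues if n_residues is not None else len(profile)
    if n < 2:
        raise ValueError("need at least 2 residues")
    if len(profile) < n:
        raise ValueError(
            f"torsion profile covers {len(profile)} residues, {n} requested"
        )
    g = geometry

    # first residue: N at origin, CA along +x, C in the xy-plane
    N = [np.zeros(3)]
    CA = [np.array([g.n_ca, 0.0, 0.0])]
    ang = np.deg2rad(g.n_ca_c)
    CA_C = g.ca_c
    C = [CA[0] + CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]

    for i in range(n - 1):
        N.append(_place_atom(N[i], CA[i], C[i], g.c_n, g.ca_c_n, profile.psi[i]))
        CA.append(_place_atom(CA[i], C[i], N[i + 1], g.n_ca, g.c_n_ca, profile.omega[i]))
        C.append(_place_atom(C[i], N[i + 1], CA[i + 1], g.ca_c, g.n_ca_c, profile.phi[i + 1]))

    O: list[np.ndarray] = []
    for i in range(n):
        if i < n - 1:
            # peptide plane, anti to the next N (torsion N(i+1)-CA-C-O = 180)
            O.append(_place_atom(N[i + 1], CA[i], C[i], g.c_o, g.ca_c_o, 180.0))
        else:
            O.append(_place_atom(N[i], CA[i], C[i], g.c_o, g.ca_c_o, profile.psi[i] + 180.0))

    atoms: list[AtomRecord] = []
    for i in range(n):
        num = start_number + i
        for name, pos, elem in (
            ("N", N[i], "N"), ("CA", CA[i], "C"), ("C", C[i], "C"), ("O", O[i], "O"),
        ):
            atoms.append(
                AtomRecord(
                    atom_name=name, residue_name="ALA", chain_id=chain_id,
                    residue_number=num, position=pos, element=elem,
                )
            )
    return Structure(id=structure_id, atoms=atoms)


def perturb(structure: Structure, noise_sd: float, seed: int) -> Structure:
    """Add independent isotropic Gaussian noise (sd per coordinate) to every atom."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if noise_sd == 0:
        return structure
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, noise_sd, size=(len(structure.atoms), 3))
    atoms = [
        replace(a, position=a.position + off)
        for a, off in zip(structure.atoms, offsets)
    ]
    return Structure(id=structure.id, atoms=atoms, model_number=structure.model_number)


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def measure_torsions(structure: Structure) -> pd.DataFrame:
    """Re-measure (φ, ψ, ω) from coordinates; NaN at chain termini."""
    coords: dict[tuple[int, str], np.ndarray] = {
        (a.residue_number, a.atom_name): a.position for a in structure.atoms
    }
    nums = structure.residue_numbers()
    rows = []
    for i, num in enumerate(nums):
        phi = psi = omega = float("nan")
        if i > 0:
            phi = _dihedral(
                coords[(nums[i - 1], "C")], coords[(num, "N")],
                coords[(num, "CA")], coords[(num, "C")],
            )
        if i < len(nums) - 1:
            psi = _dihedral(
                coords[(num, "N")], coords[(num, "CA")],
                coords[(num, "C")], coords[(nums[i + 1], "N")],
            )
            omega = _dihedral(
                coords[(num, "CA")], coords[(num, "C")],
                coords[(nums[i + 1], "N")], coords[(nums[i + 1], "CA")],
            )
        rows.append({"residue_number": num, "phi": phi, "psi": psi, "omega": omega})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSpec:
    """Study design for a synthetic two-class cohort.

    Defaults mirror the screened cohort: 21 chromophore-forming (kinked)
    and 23 non-forming (regular-helix) structures, with modest coordinate
    noise standing in for predictor variability.
    """

    n_can_form: int = 21
    n_cannot_form: int = 23
    noise_sd: float = 0.2
    seed: int = 0
    window_start: int = 60
    n_residues: int = 15
    kink_positions: tuple[int, ...] = DEFAULT_KINK_POSITIONS

    def __post_init__(self) -> None:
        if self.n_can_form < 1 or self.n_cannot_form < 1:
            raise ValueError("need at least one structure per class")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Cohort:
    """Generated structures, truth labels, references and identity alignment."""

    spec: CohortSpec
    structures: dict[str, Structure]
    labels: dict[str, str]  # target_id -> can_form | cannot_form
    references: dict[str, Structure]  # role (1EMA/2AWJ/1H4U) -> structure
    alignment: Alignment
    #: provenance of the random stream, recorded for reproducibility
    generator: str = "numpy.random.default_rng(PCG64), member_seed = seed + index"

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"target_id": tid, "label": lab} for tid, lab in self.labels.items()]
        )

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write member and reference PDBs, truth CSV and alignment FASTA."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        members = list(self.structures.values()) + list(self.references.values())
        for st in members:
            p = directory / f"{st.id}.pdb"
            write_pdb(st, p)
            paths[st.id] = p
        truth = directory / "truth.csv"
        self.truth_table().to_csv(truth, index=False)
        paths["truth"] = truth
        fasta = directory / "alignment.fasta"
        with open(fasta, "w") as fh:
            for rid, seq in self.alignment.records.items():
                fh.write(f">{rid}\n{seq}\n")
        paths["alignment"] = fasta
        return paths


def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate the labeled two-class cohort plus reference structures.

    References (noise-free):
      * role 1EMA — "mature helix" (half-amplitude kink);
      * role 2AWJ — "precyclized tight turn" (full kink);
      * role 1H4U — "regular helix" (canonical α-helix).

    Members: kinked helices labeled ``can_form`` and canonical helices
    labeled ``cannot_form``, each independently perturbed with
    ``member_seed = spec.seed + index`` (index over the concatenated cohort).
    The identity alignment contains every member and reference so the
    mapping layer is exercised end to end.
    """
    n = spec.n_residues
    start = spec.window_start
    ideal = ideal_helix_profile(n)
    kinked = kinked_helix_profile(n, spec.kink_positions, start)
    mature = kinked_helix_profile(n, spec.kink_positions, start, MATURE_TORSIONS)
    mature = replace(mature, class_label="mature_helix")

    references = {
        "1EMA": build_backbone(mature, start_number=start, structure_id="ref_mature"),
        "2AWJ": build_backbone(kinked, start_number=start, structure_id="ref_kinked"),
        "1H4U": build_backbone(ideal, start_number=start, structure_id="ref_ideal"),
    }

    structures: dict[str, Structure] = {}
    labels: dict[str, str] = {}
    index = 0
    for label, profile, count, stem in (
        ("can_form", kinked, spec.n_can_form, "kinked"),
        ("cannot_form", ideal, spec.n_cannot_form, "ideal"),
    ):
        for j in range(count):
            tid = f"{stem}_{j:02d}"
            st = build_backbone(profile, start_number=start, structure_id=tid)
            structures[tid] = perturb(st, spec.noise_sd, spec.seed + index)
            labels[tid] = label
            index += 1

    seq = "A" * n
    records = {tid: seq for tid in structures}
    records.update({ref.id: seq for ref in references.values()})
    alignment = Alignment(records=records, reference_id="ref_mature")
    return Cohort(
        spec=spec,
        structures=structures,
        labels=labels,
        references=references,
        alignment=alignment,
    )
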