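"""Geometric fingerprint of the central helix window.

Three measurement families discriminate a chromophore-primed (tight-turn)
helix from a regular α-helix:

* helix-overlap RMSD — rms displacement of the paired backbone heavy atoms
  (N, CA, C, O) of the window residues after optimal rigid-body (Kabsch)
  superposition onto each reference conformation;
* tight-turn distance — the cyclization attack distance, by default from the
  backbone amide N of the residue at reference position 67 to the carbonyl C
  of the residue at position 65;
* HD1-HD11 — the eleven i→i+4 main-chain "hydrogen bond" distances across
  the 15-residue window, measured as plain O(i)-N(i+4) Euclidean distances
  (HDk spans reference positions 59+k → 63+k). A regular helix keeps all of
  them near 3 Å; the tight turn breaks the ones crossing the kink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .helix_mapping import ResidueMap
from .structure_io import BackboneSegment, Structure, StructureError, extract_backbone

__all__ = [
    "SuperpositionResult",
    "TightTurnDefinition",
    "GeometricFingerprint",
    "GeometryError",
    "kabsch_superpose",
    "helix_overlap_rmsd",
    "hbond_distances",
    "tight_turn_distance",
    "fingerprint",
    "fingerprints_to_frame",
    "FINGERPRINT_COLUMNS",
    "HD_NAMES",
    "REFERENCE_ROLES",
]

REFERENCE_ROLES = ("1EMA", "2AWJ", "1H4U")
HD_NAMES = tuple(f"HD{k}" for k in range(1, 12))
FINGERPRINT_COLUMNS = (
    "target_id",
    "predictor",
    "label",
    "rmsd_vs_1EMA",
    "rmsd_vs_2AWJ",
    "rmsd_vs_1H4U",
    "tight_turn",
    *HD_NAMES,
)


class GeometryError(ValueError):
    """Raised for invalid geometric input (mismatched or degenerate sets)."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body superposition of one point set onto another."""

    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class TightTurnDefinition:
    """Atom pair defining the tight-turn (cyclization attack) distance."""

    donor_position: int = 67
    donor_atom: str = "N"
    acceptor_position: int = 65
    acceptor_atom: str = "C"


@dataclass
class GeometricFingerprint:
    """One row of the measurement table for one target structure."""

    target_id: str
    predictor: str  # AF2 | RF | crystal | synthetic
    rmsd_vs_1EMA: float
    rmsd_vs_2AWJ: float
    rmsd_vs_1H4U: float
    tight_turn: float
    hd: dict[str, float]
    label: str = "unknown"

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "target_id": self.target_id,
            "predictor": self.predictor,
            "label": self.label,
            "rmsd_vs_1EMA": self.rmsd_vs_1EMA,
            "rmsd_vs_2AWJ": self.rmsd_vs_2AWJ,
            "rmsd_vs_1H4U": self.rmsd_vs_1H4U,
            "tight_turn": self.tight_turn,
        }
        row.update({name: self.hd.get(name, float("nan")) for name in HD_NAMES})
        return row


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Closed-form Kabsch solution via SVD of the cross-covariance matrix, with
    the reflection corrected by flipping the sign of the smallest singular
    direction so the rotation is always proper (det = +1). Point sets are
    paired by order.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or Q.ndim != 2 or Q.shape[1] != 3:
        raise GeometryError("point sets must be (n, 3) arrays")
    if P.shape[0] != Q.shape[0]:
        raise GeometryError(
            f"point-set size mismatch: moving has {P.shape[0]}, fixed has {Q.shape[0]}"
        )
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points, got {n}")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 means the points are collinear (or coincident): the rotation
    # about the degenerate axis is unconstrained
    if np.sum(S > max(S[0], 1.0) * 1e-10) < 2:
        raise GeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


def helix_overlap_rmsd(target: BackboneSegment, reference: BackboneSegment) -> float:
    """Backbone RMSD of two helix windows after optimal superposition.

    Both segments must cover the same reference positions; atoms are paired
    N, CA, C, O per residue in window order (4n pairs).
    """
    tpos = target.reference_positions
    rpos = reference.reference_positions
    if tpos != rpos:
        only_t = sorted(set(tpos) - set(rpos))
        only_r = sorted(set(rpos) - set(tpos))
        raise GeometryError(
            f"window mismatch: target-only positions {only_t}, "
            f"reference-only positions {only_r}"
        )
    return kabsch_superpose(target.coords(), reference.coords()).rmsd


def hbond_distances(
    segment: BackboneSegment, window: Sequence[int] = tuple(range(60, 75))
) -> dict[str, float]:
    """The eleven i→i+4 O-N distances across a complete 15-residue window.

    HDk is the distance between the carbonyl oxygen of the residue at
    reference position 59+k and the backbone nitrogen at 63+k (k = 1..11).
    """
    by_pos = {r.reference_position: r for r in segment.residues}
    missing = [p for p in window if p not in by_pos]
    if missing:
        raise GeometryError(
            f"incomplete window: reference positions {missing} are absent"
        )
    start = window[0]
    out: dict[str, float] = {}
    for k in range(1, len(window) - 3):
        donor = by_pos[start + k - 1]  # position 59+k when window starts at 60
        acceptor = by_pos[start + k + 3]
        out[f"HD{k}"] = float(np.linalg.norm(acceptor.n - donor.o))
    return out


def tight_turn_distance(
    structure: Structure,
    residue_map: ResidueMap,
    definition: TightTurnDefinition = TightTurnDefinition(),
    chain_id: str | None = None,
) -> float:
    """Cyclization attack distance from the mapped anchor residues.

    Default: amide N of the residue at reference position 67 to the carbonyl
    C at position 65 — the bond-forming N→C=O approach of the first
    (cyclization) step of chromophore maturation.
    """
    anchors = residue_map.anchors
    for pos in (definition.donor_position, definition.acceptor_position):
        if pos not in anchors:
            raise GeometryError(
                f"{residue_map.target_id}: anchor for reference position {pos} "
                "is unresolved (gapped in the alignment?)"
            )
    donor = structure.atom(
        anchors[definition.donor_position], definition.donor_atom, chain_id
    )
    acceptor = structure.atom(
        anchors[definition.acceptor_position], definition.acceptor_atom, chain_id
    )
    return float(np.linalg.norm(donor.position - acceptor.position))


def fingerprint(
    target: Structure,
    residue_map: ResidueMap,
    references: Mapping[str, BackboneSegment],
    predictor: str = "unknown",
    label: str = "unknown",
    tight_turn_def: TightTurnDefinition = TightTurnDefinition(),
    chain_id: str | None = None,
    check_continuity: bool = True,
) -> GeometricFingerprint:
    """Compute the full geometric fingerprint of one mapped target.

    ``references`` maps the three reference roles (1EMA, 2AWJ, 1H4U) to their
    backbone segments. A reference whose own window is a subset of the
    target's (e.g. the mature 1EMA helix without the chromophore residues)
    is compared on its available positions only, keeping atom counts equal
    across all targets for that reference.

    ``check_continuity`` enforces the CA-CA chain-continuity bound; disable
    it for structures that carry deliberately injected coordinate noise.
    """
    try:
        segment = extract_backbone(
            target,
            residue_map.target_numbers,
            chain_id=chain_id,
            reference_positions=residue_map.reference_positions,
            check_continuity=check_continuity,
        )
        rmsds: dict[str, float] = {}
        for role in REFERENCE_ROLES:
            if role not in references:
                raise GeometryError(f"missing reference segment for role {role}")
            ref = references[role]
            ref_pos = [p for p in ref.reference_positions if p is not None]
            rmsds[role] = helix_overlap_rmsd(segment.subset(ref_pos), ref)
        hd = hbond_distances(segment)
        turn = tight_turn_distance(target, residue_map, tight_turn_def, chain_id)
    except (StructureError, GeometryError) as exc:
        raise GeometryError(f"fingerprint of {residue_map.target_id}: {exc}") from exc
    return GeometricFingerprint(
        target_id=residue_map.target_id,
        predictor=predictor,
        rmsd_vs_1EMA=rmsds["1EMA"],
        rmsd_vs_2AWJ=rmsds["2AWJ"],
        rmsd_vs_1H4U=rmsds["1H4U"],
        tight_turn=turn,
        hd=hd,
        label=label,
    )


def fingerprints_to_frame(fingerprints: Sequence[GeometricFingerprint]) -> pd.DataFrame:
    """Assemble fingerprints into the fixed-schema measurement table."""
    frame = pd.DataFrame([fp.as_row() for fp in fingerprints])
    return frame.reindex(columns=list(FINGERPRINT_COLUMNS))
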