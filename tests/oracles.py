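"""Independent oracles used only by the test suite.

Each oracle re-derives a quantity by a different route than the library:
brute-force rotation search instead of the closed-form SVD solution, and a
rotation-matrix chain builder (scipy Rotation composition) instead of the
natural-extension frame construction.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_superposition_rmsd(
    moving: np.ndarray, fixed: np.ndarray, n_coarse: int = 60_000, refine_rounds: int = 40
) -> float:
    """Minimum RMSD over rigid motions by quaternion search + local refinement.

    Centroids are aligned exactly (optimal translation is closed-form); the
    rotation is found by scanning a large quasi-random set of unit
    quaternions and then shrinking a local random search around the best
    one. Accurate to well below 1e-3 A on small point sets.
    """
    P = np.asarray(moving, float) - np.mean(moving, axis=0)
    Q = np.asarray(fixed, float) - np.mean(fixed, axis=0)

    rng = np.random.default_rng(12345)
    quats = rng.normal(size=(n_coarse, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    best_rmsd = np.inf
    best_q = None
    chunk = 2000
    for i in range(0, n_coarse, chunk):
        sub = Rotation.from_quat(quats[i : i + chunk])
        mats = sub.as_matrix()  # (c, 3, 3)
        moved = np.einsum("cij,nj->cni", mats, P)
        d = moved - Q[None]
        r = np.sqrt(np.mean(np.sum(d**2, axis=-1), axis=-1))
        j = int(np.argmin(r))
        if r[j] < best_rmsd:
            best_rmsd = float(r[j])
            best_q = quats[i + j]

    # local refinement: shrinking Gaussian perturbations of the quaternion
    scale = 0.1
    for _ in range(refine_rounds):
        cand = best_q[None] + rng.normal(scale=scale, size=(400, 4))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        mats = Rotation.from_quat(cand).as_matrix()
        moved = np.einsum("cij,nj->cni", mats, P)
        r = np.sqrt(np.mean(np.sum((moved - Q[None]) ** 2, axis=-1), axis=-1))
        j = int(np.argmin(r))
        if r[j] < best_rmsd:
            best_rmsd = float(r[j])
            best_q = cand[j]
        scale *= 0.7
    return best_rmsd


def rotation_chain_backbone(
    phi: list[float], psi: list[float], omega: list[float]
) -> dict[str, np.ndarray]:
    """Backbone N/CA/C coordinates from torsions via explicit frame rotations.

    Independent of the natural-extension construction: each atom is placed
    by composing scipy Rotations — a rotation by (180 - bond angle) about
    the current frame's z-axis followed by a torsion rotation about the new
    bond direction.
    """
    lengths = {"n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329}
    angles = {"n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7}
    n = len(phi)

    # state: current position, direction of last bond, and reference normal
    atoms = {"N": [np.zeros(3)], "CA": [], "C": []}
    direction = np.array([1.0, 0.0, 0.0])
    normal = np.array([0.0, 0.0, 1.0])

    def step(pos, direction, normal, length, bond_angle, torsion):
        # torsion rotation about the previous bond direction
        r_tor = Rotation.from_rotvec(np.deg2rad(torsion) * direction)
        normal = r_tor.apply(normal)
        # bend by (180 - angle) about the plane normal
        r_bend = Rotation.from_rotvec(np.deg2rad(180.0 - bond_angle) * normal)
        direction = r_bend.apply(direction)
        return pos + length * direction, direction, normal

    pos = atoms["N"][0]
    # first CA and C: no preceding torsion (use 0)
    pos, direction, normal = step(pos, direction, normal, lengths["n_ca"], 180.0, 0.0)
    atoms["CA"].append(pos)
    pos, direction, normal = step(pos, direction, normal, lengths["ca_c"], angles["n_ca_c"], 0.0)
    atoms["C"].append(pos)
    for i in range(n - 1):
        pos, direction, normal = step(pos, direction, normal, lengths["c_n"], angles["ca_c_n"], psi[i])
        atoms["N"].append(pos)
        pos, direction, normal = step(pos, direction, normal, lengths["n_ca"], angles["c_n_ca"], omega[i])
        atoms["CA"].append(pos)
        pos, direction, normal = step(pos, direction, normal, lengths["ca_c"], angles["n_ca_c"], phi[i + 1])
        atoms["C"].append(pos)
    return {k: np.array(v) for k, v in atoms.items()}
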