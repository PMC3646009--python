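"""Internal-coordinate peptide backbone construction.

Chains are grown atom by atom with the NeRF construction (place each atom
from a bond length, a bond angle and a torsion relative to three previously
placed atoms).  The representation is heavy-atom backbone (N, CA, C, O)
plus a single Cβ pseudo-atom standing in for the side chain (absent for
glycine) — sufficient for Cα contact maps, DSSP-style hydrogen bonding and
coarse-grained surface areas, which is all the downstream analyses consume.
"""

from __future__ import annotations

import numpy as np

from .structure import Atom, Chain, Residue, Structure

# Engh & Huber style ideal geometry, Å and degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4
OMEGA_TRANS = 180.0

# Ideal dihedrals used throughout the package.
HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -139.0, 135.0


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |c−d| = bond, ∠(b,c,d) = angle, χ(a,b,c,d) = torsion."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle in degrees (IUPAC convention)."""
    b0, b1, b2 = a - b, c - b, d - c
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def build_backbone(sequence: str,
                   phi: np.ndarray,
                   psi: np.ndarray,
                   omega: float = OMEGA_TRANS,
                   chain_id: str = "A",
                   first_author_number: int = 1) -> Structure:
    """Grow a chain with the given per-residue (φ, ψ).

    ``phi[0]`` and ``psi[-1]`` are used only for Cβ/O placement of the
    terminal residues.  Side chains are represented by Cβ only (except Gly).
    """
    n_res = len(sequence)
    phi = np.broadcast_to(np.asarray(phi, float), (n_res,))
    psi = np.broadcast_to(np.asarray(psi, float), (n_res,))

    n_pos = np.zeros((n_res, 3))
    ca_pos = np.zeros((n_res, 3))
    c_pos = np.zeros((n_res, 3))

    # Seed the first residue in the xy-plane.
    n_pos[0] = (0.0, 0.0, 0.0)
    ca_pos[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    c_pos[0] = ca_pos[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_res):
        n_pos[i] = place_atom(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                              BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        ca_pos[i] = place_atom(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                               BOND_N_CA, ANGLE_C_N_CA, omega)
        c_pos[i] = place_atom(c_pos[i - 1], n_pos[i], ca_pos[i],
                              BOND_CA_C, ANGLE_N_CA_C, phi[i])

    residues = []
    for i, aa in enumerate(sequence):
        atoms = [
            Atom("N", "N", n_pos[i]),
            Atom("CA", "C", ca_pos[i]),
            Atom("C", "C", c_pos[i]),
        ]
        # Carbonyl O: anti to the next amide N (trans peptide plane).
        if i + 1 < n_res:
            o = place_atom(n_pos[i + 1], ca_pos[i], c_pos[i],
                           BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o = place_atom(n_pos[i], ca_pos[i], c_pos[i],
                           BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
        atoms.append(Atom("O", "O", o))
        if aa != "G":
            cb = place_atom(c_pos[i], n_pos[i], ca_pos[i],
                            BOND_CA_CB, ANGLE_N_CA_CB, -122.6)
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(aa=aa, author_number=first_author_number + i,
                                seq_index=i, atoms=atoms))
    s = Structure([Chain(chain_id, residues)])
    s.validate()
    return s


def build_helix(sequence: str, **kwargs) -> Structure:
    """Ideal α-helix (φ = −57°, ψ = −47°)."""
    n = len(sequence)
    return build_backbone(sequence, np.full(n, HELIX_PHI), np.full(n, HELIX_PSI), **kwargs)


def build_extended(sequence: str, **kwargs) -> Structure:
    """Extended chain (φ = −139°, ψ = +135°), the reference-tripeptide conformation."""
    n = len(sequence)
    return build_backbone(sequence, np.full(n, EXTENDED_PHI), np.full(n, EXTENDED_PSI), **kwargs)


def principal_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant axis of a point cloud, oriented from first to last point."""
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)
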