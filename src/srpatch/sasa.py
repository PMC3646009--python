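"""Solvent-accessible surface area and buried/exposed classification.

The engine is Shrake–Rupley quadrature with a *deterministic* Fibonacci
spiral point set, so results are exactly reproducible without a random
seed.  Relative accessibility divides each residue's area in the protein
by its area in an extended Ala-Xxx-Ala tripeptide measured with the same
engine and the same atomic representation; residues at or below 20%
relative accessibility are classified buried, above 20% exposed.

Two atomic representations are supported and auto-detected:

* full-atom structures (external PDB files) use an atom-class van der
  Waals table (C 1.70/1.87, N 1.55, O 1.52, S 1.80 Å);
* the package's coarse Cβ-only structures give the Cβ pseudo-atom a
  residue-specific effective radius derived from mean side-chain volumes,
  in the spirit of coarse-grained SASA methods.

Absolute areas therefore depend on the representation; the buried/exposed
classification against the matched tripeptide reference is the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .builder import build_extended
from .structure import STANDARD_AAS, Structure

log = logging.getLogger("srpatch")

BURIAL_CUTOFF = 0.20

# van der Waals radii, Å.  Carbons split by atom class: sp2 (carbonyl,
# carboxyl/amide and aromatic ring carbons) 1.70, aliphatic 1.87.
ELEMENT_RADII = {"C": 1.87, "N": 1.55, "O": 1.52, "S": 1.80}
_SP2_CARBONS = {
    ("*", "C"),
    ("D", "CG"), ("N", "CG"), ("E", "CD"), ("Q", "CD"), ("R", "CZ"),
    ("F", "CG"), ("F", "CD1"), ("F", "CD2"), ("F", "CE1"), ("F", "CE2"), ("F", "CZ"),
    ("Y", "CG"), ("Y", "CD1"), ("Y", "CD2"), ("Y", "CE1"), ("Y", "CE2"), ("Y", "CZ"),
    ("W", "CG"), ("W", "CD1"), ("W", "CD2"), ("W", "CE2"), ("W", "CE3"),
    ("W", "CZ2"), ("W", "CZ3"), ("W", "CH2"),
    ("H", "CG"), ("H", "CD2"), ("H", "CE1"),
}

# Mean residue volumes (Å³, Zamyatnin); side-chain volume = total − Gly.
_RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


def sidechain_effective_radius(aa: str) -> float:
    """Radius of a sphere with the mean side-chain volume of residue type aa."""
    v = _RESIDUE_VOLUME[aa] - _RESIDUE_VOLUME["G"]
    return float((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))


_COARSE_ATOMS = {"N", "CA", "C", "O", "CB", "OXT"}


def is_coarse(s: Structure) -> bool:
    """True when the structure carries no side-chain atoms beyond Cβ."""
    return all(a.name in _COARSE_ATOMS for _, a in s.iter_atoms())


class RadiiError(KeyError):
    """An atom's van der Waals radius is not covered by the radii set."""


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_mode: str = "auto"  # auto | atom-class | coarse-cb

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be at least 60")
        if self.radii_mode not in ("auto", "atom-class", "coarse-cb"):
            raise ValueError(f"unknown radii_mode {self.radii_mode!r}")

    def resolve_mode(self, s: Structure) -> str:
        if self.radii_mode != "auto":
            return self.radii_mode
        return "coarse-cb" if is_coarse(s) else "atom-class"


@dataclass
class SasaResult:
    atom_area: np.ndarray                 # aligned with Structure.iter_atoms()
    residue_area: dict[int, float]        # seq_index -> Å²
    relative_area: dict[int, float]       # seq_index -> fraction of tripeptide ref
    burial_class: dict[int, str]          # seq_index -> "buried" | "exposed"
    params: SasaParams = field(default_factory=SasaParams)

    def exposed_set(self) -> set[int]:
        return {i for i, c in self.burial_class.items() if c == "exposed"}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def _atom_radius(aa: str, name: str, element: str, mode: str) -> float:
    if mode == "coarse-cb" and name == "CB" and aa in _RESIDUE_VOLUME:
        return sidechain_effective_radius(aa)
    el = element.upper()
    if el == "C":
        if ("*", name) in _SP2_CARBONS or (aa, name) in _SP2_CARBONS:
            return 1.70
        return ELEMENT_RADII["C"]
    try:
        return ELEMENT_RADII[el]
    except KeyError:
        raise RadiiError(f"no van der Waals radius for element {element!r} (atom {name})") from None


def structure_radii(s: Structure, params: SasaParams) -> np.ndarray:
    mode = params.resolve_mode(s)
    return np.array([_atom_radius(r.aa, a.name, a.element, mode)
                     for r, a in s.iter_atoms()])


def _canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Express coordinates in a frame intrinsic to the point set.

    Centring on the centroid and aligning to (sign-fixed) principal axes
    makes the quadrature independent of how the input happens to be
    oriented in the lab frame, so areas are invariant under rigid motion.
    """
    centred = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return centred
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    proj = centred @ vecs
    for k in range(3):
        skew = (proj[:, k] ** 3).sum()
        if abs(skew) > 1e-8:
            if skew < 0:
                proj[:, k] = -proj[:, k]
        else:
            extreme = np.argmax(np.abs(proj[:, k]))
            if proj[extreme, k] < 0:
                proj[:, k] = -proj[:, k]
    return proj


def sasa_spheres(coords: np.ndarray, radii: np.ndarray,
                 probe: float = 1.4, n_points: int = 960,
                 canonicalize: bool = True) -> np.ndarray:
    """Per-sphere accessible area, Å², for arbitrary sphere sets.

    Each sphere's area is (accessible fraction of test points) × 4π(r+probe)².
    With ``canonicalize`` (default) the quadrature runs in the point set's
    intrinsic frame, making areas invariant under rigid motion of the input;
    with a fixed lab frame (``canonicalize=False``) occlusion is instead
    exactly monotone when atoms are added.
    """
    coords = np.asarray(coords, float)
    if canonicalize:
        coords = _canonical_orientation(coords)
    radii = np.asarray(radii, float)
    n = len(coords)
    extended = radii + probe
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_ext = extended.max() if n else 0.0
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], extended[i] + max_ext)
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < extended[i] + extended[j]]
        test = coords[i] + extended[i] * pts
        if neigh:
            d2 = ((test[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= (extended[neigh] ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * extended[i] ** 2
    return areas


def atom_sasa(s: Structure, params: SasaParams = SasaParams()) -> np.ndarray:
    """Per-atom solvent-accessible areas, aligned with ``s.iter_atoms()``."""
    coords = s.coords()
    radii = structure_radii(s, params)
    return sasa_spheres(coords, radii, params.probe_radius, params.n_sphere_points)


@lru_cache(maxsize=None)
def reference_area(aa: str, probe_radius: float = 1.4, n_sphere_points: int = 960,
                   radii_mode: str = "coarse-cb") -> float:
    """SASA of residue Xxx in an extended, isolated Ala-Xxx-Ala tripeptide.

    Built with the internal chain builder and measured with the same engine
    and representation as the structures it normalizes, so numerator and
    denominator are mutually consistent.
    """
    if aa not in STANDARD_AAS:
        raise KeyError(f"not a standard amino acid: {aa!r}")
    tri = build_extended(f"A{aa}A")
    params = SasaParams(probe_radius, n_sphere_points, radii_mode)
    areas = atom_sasa(tri, params)
    middle = [k for k, (r, _) in enumerate(tri.iter_atoms()) if r.seq_index == 1]
    return float(areas[middle].sum())


def classify_burial(relative_area: float, cutoff: float = BURIAL_CUTOFF) -> str:
    """Exposed iff relative area exceeds the cutoff; exactly at it counts buried."""
    if relative_area < 0:
        raise ValueError(f"relative area must be non-negative, got {relative_area}")
    return "exposed" if relative_area > cutoff else "buried"


def sasa(s: Structure, params: SasaParams = SasaParams(),
         burial_cutoff: float = BURIAL_CUTOFF) -> SasaResult:
    """Full per-residue SASA analysis of a single-chain structure."""
    chain = s.single_chain()
    areas = atom_sasa(s, params)
    mode = params.resolve_mode(s)
    residue_area: dict[int, float] = {}
    for (res, _), a in zip(s.iter_atoms(), areas):
        residue_area[res.seq_index] = residue_area.get(res.seq_index, 0.0) + float(a)
    relative: dict[int, float] = {}
    burial: dict[int, str] = {}
    for res in chain:
        area = residue_area.get(res.seq_index, 0.0)
        if res.aa in STANDARD_AAS:
            ref = reference_area(res.aa, params.probe_radius,
                                 params.n_sphere_points, mode)
        else:
            log.warning("residue %s%d: nonstandard type, relative SASA unavailable",
                        res.aa, res.author_number)
            continue
        rel = area / ref if ref > 0 else 0.0
        relative[res.seq_index] = rel
        burial[res.seq_index] = classify_burial(rel, burial_cutoff)
    return SasaResult(areas, residue_area, relative, burial, params)
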