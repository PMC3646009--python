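"""Synthetic structures, conservation tables and coordinate ensembles.

Everything downstream of raw data can be exercised on generated inputs:

* :func:`build_bundle` — an idealized antiparallel three-helix bundle with
  realistic backbone geometry (the spectrin-repeat fold), built entirely
  from internal coordinates: helices are ideal α-helices packed at a stated
  axis separation, and the two connecting loops are closed by solving their
  backbone dihedrals (least squares, with seeded jittered restarts).
* :func:`plant_conservation` — a ConSurf-style grade table with a planted
  surface cluster of high grades within a stated radius over a variable
  background, the ground truth for patch-detection tests.
* :func:`build_ensemble` — coordinate ensembles with planted low-frequency
  collective modes plus isotropic Gaussian noise, the ground truth for
  RMSF/PCA tests; :func:`make_hinge_mode` builds the classic inter-repeat
  bending mode.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import builder as bld
from .builder import build_helix, place_atom, principal_axis
from .io import GradeTable
from .sasa import SasaResult
from .structure import Atom, Chain, Residue, Structure
from .trajectory import Ensemble

log = logging.getLogger("srpatch")

# Heptad-ish default sequence material (no Gly/Pro inside helices).
_HELIX_PATTERN = "LEALKAQ"
_LOOP_PATTERN = "SDTN"


@dataclass(frozen=True)
class BundleSpec:
    helix_lengths: tuple[int, int, int] = (16, 18, 16)
    loop_lengths: tuple[int, int] = (4, 4)
    inter_helix_distance: float = 10.0   # Å between helix axes
    antiparallel: bool = True
    rise_per_residue: float = 1.5        # Å, informational (ideal α-helix value)
    residues_per_turn: float = 3.6       # informational

    def __post_init__(self) -> None:
        if any(h < 8 for h in self.helix_lengths):
            raise ValueError("helix lengths must be at least 8")
        if any(l < 2 for l in self.loop_lengths):
            raise ValueError("loop lengths must be at least 2")

    @property
    def n_residues(self) -> int:
        return sum(self.helix_lengths) + sum(self.loop_lengths)


@dataclass(frozen=True)
class PlantSpec:
    centre_residue: int
    radius: float = 10.0
    planted_grades: tuple[int, ...] = (7, 8, 9)
    background_grade_max: int = 6
    seed: int = 0
    # widen the ball (1 Å steps, up to max_radius) until the planted cluster
    # is dense enough to be detectable: some planted residue must have more
    # than min_cluster planted residues among its contacts (sequence
    # neighbours never count) within detect_radius
    ensure_detectable: bool = True
    min_cluster: int = 5
    detect_radius: float = 10.0
    max_radius: float = 20.0

    def __post_init__(self) -> None:
        if any(g < 7 for g in self.planted_grades):
            raise ValueError("planted grades must be at least 7")
        if not 1 <= self.background_grade_max <= 6:
            raise ValueError("background_grade_max must be in 1..6")


@dataclass
class EnsembleSpec:
    modes: np.ndarray                    # (n_modes, 3N), orthonormal rows
    amplitudes: tuple[float, ...]        # Å
    noise_sigma: float = 0.1             # Å per coordinate
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes, float))
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if len(self.amplitudes) != len(self.modes):
            raise ValueError("one amplitude per mode required")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
            raise ValueError("modes must be pairwise orthonormal")


def _pattern(pattern: str, n: int, offset: int = 0) -> str:
    return "".join(pattern[(offset + i) % len(pattern)] for i in range(n))


def default_sequence(spec: BundleSpec) -> str:
    h1, h2, h3 = spec.helix_lengths
    l1, l2 = spec.loop_lengths
    return (_pattern(_HELIX_PATTERN, h1) + _pattern(_LOOP_PATTERN, l1)
            + _pattern(_HELIX_PATTERN, h2, 3) + _pattern(_LOOP_PATTERN, l2, 2)
            + _pattern(_HELIX_PATTERN, h3, 5))


def _align_helix(s: Structure, direction: np.ndarray, axis_xy: np.ndarray,
                 start_z: float, spin_deg: float = 0.0) -> Structure:
    """Rigidly place a built helix: axis along ``direction`` through
    ``axis_xy``, first Cα at height ``start_z``, spun by ``spin_deg``."""
    ca = s.single_chain().ca_coords()
    axis = principal_axis(ca)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    v = np.cross(axis, direction)
    c = float(np.dot(axis, direction))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(direction, direction)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    # spin about the final axis
    sa, caa = np.sin(np.deg2rad(spin_deg)), np.cos(np.deg2rad(spin_deg))
    d = direction
    spin = (caa * np.eye(3) + sa * np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
            + (1 - caa) * np.outer(d, d))
    rot = spin @ rot
    placed = s.transformed(rot, np.zeros(3))
    ca = placed.single_chain().ca_coords()
    centroid = ca.mean(axis=0)
    # shift axis to pass through axis_xy, then set the first Cα height
    t = np.array([axis_xy[0] - centroid[0], axis_xy[1] - centroid[1], 0.0])
    ca0_z = ca[0, 2] + t[2]
    t[2] = start_z - ca0_z
    return placed.transformed(np.eye(3), t)


def _extend_backbone(anchor: tuple[np.ndarray, np.ndarray, np.ndarray],
                     dihedrals: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Grow (N, CA, C) triples from an anchor residue given
    [psi_anchor, (phi, psi) per new residue...] torsions."""
    n_prev, ca_prev, c_prev = anchor
    psi = dihedrals[0]
    out = []
    k = 1
    while k < len(dihedrals):
        phi = dihedrals[k]
        n = place_atom(n_prev, ca_prev, c_prev, bld.BOND_C_N, bld.ANGLE_CA_C_N, psi)
        ca = place_atom(ca_prev, c_prev, n, bld.BOND_N_CA, bld.ANGLE_C_N_CA, bld.OMEGA_TRANS)
        c = place_atom(c_prev, n, ca, bld.BOND_CA_C, bld.ANGLE_N_CA_C, phi)
        out.append((n, ca, c))
        n_prev, ca_prev, c_prev = n, ca, c
        psi = dihedrals[k + 1] if k + 1 < len(dihedrals) else 0.0
        k += 2
    return out


def _close_loop(anchor, target, n_loop: int, rng: np.random.Generator,
                max_tries: int = 10):
    """Solve loop dihedrals so the chain lands on the next helix's N/CA/C.

    Free parameters: the anchor residue's ψ plus (φ, ψ) for each loop
    residue; the closure places a virtual first helix residue (with the
    helix φ) whose N, CA, C must coincide with the target.  Retries with
    seeded jittered starts; raises after ``max_tries`` failures.
    """
    target_flat = np.concatenate([np.asarray(t, float) for t in target])

    def residuals(x):
        dih = np.concatenate([x, [bld.HELIX_PHI]])
        triples = _extend_backbone(anchor, dih)
        virt = triples[-1]
        return np.concatenate([virt[0], virt[1], virt[2]]) - target_flat

    best = None
    for attempt in range(max_tries):
        x0 = np.concatenate([[bld.EXTENDED_PSI],
                             np.tile([bld.EXTENDED_PHI, bld.EXTENDED_PSI], n_loop)])
        x0 = x0 + rng.uniform(-60.0, 60.0, size=x0.shape) * (0.3 + 0.7 * attempt / max_tries)
        method = "lm" if len(x0) <= 9 else "trf"  # lm needs m >= n
        sol = least_squares(residuals, x0, method=method, max_nfev=4000)
        err = np.abs(sol.fun).max()
        if best is None or err < best[1]:
            best = (sol.x, err)
        if err < 0.30:
            return sol.x
    raise RuntimeError(f"loop closure failed: best residual {best[1]:.2f} Å")


def build_bundle(spec: BundleSpec = BundleSpec(), sequence: str | None = None,
                 seed: int = 0) -> Structure:
    """Idealized three-helix bundle with realistic backbone geometry.

    Helices are ideal α-helices (φ = −57°, ψ = −47°) packed antiparallel at
    ``inter_helix_distance`` on a triangular arrangement; the two loops are
    closed by dihedral optimization.  Consecutive Cα–Cα distances stay near
    3.8 Å and non-bonded Cα pairs are checked against clashes (< 3 Å).
    """
    if sequence is None:
        sequence = default_sequence(spec)
    if len(sequence) != spec.n_residues:
        raise ValueError(f"sequence length {len(sequence)} != spec residues {spec.n_residues}")
    h1, h2, h3 = spec.helix_lengths
    l1, l2 = spec.loop_lengths
    d = spec.inter_helix_distance
    seqs = {
        "h1": sequence[:h1],
        "l1": sequence[h1:h1 + l1],
        "h2": sequence[h1 + l1:h1 + l1 + h2],
        "l2": sequence[h1 + l1 + h2:h1 + l1 + h2 + l2],
        "h3": sequence[h1 + l1 + h2 + l2:],
    }
    up = np.array([0.0, 0.0, 1.0])
    down = -up if spec.antiparallel else up
    rng = np.random.default_rng(seed)

    for attempt in range(10):
        spins = rng.uniform(0.0, 360.0, size=3) if attempt else np.array([0.0, 120.0, 240.0])
        helix1 = _align_helix(build_helix(seqs["h1"]), up, np.array([0.0, 0.0]),
                              0.0, spins[0])
        top1 = helix1.single_chain().ca_coords()[-1, 2]
        helix2 = _align_helix(build_helix(seqs["h2"]), down, np.array([d, 0.0]),
                              top1, spins[1])
        bot2 = helix2.single_chain().ca_coords()[-1, 2]
        helix3 = _align_helix(build_helix(seqs["h3"]), up,
                              np.array([d / 2.0, d * np.sqrt(3.0) / 2.0]),
                              bot2, spins[2])
        try:
            s = _assemble(spec, seqs, helix1, helix2, helix3, rng)
        except RuntimeError as exc:
            log.info("bundle attempt %d failed (%s); retrying with new spins", attempt, exc)
            continue
        ca = s.single_chain().ca_coords()
        dist = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
        np.fill_diagonal(dist, np.inf)
        off = ~np.eye(len(ca), k=1, dtype=bool) & ~np.eye(len(ca), k=-1, dtype=bool)
        if (dist[off] < 3.0).any():
            log.info("bundle attempt %d produced a Cα clash; retrying", attempt)
            continue
        return s
    raise RuntimeError("could not build a clash-free bundle in 10 attempts")


def _backbone_triple(res: Residue):
    return (res.atom("N").position, res.atom("CA").position, res.atom("C").position)


def _assemble(spec, seqs, helix1, helix2, helix3, rng) -> Structure:
    pieces = []
    for key, helix_prev, helix_next in (("l1", helix1, helix2), ("l2", helix2, helix3)):
        anchor = _backbone_triple(helix_prev.single_chain().residues[-1])
        target = _backbone_triple(helix_next.single_chain().residues[0])
        dih = _close_loop(anchor, target, len(seqs[key]), rng)
        triples = _extend_backbone(anchor, np.concatenate([dih, [bld.HELIX_PHI]]))[:-1]
        pieces.append(triples)

    residues: list[Residue] = []

    def add_helix(h: Structure) -> None:
        for r in h.single_chain():
            residues.append(Residue(r.aa, 0, 0, [Atom(a.name, a.element, a.position.copy())
                                                 for a in r.atoms]))

    def add_loop(triples, seq: str) -> None:
        for aa, (n, ca, c) in zip(seq, triples):
            atoms = [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c)]
            if aa != "G":
                cb = place_atom(c, n, ca, bld.BOND_CA_CB, bld.ANGLE_N_CA_CB, -122.6)
                atoms.append(Atom("CB", "C", cb))
            residues.append(Residue(aa, 0, 0, atoms))

    add_helix(helix1)
    add_loop(pieces[0], seqs["l1"])
    add_helix(helix2)
    add_loop(pieces[1], seqs["l2"])
    add_helix(helix3)

    # renumber and rebuild carbonyl oxygens consistently across junctions
    for i, r in enumerate(residues):
        r.seq_index = i
        r.author_number = i + 1
    for i, r in enumerate(residues):
        n, ca, c = _backbone_triple(r)
        if i + 1 < len(residues):
            nxt = residues[i + 1].atom("N").position
            o = place_atom(nxt, ca, c, bld.BOND_C_O, bld.ANGLE_CA_C_O, 180.0)
        else:
            o = place_atom(n, ca, c, bld.BOND_C_O, bld.ANGLE_CA_C_O, bld.HELIX_PSI + 180.0)
        old = r.atom("O")
        if old is not None:
            old.position = o
        else:
            r.atoms.insert(3, Atom("O", "O", o))
    s = Structure([Chain("A", residues)], title="synthetic three-helix bundle")
    s.validate()
    return s


def helix_residue_ranges(spec: BundleSpec) -> list[range]:
    """seq_index ranges of the three helices of a bundle built from ``spec``."""
    h1, h2, h3 = spec.helix_lengths
    l1, l2 = spec.loop_lengths
    a = range(0, h1)
    b = range(h1 + l1, h1 + l1 + h2)
    c = range(h1 + l1 + h2 + l2, spec.n_residues)
    return [a, b, c]


def interface_outward_split(s: Structure, spec: BundleSpec) -> tuple[list[int], list[int]]:
    """Helix residues facing the bundle core vs facing solvent, by geometry.

    A helix residue faces the interface when its Cβ (Cα for Gly) points
    toward the bundle's central axis rather than away from it.
    """
    chain = s.single_chain()
    ca_all = chain.ca_coords()
    centre_xy = ca_all[:, :2].mean(axis=0)
    interface, outward = [], []
    for rng_ in helix_residue_ranges(spec):
        for i in rng_:
            r = chain.residues[i]
            ca = r.ca.position
            cb = r.atom("CB")
            tip = cb.position if cb is not None else ca
            to_axis = np.array([centre_xy[0] - ca[0], centre_xy[1] - ca[1], 0.0])
            side = tip - ca
            side[2] = 0.0
            if np.dot(side, to_axis) > 0:
                interface.append(i)
            else:
                outward.append(i)
    return interface, outward


def plant_conservation(s: Structure, sasa_result: SasaResult, p: PlantSpec) -> GradeTable:
    """Grade table with a planted conserved surface cluster.

    Exposed residues whose Cα lies within ``p.radius`` of the centre
    residue's Cα receive grades drawn from ``p.planted_grades``; everything
    else draws from 1..background_grade_max.
    """
    chain = s.single_chain()
    exposed = sasa_result.exposed_set()
    if p.centre_residue not in exposed:
        raise ValueError(f"centre residue {p.centre_residue} is not exposed")
    centre_ca = chain.residues[p.centre_residue].ca.position

    def planted_set(radius: float) -> set[int]:
        return {r.seq_index for r in chain
                if r.ca is not None and r.seq_index in exposed
                and np.linalg.norm(r.ca.position - centre_ca) <= radius}

    def detectable(cluster: set[int]) -> bool:
        members = sorted(cluster)
        pos = {i: chain.residues[i].ca.position for i in members}
        for i in members:
            contacts = sum(
                1 for j in members
                if abs(i - j) > 1
                and np.linalg.norm(pos[i] - pos[j]) <= p.detect_radius)
            if contacts > p.min_cluster:
                return True
        return False

    radius = p.radius
    if p.ensure_detectable:
        while radius <= p.max_radius:
            if detectable(planted_set(radius)):
                break
            radius += 1.0
        else:
            raise ValueError(
                f"no detectable cluster around residue {p.centre_residue} "
                f"within {p.max_radius} Å")
        if radius != p.radius:
            log.info("planting radius widened from %.1f to %.1f Å around residue %d",
                     p.radius, radius, p.centre_residue)

    cluster = planted_set(radius)
    rng = np.random.default_rng(p.seed)
    table: GradeTable = {}
    for r in chain:
        if r.ca is None:
            continue
        if r.seq_index in cluster:
            table[r.seq_index] = int(rng.choice(p.planted_grades))
        else:
            table[r.seq_index] = int(rng.integers(1, p.background_grade_max + 1))
    return table


def background_grades(s: Structure, background_grade_max: int = 6,
                      seed: int = 0) -> GradeTable:
    """Grade table with no planted cluster (all grades ≤ background max)."""
    rng = np.random.default_rng(seed)
    return {r.seq_index: int(rng.integers(1, background_grade_max + 1))
            for r in s.single_chain() if r.ca is not None}


def orthonormalize(vectors: np.ndarray) -> np.ndarray:
    """Gram-Schmidt orthonormalization of mode row-vectors."""
    vectors = np.atleast_2d(np.asarray(vectors, float)).copy()
    out = []
    for v in vectors:
        for u in out:
            v = v - np.dot(v, u) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise ValueError("linearly dependent mode vectors")
        out.append(v / nrm)
    return np.array(out)


def build_rod(n_repeats: int, spec: BundleSpec = BundleSpec(), seed: int = 0,
              spacing: float = 30.0):
    """Tandem array of bundles as one chain, emulating a multi-repeat rod.

    Repeat units are built independently (seeded) and placed side by side at
    ``spacing`` Å along x; the chain is renumbered consecutively.  Returns
    ``(structure, repeat_definitions)``.  The junctions between units are not
    covalently modelled — per-repeat surface analyses do not depend on them.
    """
    from .structure import RepeatDefinition

    if n_repeats < 1:
        raise ValueError("need at least one repeat")
    residues: list[Residue] = []
    repeats = []
    for k in range(n_repeats):
        unit = build_bundle(spec, seed=seed + k)
        shifted = unit.transformed(np.eye(3), np.array([k * spacing, 0.0, 0.0]))
        start = len(residues)
        for r in shifted.single_chain():
            residues.append(Residue(r.aa, 0, 0, [Atom(a.name, a.element, a.position.copy())
                                                 for a in r.atoms]))
        repeats.append(RepeatDefinition(f"SR{k + 1}", start, len(residues) - 1))
    for i, r in enumerate(residues):
        r.seq_index = i
        r.author_number = i + 1
    s = Structure([Chain("A", residues)], title=f"synthetic {n_repeats}-repeat rod")
    s.validate()
    return s, repeats


def rigid_body_modes(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3N) of rigid translations and rotations."""
    coords = np.asarray(coords, float)
    n = len(coords)
    centred = coords - coords.mean(axis=0)
    modes = []
    for axis in np.eye(3):
        modes.append(np.tile(axis, n))
    for axis in np.eye(3):
        modes.append(np.cross(axis, centred).reshape(-1))
    return orthonormalize(np.array(modes))


def internal_modes(vectors: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Project rigid translations/rotations out of mode vectors, then
    orthonormalize — planted collective modes should be internal motions,
    otherwise frame superposition absorbs part of them."""
    rigid = rigid_body_modes(coords)
    vectors = np.atleast_2d(np.asarray(vectors, float)).copy()
    for u in rigid:
        vectors = vectors - np.outer(vectors @ u, u)
    return orthonormalize(vectors)


def make_hinge_mode(s: Structure, pivot: int) -> np.ndarray:
    """Displacement field of a small rigid bend about the pivot residue.

    Residues past the pivot rotate rigidly about an axis through the pivot
    Cα perpendicular to the chain's long axis; residues before it stay
    fixed.  Returned as a normalized 3N vector over Cα coordinates.
    """
    chain = s.single_chain()
    ca = chain.ca_coords()
    n = len(ca)
    if not 0 < pivot < n - 1:
        raise ValueError(f"pivot {pivot} must be strictly inside the chain")
    long_axis = principal_axis(ca)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, long_axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    axis = np.cross(long_axis, helper)
    axis /= np.linalg.norm(axis)
    mode = np.zeros((n, 3))
    for i in range(pivot + 1, n):
        mode[i] = np.cross(axis, ca[i] - ca[pivot])
    flat = mode.reshape(-1)
    nrm = np.linalg.norm(flat)
    if nrm < 1e-12:
        raise ValueError("degenerate hinge mode")
    return flat / nrm


def build_ensemble(s: Structure, spec: EnsembleSpec) -> Ensemble:
    """Ensemble of Cα frames: planted sinusoidal modes plus isotropic noise.

    frame_t = ref + Σ_m amplitude_m · sin(2π (m+1) t / n_frames + φ_m) · mode_m
              + Gaussian(0, noise_sigma) per coordinate,
    with the phases φ_m and the noise fixed by the seed.  Each mode runs at
    its own harmonic of the base frequency: harmonics are orthogonal over a
    full period, so the planted modes stay statistically independent and
    PCA can recover them (a single shared frequency would make any two
    mode time courses correlate by the cosine of their phase difference).
    """
    chain = s.single_chain()
    residues = [r for r in chain if r.ca is not None]
    ref = np.array([r.ca.position for r in residues])
    n3 = ref.size
    if spec.modes.shape[1] != n3:
        raise ValueError(f"modes have dimension {spec.modes.shape[1]}, expected {n3}")
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.modes))
    t = np.arange(spec.n_frames)
    frames = np.repeat(ref.reshape(1, -1), spec.n_frames, axis=0)
    for m, (amp, phase) in enumerate(zip(spec.amplitudes, phases)):
        wave = np.sin(2.0 * np.pi * (m + 1) * t / spec.n_frames + phase)
        frames += amp * wave[:, None] * spec.modes[m][None, :]
    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    coords = frames.reshape(spec.n_frames, -1, 3)
    return Ensemble(coords, [r.aa for r in residues], [r.author_number for r in residues])


def ensemble_to_structures(e: Ensemble) -> list[Structure]:
    """Cα-only conformers, e.g. for writing a multi-MODEL PDB."""
    out = []
    for f in range(e.n_frames):
        residues = [Residue(aa, num, i, [Atom("CA", "C", e.coords[f, i])])
                    for i, (aa, num) in enumerate(zip(e.aa, e.author_numbers))]
        out.append(Structure([Chain("A", residues)]))
    return out
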