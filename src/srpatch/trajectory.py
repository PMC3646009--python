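"""Essential-dynamics analysis of Cα coordinate ensembles.

Frames are least-squares superposed (Kabsch) onto an iteratively refined
mean structure, then analysed by: per-residue root mean square fluctuation
(RMSF); principal component analysis of the 3N×3N Cα covariance matrix;
eigenvector subspace overlap between two ensembles (the average square
projection of the first k eigenvectors of one set onto the first k of the
other — 1 for identical essential subspaces); dynamic cross-correlation of
residue displacements; and porcupine export of a chosen mode.

All quantities are mass-unweighted and Cα-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Chain, Residue, Structure

log = logging.getLogger("srpatch")


@dataclass
class Ensemble:
    coords: np.ndarray                      # (n_frames, n_atoms, 3), Å
    aa: list[str] = field(default_factory=list)
    author_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if not self.aa:
            self.aa = ["A"] * self.n_atoms
        if not self.author_numbers:
            self.author_numbers = list(range(1, self.n_atoms + 1))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_structures(cls, structures) -> "Ensemble":
        """Cα ensemble from a list of conformers of the same chain."""
        frames = []
        aa: list[str] = []
        numbers: list[int] = []
        for s in structures:
            chain = s.single_chain()
            residues = [r for r in chain if r.ca is not None]
            frames.append([r.ca.position for r in residues])
            if not aa:
                aa = [r.aa for r in residues]
                numbers = [r.author_number for r in residues]
        return cls(np.asarray(frames), aa, numbers)

    @classmethod
    def from_pdb(cls, path) -> "Ensemble":
        from .io import read_pdb

        return cls.from_structures(read_pdb(path, model_policy="all"))


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, Å²
    eigenvectors: np.ndarray       # (n_modes, 3N), orthonormal rows
    mean_structure: np.ndarray     # (N, 3)
    aa: list[str] = field(default_factory=list)
    author_numbers: list[int] = field(default_factory=list)


@dataclass
class OverlapResult:
    pair_matrix: np.ndarray            # (k, k) of squared inner products
    average_square_projection: float   # in [0, 1]
    best_matches: list[tuple[int, int, float]]  # (i, argmax_j, value)


def kabsch_superpose(mobile: np.ndarray, ref: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` with
    ``aligned = mobile @ rotation.T + translation``; the rotation is proper
    (determinant +1).
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, sing, vt = np.linalg.svd(h)
    if sing[1] < 1e-12:
        raise ValueError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    aligned = mobile @ rot.T + trans
    rmsd = float(np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def superpose_ensemble(e: Ensemble, passes: int = 2) -> Ensemble:
    """Superpose every frame onto an iteratively refined mean structure."""
    coords = e.coords.copy()
    ref = coords[0]
    for _ in range(passes):
        for f in range(e.n_frames):
            rot, trans, _ = kabsch_superpose(coords[f], ref)
            coords[f] = coords[f] @ rot.T + trans
        ref = coords.mean(axis=0)
    return Ensemble(coords, e.aa, e.author_numbers)


def rmsf(e: Ensemble) -> np.ndarray:
    """Per-residue root mean square fluctuation about the mean structure, Å."""
    sup = superpose_ensemble(e)
    mean = sup.coords.mean(axis=0)
    dev = sup.coords - mean[None]
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


def covariance_pca(e: Ensemble) -> PCAResult:
    """Eigen-decomposition of the 3N×3N positional covariance."""
    if e.n_frames <= 3:
        raise ValueError("PCA needs more than 3 frames")
    sup = superpose_ensemble(e)
    x = sup.coords.reshape(sup.n_frames, -1)
    mean = x.mean(axis=0)
    dx = x - mean
    cov = dx.T @ dx / sup.n_frames
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order].T
    n_zero = int((vals < max(1e-12, 1e-10 * vals[0])).sum()) if vals.size else 0
    if n_zero:
        log.info("covariance is rank deficient: %d (near-)zero eigenvalues", n_zero)
    vals = np.clip(vals, 0.0, None)
    return PCAResult(vals, vecs, mean.reshape(-1, 3), sup.aa, sup.author_numbers)


def subspace_overlap(a: PCAResult, b: PCAResult, k: int = 10) -> OverlapResult:
    """Average square projection of a's first k eigenvectors onto b's.

    1 means identical essential subspaces; k/3N is the expectation for two
    unrelated subspaces.
    """
    if a.eigenvectors.shape[1] != b.eigenvectors.shape[1]:
        raise ValueError("eigenvector dimensionalities differ")
    if k > min(len(a.eigenvalues), len(b.eigenvalues)):
        raise ValueError(f"k={k} exceeds the available eigenvectors")
    va = a.eigenvectors[:k]
    vb = b.eigenvectors[:k]
    pair = (va @ vb.T) ** 2
    avg = float(pair.sum() / k)
    best = [(i, int(np.argmax(pair[i])), float(pair[i].max())) for i in range(k)]
    return OverlapResult(pair, avg, best)


def correlated_motions(e: Ensemble, threshold: float = 0.8):
    """Residue pairs with |normalized displacement correlation| above threshold.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩); pairs with |i−j| ≤ 1 are
    excluded; signed correlations are returned, thresholded on magnitude.
    """
    sup = superpose_ensemble(e)
    dev = sup.coords - sup.coords.mean(axis=0)[None]
    inner = np.einsum("fid,fjd->ij", dev, dev) / sup.n_frames
    var = np.diag(inner).copy()
    zero = var < 1e-12
    if zero.any():
        log.warning("%d residues with zero variance skipped in correlation analysis",
                    int(zero.sum()))
    var[zero] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = inner / np.sqrt(var[:, None] * var[None, :])
    pairs = []
    n = sup.n_atoms
    for i in range(n):
        for j in range(i + 2, n):
            c = corr[i, j]
            if np.isfinite(c) and abs(c) > threshold:
                pairs.append((i, j, float(c)))
    return pairs


def mode_structure(p: PCAResult, coords: np.ndarray) -> Structure:
    residues = [
        Residue(aa=aa, author_number=num, seq_index=i,
                atoms=[Atom("CA", "C", xyz)])
        for i, (aa, num, xyz) in enumerate(zip(p.aa, p.author_numbers, coords))
    ]
    return Structure([Chain("A", residues)])


def porcupine_export(p: PCAResult, mode: int, scale: float, path) -> None:
    """Write the mean structure plus a displaced copy along one eigenvector.

    MODEL 1 is the mean Cα structure; MODEL 2 displaces every Cα by
    ``scale`` × its eigenvector component, so the per-atom difference
    vectors are the porcupine quills.
    """
    from .io import write_pdb

    if not 0 <= mode < len(p.eigenvalues):
        raise ValueError(f"mode {mode} out of range")
    disp = p.eigenvectors[mode].reshape(-1, 3)
    mean = p.mean_structure
    write_pdb([mode_structure(p, mean), mode_structure(p, mean + scale * disp)], path)
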