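"""Shared structural data model.

A :class:`Structure` is an ordered collection of chains; each chain an
ordered collection of :class:`Residue`; each residue an ordered collection
of :class:`Atom`.  Residues carry two numbering schemes:

* ``seq_index`` — 0-based, contiguous within a chain; every internal
  computation (contact maps, grade tables, repeat boundaries) uses it.
* ``author_number`` (+ insertion code) — the numbering of the source PDB
  file, retained for reporting because published per-residue results use
  author numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AAS = frozenset(THREE_TO_ONE.values())


class StructureError(ValueError):
    """Invalid structural data (violated invariant, bad slice, ...)."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    aa: str
    author_number: int
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.aa not in STANDARD_AAS and self.aa != "X":
            raise StructureError(f"residue {self.author_number}: unknown amino acid {self.aa!r}")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def resname(self) -> str:
        return ONE_TO_THREE.get(self.aa, "UNK")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def validate(self) -> None:
        got = [r.seq_index for r in self.residues]
        if got != list(range(len(self.residues))):
            raise StructureError(f"chain {self.chain_id}: seq_index not 0-based contiguous")

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinates; residues lacking a Cα are excluded."""
        return np.array([r.ca.position for r in self.residues if r.ca is not None])


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    title: str = ""

    def validate(self) -> None:
        if not self.chains or not any(len(c) for c in self.chains):
            raise StructureError("structure has no residues")
        for c in self.chains:
            c.validate()

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def single_chain(self) -> Chain:
        """The one chain of a single-chain structure (the common SR case)."""
        if len(self.chains) != 1:
            raise StructureError(f"expected a single chain, found {len(self.chains)}")
        return self.chains[0]

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for c in self.chains:
            for r in c:
                for a in r.atoms:
                    yield r, a

    def coords(self) -> np.ndarray:
        return np.array([a.position for _, a in self.iter_atoms()])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with ``x -> R x + t`` applied to every atom."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        chains = []
        for c in self.chains:
            residues = []
            for r in c:
                atoms = [replace(a, position=rotation @ a.position + translation)
                         for a in r.atoms]
                residues.append(replace(r, atoms=atoms))
            chains.append(Chain(c.chain_id, residues))
        return Structure(chains, self.title)


@dataclass(frozen=True)
class RepeatDefinition:
    """One repeat unit, inclusive seq_index boundaries."""

    repeat_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureError(f"repeat {self.repeat_id}: start {self.start} > end {self.end}")

    def __contains__(self, seq_index: int) -> bool:
        return self.start <= seq_index <= self.end


def validate_repeats(repeats: list[RepeatDefinition]) -> None:
    """Repeats in one table must be sorted and non-overlapping."""
    for prev, cur in zip(repeats, repeats[1:]):
        if cur.start <= prev.end:
            raise StructureError(
                f"repeats {prev.repeat_id} and {cur.repeat_id} overlap or are out of order")


def slice_repeat(s: Structure, r: RepeatDefinition) -> Structure:
    """Extract one repeat as a standalone structure.

    seq_index is re-based to 0; author numbering is preserved.
    """
    chain = s.single_chain()
    if r.start < 0 or r.end >= len(chain):
        raise IndexError(
            f"repeat {r.repeat_id} [{r.start}, {r.end}] outside chain of {len(chain)} residues")
    residues = [
        replace(res, seq_index=res.seq_index - r.start)
        for res in chain.residues[r.start:r.end + 1]
    ]
    return Structure([Chain(chain.chain_id, residues)], title=f"{s.title} {r.repeat_id}".strip())
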