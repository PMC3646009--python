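"""Readers and writers for the plain-text formats the pipeline touches.

PDB parsing is delegated to Biopython's :class:`Bio.PDB.PDBParser`; the
results are mapped onto the package's own light-weight data model with the
altloc policy applied explicitly (highest occupancy wins, ties broken by
altloc letter).  HETATM records, waters and hydrogens are dropped: every
analysis downstream runs on heavy protein atoms.

Writing is done with a small fixed-column formatter so that multi-MODEL
ensembles and porcupine exports can be laid out exactly.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .structure import (
    Atom,
    Chain,
    RepeatDefinition,
    Residue,
    Structure,
    THREE_TO_ONE,
    validate_repeats,
)

log = logging.getLogger("srpatch")

GradeTable = dict[int, int]


class PdbParseError(ValueError):
    """A PDB record could not be interpreted (reports the line number)."""


class EmptyInputError(ValueError):
    """Input contains no usable records."""


def _prescan(path: Path) -> int:
    """Validate ATOM coordinate fields line by line; return the ATOM count."""
    n_atom = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if line.startswith("ATOM  "):
                n_atom += 1
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                raise PdbParseError(f"{path}: malformed ATOM record at line {lineno}") from None
    return n_atom


def _pick_altloc(variants: list) -> "object":
    """Spec policy: keep the highest occupancy; ties go to altloc 'A' first."""
    def key(a):
        occ = a.get_occupancy()
        return (-(occ if occ is not None else 1.0), a.get_altloc())
    return sorted(variants, key=key)[0]


def _convert_model(model, title: str) -> Structure:
    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.get_id()
            if hetflag.strip():
                continue  # HETATM (incl. waters)
            aa = THREE_TO_ONE.get(bio_res.get_resname().strip(), "X")
            by_name: dict[str, list] = {}
            for a in bio_res.get_unpacked_list():
                elem = (a.element or "").strip().upper()
                if elem in ("H", "D"):
                    continue
                by_name.setdefault(a.get_name(), []).append(a)
            atoms = []
            for name, variants in by_name.items():
                a = _pick_altloc(variants)
                occ = a.get_occupancy()
                atoms.append(Atom(
                    name=name,
                    element=(a.element or "").strip().upper() or name[0],
                    position=np.asarray(a.get_coord(), dtype=float),
                    occupancy=min(occ if occ is not None else 1.0, 1.0),
                    altloc=a.get_altloc().strip(),
                ))
            if not atoms:
                continue
            residues.append(Residue(
                aa=aa,
                author_number=int(resseq),
                seq_index=len(residues),
                atoms=atoms,
                insertion_code=icode.strip(),
            ))
        if residues:
            chains.append(Chain(bio_chain.id.strip() or "A", residues))
    s = Structure(chains, title=title)
    s.validate()
    return s


def read_pdb(path, model_policy: str = "first"):
    """Read a PDB file.

    Parameters
    ----------
    path:
        PDB file with at least one ATOM record.
    model_policy:
        ``"first"`` returns a single :class:`Structure` (the first MODEL);
        ``"all"`` returns a list with one Structure per MODEL.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    path = Path(path)
    if _prescan(path) == 0:
        raise EmptyInputError(f"{path}: no ATOM records")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = parser.get_structure(path.stem, str(path))
    structures = [_convert_model(m, title=path.stem) for m in bio]
    structures = [s for s in structures if s.n_residues]
    if not structures:
        raise EmptyInputError(f"{path}: no protein residues")
    if model_policy == "first":
        return structures[0]
    return structures


def _format_atom_name(name: str) -> str:
    # Element symbols of one letter start in column 14 (0-based 13).
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3}"


def write_pdb(structures, path) -> None:
    """Write one Structure, or a sequence of them as MODEL/ENDMDL blocks."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    lines: list[str] = []
    for i, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4}")
        serial = 1
        for chain in s.chains:
            for res in chain:
                for a in res.atoms:
                    x, y, z = a.position
                    lines.append(
                        f"ATOM  {serial:>5} {_format_atom_name(a.name)}{(a.altloc or ' '):1}"
                        f"{res.resname:>3} {chain.chain_id[:1]:1}{res.author_number:>4}"
                        f"{(res.insertion_code or ' '):1}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                        f"          {a.element:>2}"
                    )
                    serial += 1
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular inputs


def read_grades_tsv(path) -> GradeTable:
    """Read a per-residue conservation grade table (columns seq_index, grade).

    Grades follow the ConSurf convention: integers 1 (most variable) to
    9 (most conserved).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("seq_index", "grade"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    table: GradeTable = {}
    for row in df.itertuples(index=False):
        grade = int(row.grade)
        if not 1 <= grade <= 9:
            raise ValueError(
                f"{path}: grade {grade} outside 1..9 at seq_index {int(row.seq_index)}")
        table[int(row.seq_index)] = grade
    return table


def write_grades_tsv(table: GradeTable, path) -> None:
    df = pd.DataFrame(sorted(table.items()), columns=["seq_index", "grade"])
    df.to_csv(path, sep="\t", index=False)


def read_repeats_tsv(path) -> list[RepeatDefinition]:
    """Read repeat boundaries (columns repeat_id, start, end; inclusive)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("repeat_id", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    repeats = [RepeatDefinition(str(r.repeat_id), int(r.start), int(r.end))
               for r in df.itertuples(index=False)]
    repeats.sort(key=lambda r: r.start)
    validate_repeats(repeats)
    return repeats


def write_repeats_tsv(repeats: list[RepeatDefinition], path) -> None:
    df = pd.DataFrame([(r.repeat_id, r.start, r.end) for r in repeats],
                      columns=["repeat_id", "start", "end"])
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Sequence-only utility: FASTA id -> sequence string."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
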