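"""Conservation-guided surface patch (putative binding site) detection.

The method combines three per-residue facts — an evolutionary conservation
grade (ConSurf-style 1..9), a buried/exposed class from relative SASA, and
a Cα contact relation — into candidate protein-interaction sites:

* a residue is *conserved* when its grade is ≥ 7;
* residues i, j are in *contact* when |i−j| > 1 and their Cα distance is
  ≤ 10 Å (sequence neighbours never count, even when spatially close);
* a conserved, exposed residue is a *pbs centre* when more than five of
  its contacts are themselves conserved and exposed.

Centres are then counted per repeat unit, and maximal runs of adjacent
repeats that each hold more than five centres are flagged as candidate
interaction regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import GradeTable
from .sasa import SasaResult
from .structure import RepeatDefinition, Structure, validate_repeats

log = logging.getLogger("srpatch")

CONSERVED_GRADE = 7
MIN_NEIGHBOURS = 5          # centre requires strictly more than this
CONTACT_RADIUS = 10.0       # Å
REGION_MIN_PBS = 5          # flagged repeats each need strictly more than this


@dataclass
class ContactMap:
    """Symmetric boolean Cα neighbour relation."""

    matrix: np.ndarray                 # (n, n) bool
    seq_indices: list[int]             # residues included (those with a Cα)
    radius: float = CONTACT_RADIUS

    def index_of(self, seq_index: int) -> int:
        return self.seq_indices.index(seq_index)


@dataclass
class ResidueAnnotation:
    seq_index: int
    aa: str
    author_number: int
    grade: int
    conserved: bool
    burial_class: str
    relative_area: float

    @property
    def eligible(self) -> bool:
        """Conserved and exposed: may be a pbs centre or qualifying neighbour."""
        return self.conserved and self.burial_class == "exposed"


@dataclass
class PbsResult:
    centres: set[int]
    neighbour_counts: dict[int, int]                  # conserved∧exposed -> count
    per_repeat_counts: dict[str, int] = field(default_factory=dict)
    flagged_regions: list[list[str]] = field(default_factory=list)


def build_contact_map(s: Structure, radius: float = CONTACT_RADIUS,
                      inclusive: bool = True) -> ContactMap:
    """Cα contact map: contact iff |i−j| > 1 and d(i,j) ≤ radius.

    ``inclusive=False`` switches the distance comparison to strict (<),
    the alternative reading of the rule.
    """
    chain = s.single_chain()
    included = [r.seq_index for r in chain if r.ca is not None]
    for r in chain:
        if r.ca is None:
            log.warning("residue %s%d has no Cα; excluded from contact map",
                        r.aa, r.author_number)
    coords = np.array([chain.residues[i].ca.position for i in included])
    n = len(included)
    if n == 0:
        return ContactMap(np.zeros((0, 0), bool), [], radius)
    d = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    within = d <= radius if inclusive else d < radius
    idx = np.asarray(included)
    seq_sep = np.abs(idx[:, None] - idx[None, :])
    matrix = within & (seq_sep > 1)
    return ContactMap(matrix, included, radius)


def annotate(s: Structure, grades: GradeTable, sasa_result: SasaResult,
             conserved_grade: int = CONSERVED_GRADE) -> list[ResidueAnnotation]:
    """Merge grades and burial classes into per-residue annotations.

    Residues absent from the grade table are treated as non-conserved
    (grade 1) with a log message.
    """
    out = []
    for r in s.single_chain():
        if r.seq_index in grades:
            grade = grades[r.seq_index]
        else:
            grade = 1
            log.info("residue %s%d missing from grade table; treated as non-conserved",
                     r.aa, r.author_number)
        out.append(ResidueAnnotation(
            seq_index=r.seq_index,
            aa=r.aa,
            author_number=r.author_number,
            grade=grade,
            conserved=grade >= conserved_grade,
            burial_class=sasa_result.burial_class.get(r.seq_index, "buried"),
            relative_area=sasa_result.relative_area.get(r.seq_index, 0.0),
        ))
    return out


def find_pbs(annotations: list[ResidueAnnotation], cm: ContactMap,
             min_neighbours: int = MIN_NEIGHBOURS) -> PbsResult:
    """Detect pbs cluster centres.

    A conserved, exposed residue is a centre when strictly more than
    ``min_neighbours`` of its contact-map neighbours are conserved and
    exposed themselves.
    """
    by_seq = {a.seq_index: a for a in annotations}
    eligible = np.array([by_seq[i].eligible if i in by_seq else False
                         for i in cm.seq_indices])
    counts = cm.matrix.astype(np.int64) @ eligible.astype(np.int64)
    neighbour_counts: dict[int, int] = {}
    centres: set[int] = set()
    for pos, seq_index in enumerate(cm.seq_indices):
        if not eligible[pos]:
            continue
        neighbour_counts[seq_index] = int(counts[pos])
        if counts[pos] > min_neighbours:
            centres.add(seq_index)
    return PbsResult(centres, neighbour_counts)


def count_pbs_per_repeat(result: PbsResult, repeats: list[RepeatDefinition],
                         region_min_pbs: int = REGION_MIN_PBS) -> PbsResult:
    """Count centres per repeat and flag runs of adjacent high-count repeats.

    A flagged region is a maximal run of contiguous repeats each holding
    strictly more than ``region_min_pbs`` centres.  Centres outside every
    repeat go into an "unassigned" bucket.
    """
    validate_repeats(repeats)
    counts = {r.repeat_id: 0 for r in repeats}
    unassigned = 0
    for c in sorted(result.centres):
        for r in repeats:
            if c in r:
                counts[r.repeat_id] += 1
                break
        else:
            unassigned += 1
    if unassigned:
        counts["unassigned"] = unassigned
        log.warning("%d pbs centres fall outside every repeat", unassigned)
    regions: list[list[str]] = []
    run: list[str] = []
    for r in repeats:
        if counts[r.repeat_id] > region_min_pbs:
            run.append(r.repeat_id)
        elif run:
            regions.append(run)
            run = []
    if run:
        regions.append(run)
    result.per_repeat_counts = counts
    result.flagged_regions = regions
    return result


def conserved_burial_split(annotations: list[ResidueAnnotation]) -> tuple[float, float] | None:
    """(buried, exposed) fractions among conserved residues; None if no residue is conserved."""
    conserved = [a for a in annotations if a.conserved]
    if not conserved:
        log.warning("no conserved residues; burial split undefined")
        return None
    n_buried = sum(1 for a in conserved if a.burial_class == "buried")
    frac = n_buried / len(conserved)
    return frac, 1.0 - frac
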