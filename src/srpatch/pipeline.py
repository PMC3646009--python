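"""End-to-end per-repeat analysis: one call from structure + grades +
repeat boundaries (+ optional Z-scores) to a full report.

For every repeat unit the report aggregates helical content and its quality
gate, the optional Z-score reliability class, the fraction of conserved
residues and their buried/exposed split, and the pbs centres found inside
the repeat.  A manifest records the package version and the effective
thresholds so a run can be reproduced exactly; report serialization is
canonicalized (sorted keys, floats rounded to 1e-6) to be byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .conservation import (
    CONSERVED_GRADE,
    CONTACT_RADIUS,
    MIN_NEIGHBOURS,
    REGION_MIN_PBS,
    annotate,
    build_contact_map,
    conserved_burial_split,
    count_pbs_per_repeat,
    find_pbs,
)
from .io import GradeTable, read_grades_tsv, read_pdb, read_repeats_tsv
from .quality import (
    HELICITY_REL_TOL,
    TEMPLATE_AVG_HELICITY,
    ZSCORE_LESS_CUT,
    ZSCORE_VERY_CUT,
    helicity_gate,
    zscore_classify,
)
from .sasa import BURIAL_CUTOFF, SasaParams, sasa
from .secstruct import assign_ss
from .structure import RepeatDefinition, Structure, slice_repeat

log = logging.getLogger("srpatch")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every threshold of the pipeline, defaulting to the published values."""

    burial_cutoff: float = BURIAL_CUTOFF
    conserved_grade: int = CONSERVED_GRADE
    min_neighbours: int = MIN_NEIGHBOURS
    contact_radius: float = CONTACT_RADIUS
    contact_inclusive: bool = True
    region_min_pbs: int = REGION_MIN_PBS
    template_avg_helicity: float = TEMPLATE_AVG_HELICITY
    helicity_rel_tol: float = HELICITY_REL_TOL
    gate_reading: str = "relative"
    zscore_very_cut: float = ZSCORE_VERY_CUT
    zscore_less_cut: float = ZSCORE_LESS_CUT
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RepeatReport:
    repeat_id: str
    helical_content: float
    gate: str
    zscore: float | None = None
    reliability: str | None = None
    percent_conserved: float = 0.0
    conserved_buried_fraction: float | None = None
    conserved_exposed_fraction: float | None = None
    pbs_count: int = 0
    centres: list[dict] = field(default_factory=list)


def _canonical(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def report_json(reports: list[RepeatReport], manifest: dict) -> str:
    payload = {
        "manifest": _canonical(manifest),
        "repeats": [_canonical(dataclasses.asdict(r)) for r in reports],
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def analyze(structure, grades, repeats=None, zscores: dict[str, float] | None = None,
            config: AnalysisConfig = AnalysisConfig()):
    """Run the full per-repeat analysis.

    Parameters
    ----------
    structure:
        A :class:`Structure` or a PDB file path.
    grades:
        A grade table (seq_index -> 1..9) or a TSV path.
    repeats:
        Repeat definitions, a TSV path, or None for one repeat spanning
        the whole chain.
    zscores:
        Optional externally computed knowledge-based Z-scores per repeat_id.

    Returns
    -------
    (reports, manifest): list of :class:`RepeatReport` and a manifest dict.
    """
    if not isinstance(structure, Structure):
        structure = read_pdb(structure)
    if isinstance(grades, (str, Path)):
        grades = read_grades_tsv(grades)
    if repeats is None:
        repeats = [RepeatDefinition("ALL", 0, len(structure.single_chain()) - 1)]
    elif isinstance(repeats, (str, Path)):
        repeats = read_repeats_tsv(repeats)
    zscores = zscores or {}

    warnings: list[str] = []
    if not grades:
        warnings.append("empty grade table: every residue treated as non-conserved")

    params = SasaParams(config.probe_radius, config.n_sphere_points)
    sasa_result = sasa(structure, params, burial_cutoff=config.burial_cutoff)
    contact_map = build_contact_map(structure, config.contact_radius,
                                    inclusive=config.contact_inclusive)
    annotations = annotate(structure, grades, sasa_result, config.conserved_grade)
    pbs = find_pbs(annotations, contact_map, config.min_neighbours)
    pbs = count_pbs_per_repeat(pbs, repeats, config.region_min_pbs)

    chain = structure.single_chain()
    by_seq = {a.seq_index: a for a in annotations}
    reports = []
    for rep in repeats:
        sub = slice_repeat(structure, rep)
        helical = assign_ss(sub).helical_content
        gate = helicity_gate(helical, config.template_avg_helicity,
                             config.helicity_rel_tol, config.gate_reading)
        rep_ann = [by_seq[i] for i in range(rep.start, rep.end + 1) if i in by_seq]
        n = len(rep_ann)
        conserved = [a for a in rep_ann if a.conserved]
        split = conserved_burial_split(rep_ann) if conserved else None
        centres = [
            {"seq_index": i, "author_number": chain.residues[i].author_number,
             "aa": chain.residues[i].aa,
             "neighbour_count": pbs.neighbour_counts.get(i, 0)}
            for i in sorted(pbs.centres) if i in rep
        ]
        report = RepeatReport(
            repeat_id=rep.repeat_id,
            helical_content=helical,
            gate=gate,
            percent_conserved=(len(conserved) / n if n else 0.0),
            conserved_buried_fraction=split[0] if split else None,
            conserved_exposed_fraction=split[1] if split else None,
            pbs_count=pbs.per_repeat_counts.get(rep.repeat_id, 0),
            centres=centres,
        )
        if rep.repeat_id in zscores:
            report.zscore = zscores[rep.repeat_id]
            report.reliability = zscore_classify(
                zscores[rep.repeat_id], config.zscore_very_cut, config.zscore_less_cut)
        reports.append(report)

    cfg = config.to_dict()
    manifest = {
        "tool": "srpatch",
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "n_residues": structure.n_residues,
        "n_repeats": len(repeats),
        "flagged_regions": pbs.flagged_regions,
        "warnings": warnings,
    }
    return reports, manifest
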