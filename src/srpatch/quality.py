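"""Model-quality gates for spectrin-repeat structure models.

Two triage rules are applied to homology models of SR units:

* **Helicity gate.**  Canonical SR template structures average 82% helical
  content; models falling more than 10% (relative) below that average are
  sent back for refinement.  The threshold is therefore 0.9 × 0.82 = 73.8%
  at the defaults.  An absolute-percentage-point reading of the rule is
  selectable but not the default: only the relative reading classifies all
  known outlier models (helicities of 66–73%) as needing refinement.

* **Z-score reliability bands.**  Knowledge-based Z-scores (computed
  externally, e.g. with ProSA) are banded against two empirical control
  distribution centres: canonical SR templates centre at −5.3 and non-SR
  three-helix-bundle decoy models at −3.  Models at or below −5.3 are very
  reliable, at or above −3 less reliable, and reliable in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TEMPLATE_AVG_HELICITY = 0.82
HELICITY_REL_TOL = 0.10
ZSCORE_VERY_CUT = -5.3
ZSCORE_LESS_CUT = -3.0


@dataclass
class QualityReport:
    helical_content: float
    gate: str                       # pass | refine
    zscore: float | None = None
    reliability: str | None = None  # very_reliable | reliable | less_reliable


def helicity_gate(content: float, template_avg: float = TEMPLATE_AVG_HELICITY,
                  rel_tol: float = HELICITY_REL_TOL, reading: str = "relative") -> str:
    """Gate a model's helical content against the template average.

    ``reading="relative"`` (default): refine iff content < (1 − rel_tol) × avg.
    ``reading="absolute"``: refine iff content < avg − rel_tol.
    """
    for name, v in (("content", content), ("template_avg", template_avg)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if reading == "relative":
        threshold = template_avg * (1.0 - rel_tol)
    elif reading == "absolute":
        threshold = template_avg - rel_tol
    else:
        raise ValueError(f"unknown reading {reading!r}")
    return "refine" if content < threshold else "pass"


def zscore_classify(z: float, very_cut: float = ZSCORE_VERY_CUT,
                    less_cut: float = ZSCORE_LESS_CUT) -> str:
    """Band a Z-score into a reliability class; the bands partition the line."""
    if not math.isfinite(z):
        raise ValueError(f"Z-score must be finite, got {z}")
    if not very_cut < less_cut:
        raise ValueError("very_cut must lie below less_cut")
    if z <= very_cut:
        return "very_reliable"
    if z >= less_cut:
        return "less_reliable"
    return "reliable"


def distribution_centre(zs, method: str = "mean", bin_width: float = 0.5) -> float:
    """Centre of a score distribution.

    ``method="mean"`` (default) is the arithmetic mean; ``method="mode"``
    returns the midpoint of the fullest histogram bin (ties to the lower
    bin), matching how plotted score distributions are usually read.
    """
    zs = np.asarray(list(zs), dtype=float)
    if zs.size == 0:
        raise ValueError("empty score collection")
    if method == "mean":
        return float(zs.mean())
    if method == "mode":
        lo = np.floor(zs.min() / bin_width) * bin_width
        nbins = max(1, int(np.ceil((zs.max() - lo) / bin_width)) or 1)
        edges = lo + bin_width * np.arange(nbins + 1)
        hist, _ = np.histogram(zs, bins=edges)
        k = int(np.argmax(hist))
        return float(edges[k] + bin_width / 2.0)
    raise ValueError(f"unknown method {method!r}")


def assess(helical: float, zscore: float | None = None, **gate_kwargs) -> QualityReport:
    """Combined quality report for one model."""
    report = QualityReport(helical, helicity_gate(helical, **gate_kwargs))
    if zscore is not None:
        report.zscore = zscore
        report.reliability = zscore_classify(zscore)
    return report
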