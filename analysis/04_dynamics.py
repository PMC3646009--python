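#!/usr/bin/env python
"""Essential-dynamics analysis of a hinge-bending ensemble.

Builds an ensemble of one synthetic bundle driven by an inter-segment
hinge mode plus thermal-like noise, then runs the full trajectory branch:
RMSF, covariance PCA, replica subspace overlap, residue-motion
correlations and the porcupine export of the leading mode.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from srpatch.synth import (
    BundleSpec,
    EnsembleSpec,
    build_bundle,
    build_ensemble,
    ensemble_to_structures,
    internal_modes,
    make_hinge_mode,
)
from srpatch.io import write_pdb
from srpatch.trajectory import (
    correlated_motions,
    covariance_pca,
    porcupine_export,
    rmsf,
    subspace_overlap,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 0


def main() -> None:
    spec = BundleSpec()
    bundle = build_bundle(spec, seed=SEED)
    pivot = spec.helix_lengths[0] + spec.loop_lengths[0] + spec.helix_lengths[1] + 1
    mode = make_hinge_mode(bundle, pivot)

    replicas = [build_ensemble(bundle, EnsembleSpec(mode, (3.0,), 0.1, 1000, SEED + k))
                for k in range(2)]
    SCRATCH.mkdir(exist_ok=True)
    write_pdb(ensemble_to_structures(replicas[0])[:50], SCRATCH / "ensemble_head.pdb")

    values = rmsf(replicas[0])
    pd.DataFrame({"seq_index": np.arange(len(values)),
                  "rmsf": np.round(values, 4)}).to_csv(
        RESULTS / "rmsf.tsv", sep="\t", index=False)
    print(f"RMSF: mean {values.mean():.3f} Å, max {values.max():.3f} Å "
          f"(C-terminal segment past the hinge at residue {pivot})")

    pcas = [covariance_pca(e) for e in replicas]
    lead_share = pcas[0].eigenvalues[0] / pcas[0].eigenvalues.sum()
    # frame superposition absorbs the rigid-rotation part of a hinge swing,
    # so PCA can only see the internal component of the planted mode
    ca = bundle.single_chain().ca_coords()
    internal_hinge = internal_modes(mode.reshape(1, -1), ca)[0]
    print(f"PCA: leading mode carries {lead_share:.0%} of the variance "
          f"(planted hinge); |dot| with the hinge's internal component "
          f"{abs(np.dot(pcas[0].eigenvectors[0], internal_hinge)):.3f}")

    ov = subspace_overlap(pcas[0], pcas[1], k=10)
    print(f"replica essential-subspace overlap (k=10): "
          f"{ov.average_square_projection:.3f}; "
          f"leading-pair inner product {ov.pair_matrix[0, 0]:.3f}")

    pairs = correlated_motions(replicas[0], threshold=0.8)
    pd.DataFrame(pairs, columns=["i", "j", "correlation"]).to_csv(
        RESULTS / "correlated_motions.tsv", sep="\t", index=False)
    print(f"{len(pairs)} residue pairs with |correlation| > 0.8 "
          "(hinge-coupled segments)")

    porcupine_export(pcas[0], mode=0, scale=5.0, path=RESULTS / "porcupine_mode0.pdb")
    print(f"wrote {RESULTS}/rmsf.tsv, correlated_motions.tsv, porcupine_mode0.pdb")


if __name__ == "__main__":
    main()
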