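#!/usr/bin/env python
"""Directional ANM modes of the four-helix bundle.

Where GNM gives only amplitudes, the ANM Hessian's slow eigenvectors give
per-residue displacement directions — the cones a normal-mode viewer draws.
Writes the spectrum, per-node vectors/magnitudes for the three slowest
modes, and an NMD file under results/anm/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from enmkit import (
    SyntheticSpec,
    build_hessian,
    decompose_anm,
    export_nmd,
    make_structure,
    mode_vectors,
)

OUT = Path("results/anm")
OUT.mkdir(parents=True, exist_ok=True)

built = make_structure(SyntheticSpec(kind="bundle"))
hessian = build_hessian(built.nodes)               # 13 Å ANM cutoff
spectrum = decompose_anm(hessian)

rows = []
for mode in (1, 2, 3):
    vectors, magnitudes = mode_vectors(spectrum, mode)
    lam, _ = spectrum.nonrigid(mode)
    for i in range(built.nodes.n_nodes):
        rows.append({"mode": mode, "eigenvalue": lam, "node_index": i,
                     "dx": vectors[i, 0], "dy": vectors[i, 1],
                     "dz": vectors[i, 2], "magnitude": magnitudes[i]})
pd.DataFrame(rows).to_csv(OUT / "mode_vectors.tsv", sep="\t", index=False)
pd.DataFrame({
    "mode_0based": np.arange(spectrum.n_modes),
    "eigenvalue": spectrum.eigenvalues,
}).to_csv(OUT / "anm_eigenvalues.tsv", sep="\t", index=False)
export_nmd(built.nodes, spectrum, [1, 2, 3], OUT / "bundle_modes.nmd")

print(f"N={built.nodes.n_nodes}, contacts={hessian.contact_count}, "
      f"zero modes={spectrum.n_zero_modes} (6 rigid-body modes expected)")
vectors, magnitudes = mode_vectors(spectrum, 1)
per_helix = magnitudes.reshape(4, -1).mean(axis=1)
print("slowest-mode mean |v| per helix:", np.round(per_helix, 4))
print(f"net translation of mode 1: {np.linalg.norm(vectors.sum(axis=0)):.2e} "
      "(zero — non-rigid modes are orthogonal to the rigid translations)")
print("finding: the slowest mode is a collective distortion spreading "
      "nearly evenly over the four helices (a symmetric bundle has no soft "
      "spot); per-node direction cones are in results/anm/bundle_modes.nmd "
      "for any NMD viewer.")
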