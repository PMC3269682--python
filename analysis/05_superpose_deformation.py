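#!/usr/bin/env python
"""Superpose a 'bound' (bent-helix) conformation onto the free one.

Emulates reading a deformation out of a complex structure: take an ideal
30-residue helix, bend its last third by 30° (the kind of kink a long
central helix develops when a partner binds), then Kabsch-superpose the bent
copy onto the straight one, fitting on the rigid core (fit, drop worst 10%,
refit once). The deviation should localize in the bent third, and the
bend-angle measurement should recover the planted 30°. Writes the
per-residue deviation table and the superposed structure (deviation in the
B-factor column) under results/superpose/.
"""

from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from enmkit import (
    SyntheticSpec,
    deviation_table,
    helix_bend_angle,
    make_structure,
    trimmed_superpose,
    write_pdb,
)

OUT = Path("results/superpose")
OUT.mkdir(parents=True, exist_ok=True)

built = make_structure(SyntheticSpec(kind="helix", n=30))
straight = built.nodes
bent_coords = straight.coords.copy()
pivot = bent_coords[19]
bend = Rotation.from_euler("x", 30, degrees=True).as_matrix()
bent_coords[19:] = (bent_coords[19:] - pivot) @ bend.T + pivot

result = trimmed_superpose(straight.coords, bent_coords, trim_fraction=0.1)
table = deviation_table(straight, result)
table.to_csv(OUT / "deviations.tsv", sep="\t", index=False)

moved = straight.transformed(np.eye(3), np.zeros(3))  # copy with same labels
moved.coords[:] = bent_coords @ result.rotation.T + result.translation
write_pdb(moved, OUT / "bent_superposed.pdb",
          bfactors=result.per_residue_deviation)

angle = helix_bend_angle(bent_coords, (0, 29), split=18)
print(f"core RMSD: {result.rmsd:.4f} Å over {result.fit_selection.size} pairs "
      f"(of {len(result.per_residue_deviation)} matched)")
print(f"deviation: straight core max {table['deviation_A'][:19].max():.3f} Å, "
      f"bent third max {table['deviation_A'][19:].max():.3f} Å")
print(table["class"].value_counts().to_string())
print(f"recovered bend angle: {angle:.2f} deg (planted 30)")
print("finding: the deformation localizes in the bent third; the middle of "
      "the helix stays put while its end swings away — the signature of a "
      "bending long helix.")
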