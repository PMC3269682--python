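#!/usr/bin/env python
"""Slowest GNM mode of the two-domain dumbbell: domains, hinges, profile.

The slowest non-rigid mode splits the structure into two rigid dynamic
domains moving anti-phase about the thin linker; the hinge call (smoothed
local minimum of the normalized squared-fluctuation profile) should land
inside the true linker. Writes the per-node profile, per-segment statistics
and the hinge list under results/gnm/, plus a profile figure.
"""

from pathlib import Path

import pandas as pd

from enmkit import (
    SyntheticSpec,
    build_kirchhoff,
    decompose,
    find_hinges,
    make_structure,
    msf,
    slow_mode_profile,
)
from enmkit.plots import plot_slow_mode_profile

OUT = Path("results/gnm")
OUT.mkdir(parents=True, exist_ok=True)

built = make_structure(SyntheticSpec(kind="dumbbell"))
kirchhoff = build_kirchhoff(built.nodes)           # 7.3 Å cutoff
spectrum = decompose(kirchhoff)
profile, segments = slow_mode_profile(spectrum, built.annotation)
hinges = find_hinges(profile)                      # window 5, prominence 0.05
fluctuations = msf(spectrum, "all")

pd.DataFrame({
    "node_index": built.nodes.node_index,
    "resSeq": built.nodes.residue_numbers,
    "slow_mode_profile": profile,
    "msf_all_modes": fluctuations,
}).to_csv(OUT / "slow_mode_profile.tsv", sep="\t", index=False)
segments.to_csv(OUT / "segment_stats.tsv", sep="\t", index=False)
pd.DataFrame({"hinge_node": hinges.hinge_nodes}).to_csv(
    OUT / "hinges.tsv", sep="\t", index=False
)
plot_slow_mode_profile(profile, OUT / "slow_mode_profile.png",
                       built.annotation, hinges)

print(f"contacts: {kirchhoff.contact_count}, zero modes: {spectrum.n_zero_modes}")
print(segments.to_string(index=False))
print(f"hinge nodes: {hinges.hinge_nodes} (true linker {built.linker_span})")
low = segments.set_index('label')['mean'].idxmin()
print(f"finding: the '{low}' segment has the lowest slow-mode fluctuation — "
      "the two domains move as rigid units about a low-mobility hinge.")
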