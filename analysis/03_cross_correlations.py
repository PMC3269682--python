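#!/usr/bin/env python
"""Cross-correlation map over the 40 slowest modes of the dumbbell.

Positive C_ij = in-phase motion, negative = anti-phase. The two domains
should appear as strongly self-correlated diagonal blocks with a strongly
negative between-domain block — the numerical restatement of the block
structure one reads off a correlation heat map. Writes the matrix, the
segment-averaged block matrix, and a heat map under results/crosscorr/.
"""

from pathlib import Path

import numpy as np

from enmkit import (
    SyntheticSpec,
    block_correlation,
    build_kirchhoff,
    cross_correlation,
    decompose,
    make_structure,
)
from enmkit.plots import plot_correlation_map

OUT = Path("results/crosscorr")
OUT.mkdir(parents=True, exist_ok=True)

built = make_structure(SyntheticSpec(kind="dumbbell"))
spectrum = decompose(build_kirchhoff(built.nodes))
cmap = cross_correlation(spectrum, (1, 40))
blocks = block_correlation(cmap, built.annotation)

np.savetxt(OUT / "crosscorr.tsv", cmap.matrix, delimiter="\t", fmt="%.10g")
blocks.to_csv(OUT / "block_correlation.tsv", sep="\t", float_format="%.10g")
plot_correlation_map(cmap, OUT / "crosscorr.png")

start, count = cmap.mode_range
print(f"modes used: {start}..{start + count - 1} "
      f"(clipped from 40 to the {spectrum.n_nonrigid} available)"
      if count < 40 else f"modes used: {start}..{start + count - 1}")
print(blocks.round(3).to_string())
within = min(blocks.loc["domainA", "domainA"], blocks.loc["domainB", "domainB"])
between = blocks.loc["domainA", "domainB"]
print(f"finding: within-domain mean correlation ({within:.3f}) far exceeds "
      f"the between-domain mean ({between:.3f}) — the domains move "
      "anti-phase as rigid blocks.")
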