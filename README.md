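# enmkit

Coarse-grained elastic network models for protein motion-mode analysis.

Large multi-domain proteins move: domains rotate about hinges, long central
helices bend, and those collective motions — not atomic detail — often decide
whether an autoinhibited protein can open up and expose its binding sites.
`enmkit` computes these motions directly from a Cα trace using the two
standard elastic network models, for structural biologists and modellers who
want domain/hinge/correlation analyses without molecular dynamics:

- **GNM** (Gaussian network model): the N×N Kirchhoff matrix
  Γ (Γ_ij = −1 for Cα pairs within 7.3 Å, diagonal = contact degree) gives
  fluctuation amplitudes ⟨ΔR_i·ΔR_j⟩ ∝ [Γ⁺]_ij, per-mode profiles
  λ_k⁻¹[u_k]_i², and normalized cross-correlations C_ij ∈ [−1, 1].
- **ANM** (anisotropic network model): the 3N×3N Hessian with blocks
  h_ij = −γ outer(d_ij, d_ij)/R_ij² adds *directions* — each slow eigenvector
  is a per-residue displacement field (exported as NMD for mode viewers).
- **Mode analysis**: slowest-mode fluctuation profile with per-domain
  statistics, deterministic hinge detection (smoothed prominent minima), and
  segment-averaged correlation blocks.
- **Superposition**: residue-matched Kabsch alignment with rigid-core
  trimming, per-residue deviations (written into the B-factor column for
  color-by-deviation), and helix bend-angle measurement.
- **Synthetic structures**: chains, rings, ideal helices, helix bundles,
  two-domain dumbbells and gap-numbered chains with known ground truth, so
  the full pipeline is verifiable offline.

See `docs/methods.md` for the models, parameter defaults, and numerical
choices.

## Worked example

```python
import numpy as np
from enmkit import (SyntheticSpec, make_structure, build_kirchhoff, decompose,
                    slow_mode_profile, find_hinges, cross_correlation,
                    block_correlation)

dumbbell = make_structure(SyntheticSpec(kind="dumbbell"))  # 20 + 4 + 20 nodes
spectrum = decompose(build_kirchhoff(dumbbell.nodes))      # 7.3 Å cutoff
profile, segments = slow_mode_profile(spectrum, dumbbell.annotation)
print(segments[["label", "mean"]])
print("hinges:", find_hinges(profile).hinge_nodes)
blocks = block_correlation(cross_correlation(spectrum, (1, 40)),
                           dumbbell.annotation)
print(blocks.round(3))
```

prints

```
     label      mean
0  domainA  0.024359
1   linker  0.006410
2  domainB  0.024359
hinges: [21]
         domainA  linker  domainB
domainA    0.775  -0.031   -0.776
linker    -0.031   0.095   -0.031
domainB   -0.776  -0.031    0.767
```

Read: in the slowest mode the two compact domains fluctuate ~4× more than
the thin linker, the hinge call (node 21) lands inside the true linker
(nodes 20–23), and the 40-mode correlation map shows the two domains moving
as rigid blocks (within-domain mean ≈ +0.77) in anti-phase with each other
(between-domain mean ≈ −0.78).

The same stages run from the shell on any PDB file:

```bash
enmkit synth --kind dumbbell --out dumbbell.pdb
enmkit gnm       --input dumbbell.pdb --outdir out/gnm \
                 --domains domainA:1-20 --domains linker:21-24 --domains domainB:25-44
enmkit crosscorr --input dumbbell.pdb --outdir out/crosscorr --plot
enmkit anm       --input dumbbell.pdb --outdir out/anm
enmkit superpose --ref monomer.pdb --mov complex.pdb --outdir out/superpose
```

Each run echoes its resolved configuration to `config.yaml` and writes a
`manifest.json` with sha256 hashes of every output; identical configurations
re-run to identical hashes.

## Analysis scripts

`analysis/01_build_structures.py` … `05_superpose_deformation.py` are thin
narrative drivers that exercise the pipeline end to end on the synthetic
set — structure generation, slow-mode/hinge analysis, cross-correlation
blocks, directional ANM modes, and deformation-by-superposition — writing
their tables and figures under `results/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch — synthetic structure generation,
GNM slow-mode/hinge/correlation analysis, ANM directional modes, and the
rigid-core superposition with bend-angle recovery — printing a summary and
writing the result file to `--out`.
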