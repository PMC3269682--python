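# Methods

## The models

A protein's Cα trace is treated as a network of nodes joined by identical
harmonic springs whenever two nodes lie within a cutoff distance r_c. Two
coarse-grained models are built on that network:

**Gaussian network model (GNM).** The potential is
V = (γ/2) ΔRᵀ (Γ ⊗ E₃) ΔR, where Γ is the N×N Kirchhoff (contact-graph
Laplacian) matrix: Γ_ij = −1 if i ≠ j and R_ij ≤ r_c, 0 if beyond, and
Γ_ii = the contact degree. Equal-time fluctuations and cross-correlations
are proportional to the Moore–Penrose pseudo-inverse of Γ:
⟨ΔR_i·ΔR_j⟩ = (3k_BT/γ)[Γ⁺]_ij. Eigendecomposing Γ = U Λ Uᵀ resolves this
into modes; the per-mode fluctuation of node i in mode k is
(3k_BT/γ) λ_k⁻¹ [u_k]_i², and the normalized correlation is
C_ij = ⟨ΔR_i·ΔR_j⟩ / (⟨ΔR_i²⟩⟨ΔR_j²⟩)^{1/2} ∈ [−1, 1]. GNM gives amplitudes
only, no directions.

**Anisotropic network model (ANM).** The 3N×3N Hessian of the pairwise
spring energy carries directions. For a contact pair at equilibrium
separation d = r_j − r_i, the off-diagonal 3×3 block is
h_ij = −γ outer(d, d)/|d|², and diagonal blocks are the negated off-diagonal
row sums, which enforces translation invariance to machine precision by
construction. A connected, non-collinear structure has exactly six zero
modes (rigid translations + rotations); each non-rigid eigenvector reshapes
to N displacement 3-vectors.

Low-eigenvalue ("slow") modes are the large-amplitude collective motions
that carry functional rearrangements; high modes are localized noise-like
wiggles.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| GNM cutoff r_c | 7.3 | Å | standard Cα GNM contact radius |
| ANM cutoff | 13 | Å | 7.3 Å Cα networks are under-constrained in 3D (spurious floppy modes); 13 Å is standard Cα-ANM practice. This is the one consequential parameter the two models do not share, and it is logged on every run. |
| spring constant γ | 1 | energy/Å² | uniform for all springs; only sets the overall scale |
| kT_scale (3k_BT/γ) | 1 | — | fluctuations are reported in units of this prefactor, never in joules: all downstream analyses use relative or normalized profiles |
| zero-mode tolerance | 1e-8 × λ_max | — | separates graph-theoretic null space from numerical noise up to N ≈ 1000 |
| correlation mode count | 40 | modes | slow-mode window for the correlation map, improving signal-to-noise over the full spectrum; counted over non-rigid modes (mode 1 = slowest non-rigid), clipped with a warning when fewer exist |
| hinge smoothing window | 5 | nodes | moving average before minima detection |
| hinge prominence | 0.05 | fraction of profile max | minimum dip depth for a hinge call |
| superposition trim | 10% | of matched pairs | one round of fit → drop worst → refit |

Mode numbering facing the user is 1-based over non-rigid modes everywhere
(GNM and ANM); internal storage is 0-based over the full spectrum.

## Numerical choices

- **Contacts** use an inclusive comparison (R_ij ≤ r_c) and are counted in
  integer arithmetic, so Kirchhoff row sums are exactly zero.
- **Eigensolver**: dense symmetric (`numpy.linalg.eigh`), ascending. Fine to
  N ≈ 1000 (3N ≈ 3000 for ANM) on one CPU.
- **Sign convention**: each eigenvector is flipped so its largest-magnitude
  entry is positive (ties: first such entry), making decompositions
  reproducible across solvers. Within a degenerate eigenvalue cluster the
  span, not individual vectors, is the meaningful object; tests compare
  invariant quantities (sums over the degenerate pair, projectors).
- **Hessian row sums**: the diagonal-block construction cancels the
  off-diagonal blocks exactly as accumulated, but re-summing the blocks in a
  different order leaves O(ε) residue; the translation-invariance check is
  therefore at 1e-12, not bitwise zero.
- **Hinge detection** turns the visual reading of a slow-mode profile into a
  deterministic rule: moving-average smoothing (window shrinking at the
  edges), strict local minima with plateau ties resolved to the lower node
  index, prominence measured on the inverted profile and thresholded as a
  fraction of the profile maximum (hence invariance under uniform scaling).
- **Kabsch superposition** uses the SVD construction with the determinant
  correction, so the rotation is always proper even for mirror-image inputs;
  degenerate (collinear) fit selections are rejected. RMSD is reported over
  the fit selection; per-residue deviations over all matched pairs.
- **Helix bend angle**: each half's axis is estimated from second
  differences of its Cα positions, v_i = p_{i−1} + p_{i+1} − 2p_i. For an
  ideal helix these vectors are exactly radial, so the axis is the normal of
  their plane (smallest right singular vector), sign-aligned N→C. A plain
  PCA axis of the raw coordinates — the obvious first choice — is biased by
  the incomplete final turn and misreads a straight 20-residue helix as bent
  by ~8°; the second-difference axis is exact there and degrades gracefully
  with noise. Straight-line halves (zero curvature) fall back to the PCA
  direction.
- **Fit selection for conformer comparison** defaults to one round of
  iterative trimming (fit all, drop the worst 10%, refit once). Anchoring on
  the rigid core keeps a localized deformation from leaking into the global
  fit; the trim fraction is exposed because the right value depends on how
  much of the structure actually moved.
- **Deviation color classes** (low/moderate/high) default to tertiles of the
  observed per-residue deviations; there is no universal Å threshold for
  "high", so the classes are relative unless explicit thresholds are given.

## Synthetic structures: what they emulate and what they don't

The generator builds Cα architectures whose network behaviour is known by
construction: straight chains (3.8 Å virtual bonds), rings (circulant
Kirchhoff matrices with closed-form eigenvalues 2 − 2cos(2πk/n)), ideal
α-helices (rise 1.5 Å, twist 100°, radius 2.3 Å, consecutive Cα ≈ 3.8 Å),
antiparallel helix bundles (axes 9 Å apart, chain-connected), two-domain
dumbbells (20 + 4 + 20 nodes: two FCC-packed blobs at 3.8 Å nearest-neighbour
spacing joined by a thin linker), and gapped chains whose author numbering
skips a run mid-chain, emulating a disordered linker missing from a crystal
structure. The dumbbell linker follows a coarse 3-D spiral (±0.95 Å wobble)
rather than a straight line: a perfectly collinear strut has no transverse
or torsional stiffness in a central-force network and would show spurious
ANM zero modes that no real Cα trace exhibits.

These fixtures have protein-like densities and topologies but are not
protein decoys: no side chains, no secondary-structure irregularity, no
heterogeneous packing. A green test on them establishes that the machinery
is correct (matrices, spectra, oracles, invariances, and the qualitative
domain/hinge/correlation logic on a known two-domain topology) — not that
any particular real protein shows a particular motion. Real-structure
analyses run through the same CLI on standard PDB files.

## Degenerate and edge inputs

Residues without a Cα are skipped with a warning (they are simply absent
from the network, as disordered segments are absent from crystal
structures); alternate locations resolve to the highest-occupancy Cα (ties:
first listed). Zero-contact nodes are allowed but logged, and the zero-mode
count always equals the number of connected components. Coincident nodes
within a contact are an error for ANM (the block formula divides by R²).
Nodes with zero variance over a correlation mode range get zeroed rows with
a unit diagonal, and a warning.

## Known limitations

- Uniform γ only: no distance-weighted or residue-specific springs.
- Residue pairing for superposition is by (chain, resSeq, iCode); there is
  no sequence alignment, so renumbered structures must be renumbered first.
- Dense eigendecomposition only; no sparse/partial solver, so ANM beyond a
  few thousand residues is slow.
- Hinge calls come from the slowest mode's minima only; no multi-mode
  dynamic-domain clustering.
- Whether a published "first 40 modes" convention counts the zero mode is
  ambiguous in general; here the count is always over non-rigid modes, and
  the mode range is explicit in every output.
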