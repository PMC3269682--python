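"""Synthetic Cα architectures with known topology for verifiable ENM tests.

Each generator builds an idealized Cα trace whose elastic-network behaviour
is known in closed form or by construction, standing in for downloaded
crystal structures:

- ``chain``   — straight trace, 3.8 Å virtual-bond spacing.
- ``ring``    — closed loop; its Kirchhoff matrix is circulant, so GNM
  eigenvalues are {2 − 2cos(2πk/n)} when each node touches two neighbours.
- ``helix``   — ideal α-helix (rise 1.5 Å, twist 100°, radius 2.3 Å; chord
  between consecutive Cα ≈ 3.8 Å).
- ``bundle``  — several antiparallel helices, chain-connected, emulating the
  α-helix-bundle domains that dominate large adaptor proteins.
- ``dumbbell``— two compact FCC-packed clusters joined by a thin linker: the
  canonical two-domain-plus-hinge topology. Ground-truth domain segments and
  the true linker range are returned.
- ``gapped_chain`` — a chain whose author residue numbering skips a run
  mid-chain, emulating a disordered linker absent from the coordinates.

All generators are deterministic given the seed; optional isotropic Gaussian
coordinate noise is added after ideal construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .structures import DomainAnnotation, NodeSet

__all__ = ["SyntheticSpec", "SyntheticStructure", "make_structure", "KINDS"]

KINDS = ("chain", "ring", "helix", "bundle", "dumbbell", "gapped_chain")

#: Canonical Cα geometry: virtual-bond length and ideal α-helix parameters.
CA_SPACING = 3.8
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic structure.

    Geometry parameters are in Å (spacing, rise, radius, separations) and
    degrees (twist); counts are residues. ``noise_sd`` is the standard
    deviation of isotropic Gaussian coordinate noise, applied after the
    ideal construction with the given ``seed``.
    """

    kind: str = "chain"
    n: int = 20                       # residues (chain/ring/helix/gapped_chain)
    spacing: float = CA_SPACING
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST_DEG
    radius: float = HELIX_RADIUS
    n_helices: int = 4                # bundle
    helix_length: int = 15            # bundle, residues per helix
    helix_separation: float = 9.0     # bundle, Å between adjacent helix axes
    cluster_size: int = 20            # dumbbell, residues per cluster
    linker_length: int = 4            # dumbbell, residues in the thin linker
    gap_after: int = 15               # gapped_chain, last residue before gap
    gap_size: int = 10                # gapped_chain, missing residue numbers
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"kind must be one of {KINDS}, got {self.kind!r}")
        for name in ("n", "n_helices", "helix_length", "cluster_size",
                     "linker_length"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2, got {getattr(self, name)}")
        for name in ("spacing", "rise", "radius", "helix_separation"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.gap_size < 1:
            raise ValidationError(f"gap_size must be >= 1, got {self.gap_size}")


@dataclass
class SyntheticStructure:
    """A generated node set plus its ground truth."""

    nodes: NodeSet
    annotation: DomainAnnotation
    linker_span: tuple[int, int] | None = None   # node-index range, inclusive
    spec: SyntheticSpec = field(default=None)


def _chain_coords(n: int, spacing: float) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return coords


def _ring_coords(n: int, spacing: float) -> np.ndarray:
    # circumradius such that adjacent chord length equals `spacing`
    radius = spacing / (2.0 * np.sin(np.pi / n))
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
    )


def _helix_coords(n: int, rise: float, twist_deg: float, radius: float) -> np.ndarray:
    theta = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    )


def _bundle_coords(spec: SyntheticSpec) -> np.ndarray:
    """Antiparallel helices on a regular polygon of axes, chain-connected."""
    k = spec.n_helices
    if k == 2:
        centers = np.array([[0.0, 0.0], [spec.helix_separation, 0.0]])
    else:
        circum = spec.helix_separation / (2.0 * np.sin(np.pi / k))
        phi = 2.0 * np.pi * np.arange(k) / k
        centers = np.column_stack([circum * np.cos(phi), circum * np.sin(phi)])
    pieces = []
    for h in range(k):
        helix = _helix_coords(spec.helix_length, spec.rise, spec.twist, spec.radius)
        if h % 2 == 1:          # antiparallel: reverse so chain ends stay close
            helix = helix[::-1].copy()
        helix[:, 0] += centers[h, 0]
        helix[:, 1] += centers[h, 1]
        pieces.append(helix)
    return np.vstack(pieces)


def _fcc_blob(n_points: int, spacing: float) -> np.ndarray:
    """The ``n_points`` FCC lattice sites closest to the origin.

    FCC with nearest-neighbour distance ``spacing`` packs residues at
    protein-core density, so cluster-internal contact counts dwarf the
    linker's at the GNM cutoff.
    """
    # primitive vectors of FCC with cube edge a = spacing * sqrt(2)
    a = spacing * np.sqrt(2.0)
    prim = (a / 2.0) * np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=float)
    reach = int(np.ceil(n_points ** (1 / 3))) + 2
    grid = np.arange(-reach, reach + 1)
    combos = np.array(np.meshgrid(grid, grid, grid)).T.reshape(-1, 3)
    points = combos @ prim
    # deterministic order: distance from origin, then lexicographic
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0],
                        np.linalg.norm(points, axis=1).round(9)))
    return points[order[:n_points]]


def _dumbbell_coords(spec: SyntheticSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Two FCC blobs joined by a thin zigzag linker along x.

    Consecutive nodes along the attachment path stay within one ``spacing``
    of each other, so the whole structure is a single connected component at
    the GNM cutoff while the linker itself stays locally sparse. The linker
    zigzags in y (as real extended Cα traces do) rather than lying on a
    perfect line: a perfectly collinear strut has no transverse or torsional
    stiffness in a pairwise central-force network and would introduce
    spurious ANM zero modes.
    """
    blob = _fcc_blob(spec.cluster_size, spec.spacing)
    order_a = np.lexsort((blob[:, 2], blob[:, 1], blob[:, 0]))
    cluster_a = blob[order_a]
    # attach the linker to cluster A's most +x point (ties: lexsort order)
    a_attach = cluster_a[np.argmax(cluster_a[:, 0])]
    amp = 0.25 * spec.spacing                      # off-axis wobble amplitude
    phase = 2.0 * np.pi / 3.0                      # ~120° per residue
    dx = np.sqrt(spec.spacing**2 - (amp * 2.0 * np.sin(phase / 2.0)) ** 2)
    linker = np.array(
        [a_attach + [(m + 1) * dx,
                     amp * np.cos(m * phase),
                     amp * np.sin(m * phase)]
         for m in range(spec.linker_length)]
    )
    cluster_b = blob[order_a][::-1] * np.array([-1.0, 1.0, 1.0])
    b_attach = cluster_b[np.argmin(cluster_b[:, 0])]
    step = np.array([dx, 0.0, 0.0]) + (a_attach - linker[-1]) * [0.0, 1.0, 1.0]
    cluster_b = cluster_b + (linker[-1] + step - b_attach)
    coords = np.vstack([cluster_a, linker, cluster_b])
    linker_span = (spec.cluster_size, spec.cluster_size + spec.linker_length - 1)
    return coords, linker_span


def make_structure(spec: SyntheticSpec) -> SyntheticStructure:
    """Build the structure described by ``spec``, with ground truth.

    Deterministic given ``spec.seed``; noise (if any) is drawn from an
    isotropic Gaussian after the ideal geometry is laid down.
    """
    linker_span = None
    if spec.kind == "chain":
        coords = _chain_coords(spec.n, spec.spacing)
        resnums = np.arange(1, spec.n + 1)
        segments = [("chain", 0, spec.n - 1)]
    elif spec.kind == "ring":
        coords = _ring_coords(spec.n, spec.spacing)
        resnums = np.arange(1, spec.n + 1)
        segments = [("ring", 0, spec.n - 1)]
    elif spec.kind == "helix":
        coords = _helix_coords(spec.n, spec.rise, spec.twist, spec.radius)
        resnums = np.arange(1, spec.n + 1)
        segments = [("helix", 0, spec.n - 1)]
    elif spec.kind == "bundle":
        coords = _bundle_coords(spec)
        n = coords.shape[0]
        resnums = np.arange(1, n + 1)
        segments = [
            (f"H{h + 1}", h * spec.helix_length, (h + 1) * spec.helix_length - 1)
            for h in range(spec.n_helices)
        ]
    elif spec.kind == "dumbbell":
        coords, linker_span = _dumbbell_coords(spec)
        n = coords.shape[0]
        resnums = np.arange(1, n + 1)
        segments = [
            ("domainA", 0, linker_span[0] - 1),
            ("linker", linker_span[0], linker_span[1]),
            ("domainB", linker_span[1] + 1, n - 1),
        ]
    elif spec.kind == "gapped_chain":
        if not 1 <= spec.gap_after < spec.n:
            raise ValidationError(
                f"gap_after must be in 1..{spec.n - 1}, got {spec.gap_after}"
            )
        coords = _chain_coords(spec.n, spec.spacing)
        resnums = np.arange(1, spec.n + 1)
        resnums[spec.gap_after:] += spec.gap_size
        segments = [
            ("before_gap", 0, spec.gap_after - 1),
            ("after_gap", spec.gap_after, spec.n - 1),
        ]
    else:  # pragma: no cover - guarded by SyntheticSpec validation
        raise ValidationError(f"unknown kind {spec.kind!r}")

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    n = coords.shape[0]
    nodes = NodeSet(
        coords=coords,
        residue_numbers=resnums,
        chain_ids=["A"] * n,
        residue_names=["ALA"] * n,
    )
    annotation = DomainAnnotation(segments=segments, n_nodes=n)
    return SyntheticStructure(
        nodes=nodes, annotation=annotation, linker_span=linker_span, spec=spec
    )
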