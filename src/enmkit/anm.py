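"""Anisotropic network model: 3N×3N Hessian, directional modes, NMD export.

Where the GNM yields only fluctuation amplitudes, the ANM Hessian's
eigenvectors carry per-residue displacement *directions*. For a contact pair
(i, j) at equilibrium separation d = r_j − r_i, the off-diagonal 3×3 block is

    h_ij = −γ · outer(d, d) / |d|²,

and the diagonal blocks are the negated off-diagonal row sums — computed that
way (rather than from an independent formula) so translation invariance holds
exactly in floating point. A connected, non-collinear structure has exactly
six zero modes (three rigid translations, three rotations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateGeometryError, RigidModeError, ValidationError
from .gnm import (
    ANM_CUTOFF_DEFAULT,
    EnmParameters,
    _count_zero_modes,
    _fix_eigenvector_signs,
)
from .structures import NodeSet

logger = logging.getLogger(__name__)

__all__ = [
    "HessianMatrix",
    "AnmSpectrum",
    "anm_parameters",
    "build_hessian",
    "decompose_anm",
    "mode_vectors",
    "export_nmd",
    "parse_nmd",
]


def anm_parameters(cutoff: float = ANM_CUTOFF_DEFAULT, **kwargs) -> EnmParameters:
    """ENM parameters with the ANM default cutoff (13 Å)."""
    return EnmParameters(cutoff=cutoff, **kwargs)


@dataclass
class HessianMatrix:
    """3N×3N second-derivative matrix of the pairwise-spring energy.

    Node i occupies rows/columns 3i..3i+2 in x, y, z order.
    """

    matrix: np.ndarray
    cutoff_used: float
    contact_count: int

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class AnmSpectrum:
    """Hessian eigenpairs, ascending; each non-rigid mode reshapes to N
    displacement 3-vectors. Mode numbering for users is 1-based over
    non-rigid modes, as in the GNM spectrum."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes: int

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n_nonrigid(self) -> int:
        return self.n_modes - self.n_zero_modes

    def nonrigid(self, mode: int) -> tuple[float, np.ndarray]:
        if not 1 <= mode <= self.n_nonrigid:
            raise RigidModeError(
                f"mode {mode} outside the non-rigid range 1..{self.n_nonrigid} "
                f"({self.n_zero_modes} rigid mode(s) excluded)"
            )
        col = self.n_zero_modes + mode - 1
        return float(self.eigenvalues[col]), self.eigenvectors[:, col]


def build_hessian(nodes: NodeSet, params: EnmParameters | None = None) -> HessianMatrix:
    """Assemble the ANM Hessian over all contact pairs within the cutoff.

    The default cutoff is the ANM value (13 Å), not the GNM 7.3 Å; pass
    explicit :class:`EnmParameters` to override. Coincident nodes within a
    contact are rejected (the block formula divides by R_ij²).
    """
    params = params or anm_parameters()
    n = nodes.n_nodes
    dist = squareform(pdist(nodes.coords))
    contacts = dist <= params.cutoff
    np.fill_diagonal(contacts, False)
    pairs = np.argwhere(np.triu(contacts, k=1))
    hessian = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = nodes.coords[j] - nodes.coords[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            raise DegenerateGeometryError(
                f"nodes {i} and {j} are coincident: contact distance is zero"
            )
        block = -params.gamma * np.outer(d, d) / r2
        hessian[3 * i: 3 * i + 3, 3 * j: 3 * j + 3] = block
        hessian[3 * j: 3 * j + 3, 3 * i: 3 * i + 3] = block
        # diagonal blocks as negated row sums: exact translation invariance
        hessian[3 * i: 3 * i + 3, 3 * i: 3 * i + 3] -= block
        hessian[3 * j: 3 * j + 3, 3 * j: 3 * j + 3] -= block
    return HessianMatrix(
        matrix=hessian, cutoff_used=params.cutoff, contact_count=len(pairs)
    )


def decompose_anm(h: HessianMatrix, zero_tol: float = 1e-8) -> AnmSpectrum:
    """Eigendecompose the Hessian (ascending; GNM sign convention).

    Warns when the zero-mode count differs from the six rigid-body modes of
    a connected, non-collinear 3D structure.
    """
    try:
        eigenvalues, eigenvectors = np.linalg.eigh(h.matrix)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"eigendecomposition failed for 3N={h.matrix.shape[0]} Hessian "
            f"(cutoff {h.cutoff_used} Å, {h.contact_count} contacts): {exc}"
        ) from exc
    eigenvectors = _fix_eigenvector_signs(eigenvectors)
    n_zero = _count_zero_modes(eigenvalues, zero_tol)
    if n_zero != 6:
        logger.warning(
            "found %d zero modes (expected 6): geometry is collinear or the "
            "contact graph is disconnected", n_zero,
        )
    return AnmSpectrum(
        eigenvalues=eigenvalues, eigenvectors=eigenvectors, n_zero_modes=n_zero
    )


def mode_vectors(spec: AnmSpectrum, mode: int) -> tuple[np.ndarray, np.ndarray]:
    """Displacement field of one non-rigid mode.

    Returns ``(vectors, magnitudes)``: the unit eigenvector reshaped to
    (N, 3) — one displacement 3-vector per node — and per-node Euclidean
    norms (the cone lengths in mode visualizations).
    """
    _, u = spec.nonrigid(mode)
    vectors = u.reshape(-1, 3)
    magnitudes = np.linalg.norm(vectors, axis=1)
    return vectors, magnitudes


# ---------------------------------------------------------------------------
# NMD export for normal-mode viewers

_NMD_SCALINGS = ("inv_sqrt_eigenvalue", "inv_eigenvalue", "raw")


def _nmd_scale(lam: float, scaling: str) -> float:
    if scaling == "inv_sqrt_eigenvalue":
        return 1.0 / np.sqrt(lam)
    if scaling == "inv_eigenvalue":
        return 1.0 / lam
    if scaling == "raw":
        return 1.0
    raise ValidationError(f"unknown NMD scaling {scaling!r}; use one of {_NMD_SCALINGS}")


def export_nmd(
    nodes: NodeSet,
    spec: AnmSpectrum,
    modes: list[int],
    path,
    name: str = "enmkit_anm",
    scaling: str = "inv_sqrt_eigenvalue",
) -> None:
    """Write modes in NMD format for standard normal-mode viewers.

    Each ``mode`` line carries the 1-based non-rigid mode number, a scale
    factor, and the 3N eigenvector entries. Thermal amplitudes scale as
    1/√λ, the default; 1/λ and raw are available because viewers differ.
    """
    lines = [
        f"name {name}",
        "atomnames " + " ".join(["CA"] * nodes.n_nodes),
        "resnames " + " ".join(nodes.residue_names),
        "resnums " + " ".join(str(int(r)) for r in nodes.residue_numbers),
        "chainids " + " ".join(nodes.chain_ids),
        "coordinates " + " ".join(f"{x:.3f}" for x in nodes.coords.ravel()),
    ]
    if not modes:
        logger.warning("no modes requested; writing a header-only NMD file")
    for m in modes:
        lam, u = spec.nonrigid(m)
        scale = _nmd_scale(lam, scaling)
        lines.append(
            f"mode {m} {scale:.8g} " + " ".join(f"{x:.8g}" for x in u)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_nmd(path) -> dict:
    """Read back an NMD file written by :func:`export_nmd`.

    Returns a dict with ``coordinates`` (N, 3) and ``modes`` mapping mode
    number -> (scale, (N, 3) vector field).
    """
    out: dict = {"modes": {}}
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            key = fields[0]
            if key == "coordinates":
                out["coordinates"] = np.array(fields[1:], dtype=float).reshape(-1, 3)
            elif key == "resnums":
                out["resnums"] = np.array(fields[1:], dtype=int)
            elif key == "mode":
                mode_num = int(fields[1])
                scale = float(fields[2])
                vec = np.array(fields[3:], dtype=float).reshape(-1, 3)
                out["modes"][mode_num] = (scale, vec)
    return out
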