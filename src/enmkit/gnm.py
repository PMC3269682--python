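"""Gaussian network model: Kirchhoff matrix, spectrum, fluctuations,
cross-correlations.

The GNM treats the Cα trace as a network of identical harmonic springs
connecting every residue pair within a cutoff distance r_c (7.3 Å by
default). Its potential is (γ/2) ΔRᵀ (Γ ⊗ E₃) ΔR, with Γ the contact-graph
Laplacian (Kirchhoff matrix). Equal-time fluctuations and correlations are
proportional to the Moore–Penrose pseudo-inverse of Γ; decomposing Γ into
eigenmodes lets the analysis focus on the slow (low-eigenvalue, collective)
modes that carry functional motions.

Eigenvalues are kept γ-scaled (unitless); the physical prefactor 3k_BT/γ is
a single reporting scale ``kT_scale`` and is never evaluated in joules — all
downstream analyses use relative or normalized profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import RigidModeError, ValidationError
from .structures import NodeSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnmParameters",
    "KirchhoffMatrix",
    "GnmSpectrum",
    "CrossCorrelationMap",
    "GNM_CUTOFF_DEFAULT",
    "ANM_CUTOFF_DEFAULT",
    "build_kirchhoff",
    "decompose",
    "mode_fluctuation",
    "msf",
    "cross_correlation",
]

#: GNM contact cutoff in Å.
GNM_CUTOFF_DEFAULT = 7.3
#: ANM contact cutoff in Å. A 7.3 Å Cα network is usually under-constrained
#: in 3D (spurious floppy modes), so the directional model uses the
#: field-standard wider cutoff.
ANM_CUTOFF_DEFAULT = 13.0


@dataclass(frozen=True)
class EnmParameters:
    """Spring-network parameters.

    cutoff   — contact distance r_c in Å (inclusive comparison).
    gamma    — uniform harmonic force constant (energy/Å²); all springs
               identical.
    kT_scale — the 3 k_B T / γ prefactor treated as one opaque reporting
               scale; fluctuation outputs are in units of it.
    """

    cutoff: float = GNM_CUTOFF_DEFAULT
    gamma: float = 1.0
    kT_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cutoff", "gamma", "kT_scale"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray          # (N, N), symmetric, integer-valued
    cutoff_used: float
    contact_count: int          # number of off-diagonal -1 pairs (i < j)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GnmSpectrum:
    """Eigendecomposition of Γ, ascending, with zero-mode bookkeeping.

    ``n_zero_modes`` equals the number of connected components of the contact
    graph. User-facing mode numbering is 1-based over non-rigid modes
    ("mode 1" = slowest non-rigid); internal column k of ``eigenvectors``
    is 0-based over all modes, so mode m lives at column n_zero_modes + m - 1.
    """

    eigenvalues: np.ndarray     # (N,) ascending
    eigenvectors: np.ndarray    # (N, N), columns orthonormal
    n_zero_modes: int

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    @property
    def n_nonrigid(self) -> int:
        return self.n_modes - self.n_zero_modes

    def nonrigid(self, mode: int) -> tuple[float, np.ndarray]:
        """Eigenpair of 1-based non-rigid mode ``mode`` (1 = slowest)."""
        if not 1 <= mode <= self.n_nonrigid:
            raise RigidModeError(
                f"mode {mode} outside the non-rigid range 1..{self.n_nonrigid} "
                f"({self.n_zero_modes} rigid mode(s) excluded)"
            )
        col = self.n_zero_modes + mode - 1
        return float(self.eigenvalues[col]), self.eigenvectors[:, col]


@dataclass
class CrossCorrelationMap:
    """Normalized residue-fluctuation correlation matrix over a mode range.

    Entries lie in [-1, 1]: positive = in-phase motion, negative =
    anti-phase. ``mode_range`` is (first_nonrigid_mode, count), 1-based.
    """

    matrix: np.ndarray
    mode_range: tuple[int, int]


def build_kirchhoff(nodes: NodeSet, params: EnmParameters | None = None) -> KirchhoffMatrix:
    """Contact-graph Laplacian: Γ_ij = -1 iff R_ij ≤ r_c (i ≠ j), diagonal =
    contact degree. Rows sum to exactly 0 (contacts counted in integers)."""
    params = params or EnmParameters()
    dist = squareform(pdist(nodes.coords))
    contacts = (dist <= params.cutoff)
    np.fill_diagonal(contacts, False)
    degree = contacts.sum(axis=1)
    if np.any(degree == 0):
        isolated = np.nonzero(degree == 0)[0]
        logger.warning(
            "%d node(s) with zero contacts at cutoff %.2f Å (graph is "
            "disconnected): node_index %s",
            isolated.size, params.cutoff, isolated.tolist(),
        )
    gamma_matrix = np.diag(degree).astype(float) - contacts.astype(float)
    return KirchhoffMatrix(
        matrix=gamma_matrix,
        cutoff_used=params.cutoff,
        contact_count=int(contacts.sum() // 2),
    )


def _fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (ties: first
    such entry), so decompositions are reproducible across solvers."""
    out = vectors.copy()
    for k in range(out.shape[1]):
        lead = np.argmax(np.abs(out[:, k]))
        if out[lead, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _count_zero_modes(eigenvalues: np.ndarray, zero_tol: float) -> int:
    lam_max = float(eigenvalues[-1])
    if lam_max <= 0:
        return eigenvalues.size
    return int(np.sum(eigenvalues < zero_tol * lam_max))


def decompose(k: KirchhoffMatrix, zero_tol: float = 1e-8) -> GnmSpectrum:
    """Full symmetric eigendecomposition of Γ, ascending eigenvalues.

    ``zero_tol`` is relative to the largest eigenvalue; it separates the
    graph-theoretic zero modes (one per connected component) from numerical
    noise even at N ≈ 1000.
    """
    try:
        eigenvalues, eigenvectors = np.linalg.eigh(k.matrix)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"eigendecomposition failed for N={k.n_nodes} Kirchhoff matrix "
            f"(cutoff {k.cutoff_used} Å, {k.contact_count} contacts): {exc}"
        ) from exc
    eigenvectors = _fix_eigenvector_signs(eigenvectors)
    n_zero = _count_zero_modes(eigenvalues, zero_tol)
    if n_zero != 1:
        logger.warning(
            "contact graph has %d connected components (expected 1)", n_zero
        )
    return GnmSpectrum(
        eigenvalues=eigenvalues, eigenvectors=eigenvectors, n_zero_modes=n_zero
    )


def mode_fluctuation(
    spec: GnmSpectrum, mode_k: int, params: EnmParameters | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node mean-square fluctuation carried by one non-rigid mode.

    Returns ``(values, normalized)``: values_i = kT_scale · λ_k⁻¹ [u_k]_i²,
    and the unit-sum normalized profile used for slow-mode plots.
    ``mode_k`` is 1-based over non-rigid modes.
    """
    params = params or EnmParameters()
    lam, u = spec.nonrigid(mode_k)
    values = params.kT_scale * (u**2) / lam
    total = values.sum()
    normalized = values / total if total > 0 else values
    return values, normalized


def _resolve_mode_range(
    spec: GnmSpectrum, mode_range: tuple[int, int] | str
) -> range:
    """Turn a 1-based non-rigid (start, count) or \"all\" into mode numbers."""
    if mode_range == "all":
        return range(1, spec.n_nonrigid + 1)
    start, count = mode_range
    if start < 1:
        raise RigidModeError(
            f"mode range must start at non-rigid mode >= 1, got {start}"
        )
    if count < 1 or start > spec.n_nonrigid:
        raise ValidationError(
            f"empty effective mode range: start={start}, count={count}, "
            f"{spec.n_nonrigid} non-rigid modes available"
        )
    stop = start + count
    if stop > spec.n_nonrigid + 1:
        logger.warning(
            "mode range (%d, %d) clipped to the %d available non-rigid modes",
            start, count, spec.n_nonrigid,
        )
        stop = spec.n_nonrigid + 1
    return range(start, stop)


def msf(
    spec: GnmSpectrum,
    mode_range: tuple[int, int] | str = "all",
    params: EnmParameters | None = None,
) -> np.ndarray:
    """Mean-square fluctuation per node over a non-rigid mode range.

    With ``"all"`` this equals kT_scale × diag(Γ⁺) (pseudo-inverse of the
    Kirchhoff matrix), the full-basis equal-time fluctuation.
    """
    params = params or EnmParameters()
    modes = _resolve_mode_range(spec, mode_range)
    total = np.zeros(spec.n_modes)
    for m in modes:
        lam, u = spec.nonrigid(m)
        total += (u**2) / lam
    return params.kT_scale * total


def cross_correlation(
    spec: GnmSpectrum, mode_range: tuple[int, int] | str = (1, 40)
) -> CrossCorrelationMap:
    """Normalized cross-correlation map over a non-rigid mode range.

    Raw covariance Σ_k λ_k⁻¹ [u_k]_i [u_k]_j over the range (default: the
    40 slowest non-rigid modes, clipped with a warning when fewer exist),
    normalized to C_ij = cov_ij / sqrt(cov_ii · cov_jj). The γ and kT
    prefactors cancel in the normalization.
    """
    modes = _resolve_mode_range(spec, mode_range)
    cols = [spec.n_zero_modes + m - 1 for m in modes]
    u_sel = spec.eigenvectors[:, cols]
    inv_lam = 1.0 / spec.eigenvalues[cols]
    cov = (u_sel * inv_lam) @ u_sel.T
    var = np.diag(cov).copy()
    dead = var <= 0
    if np.any(dead):
        logger.warning(
            "%d node(s) with zero variance over modes %d..%d; their "
            "correlations set to 0", int(dead.sum()), modes.start, modes.stop - 1,
        )
        var[dead] = 1.0
    scale = 1.0 / np.sqrt(var)
    corr = cov * np.outer(scale, scale)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    return CrossCorrelationMap(
        matrix=corr, mode_range=(modes.start, modes.stop - modes.start)
    )
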