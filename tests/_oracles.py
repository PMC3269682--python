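"""Independent oracles used to cross-check enmkit implementations.

Everything here deliberately avoids the code paths under test: contacts by
brute-force pair enumeration, components by graph traversal (networkx),
fluctuations by a direct Moore–Penrose pseudo-inverse, Hessians by finite
differences of the pairwise-spring energy, and superposition optimality by
Monte-Carlo rotation sampling.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_kirchhoff(coords: np.ndarray, cutoff: float) -> np.ndarray:
    n = len(coords)
    gamma = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(coords[i], coords[j]) <= cutoff:
                gamma[i, j] = gamma[j, i] = -1.0
    for i in range(n):
        gamma[i, i] = -gamma[i].sum()
    return gamma


def component_count(coords: np.ndarray, cutoff: float) -> int:
    n = len(coords)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(coords[i], coords[j]) <= cutoff:
                graph.add_edge(i, j)
    return nx.number_connected_components(graph)


def pinv_msf(kirchhoff: np.ndarray, kT_scale: float = 1.0) -> np.ndarray:
    """diag of the Moore–Penrose pseudo-inverse, via SVD (np.linalg.pinv)."""
    return kT_scale * np.diag(np.linalg.pinv(kirchhoff, hermitian=True))


def pinv_correlation(kirchhoff: np.ndarray) -> np.ndarray:
    """Normalized full pseudo-inverse: the all-mode correlation map."""
    cov = np.linalg.pinv(kirchhoff, hermitian=True)
    scale = 1.0 / np.sqrt(np.diag(cov))
    return cov * np.outer(scale, scale)


def ring_eigenvalues(n: int) -> np.ndarray:
    """Circulant closed form for the nearest-neighbour ring Laplacian."""
    k = np.arange(n)
    return np.sort(2.0 - 2.0 * np.cos(2.0 * np.pi * k / n))


def spring_energy(
    flat_coords: np.ndarray,
    ref_coords: np.ndarray,
    pairs: list[tuple[int, int]],
    gamma: float,
) -> float:
    """Pairwise-spring energy (γ/2) Σ (|r_ij| − |r_ij⁰|)² over fixed contacts."""
    coords = flat_coords.reshape(-1, 3)
    energy = 0.0
    for i, j in pairs:
        r = math.dist(coords[i], coords[j])
        r0 = math.dist(ref_coords[i], ref_coords[j])
        energy += 0.5 * gamma * (r - r0) ** 2
    return energy


def finite_difference_hessian(
    coords: np.ndarray, cutoff: float, gamma: float, h: float = 1e-5
) -> np.ndarray:
    """Central-difference second derivative of the spring energy at the
    input geometry (the contact set is frozen at the equilibrium one)."""
    n = len(coords)
    pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if math.dist(coords[i], coords[j]) <= cutoff
    ]
    x0 = coords.ravel().astype(float)
    dim = x0.size
    hessian = np.zeros((dim, dim))
    for a in range(dim):
        for b in range(a, dim):
            ea = np.zeros(dim); ea[a] = h
            eb = np.zeros(dim); eb[b] = h
            val = (
                spring_energy(x0 + ea + eb, coords, pairs, gamma)
                - spring_energy(x0 + ea - eb, coords, pairs, gamma)
                - spring_energy(x0 - ea + eb, coords, pairs, gamma)
                + spring_energy(x0 - ea - eb, coords, pairs, gamma)
            ) / (4.0 * h * h)
            hessian[a, b] = hessian[b, a] = val
    return hessian


def best_random_rotation_rmsd(
    ref: np.ndarray, mov: np.ndarray, n_rotations: int = 10_000, seed: int = 0
) -> float:
    """Minimum RMSD over random rotations (optimal translation for each):
    a Monte-Carlo lower-bound check on Kabsch optimality."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    rotations = Rotation.random(n_rotations, rng=np.random.default_rng(seed))
    best = np.inf
    for rot in rotations:
        moved = rot.apply(mov_c)
        best = min(best, float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1)))))
    return best


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A random proper rotation and a translation of up to ~50 Å."""
    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.uniform(-50.0, 50.0, 3)
    return rotation, translation
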