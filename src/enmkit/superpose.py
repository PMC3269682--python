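"""Rigid superposition of conformations and deformation measures.

Comparing a bound (complex) conformation with the free monomer requires
pairing residues, finding the least-squares optimal rigid transform (Kabsch,
with the determinant correction that excludes reflections), and reading the
deformation off the per-residue deviations that remain. Fitting on a
low-deviation rigid core — one round of trim-and-refit — keeps a localized
deformation (e.g. a bent central helix) from leaking into the global fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, ValidationError
from .structures import NodeSet

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "match_by_residue",
    "kabsch_superpose",
    "trimmed_superpose",
    "helix_bend_angle",
    "deviation_table",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping the mobile set onto the reference.

    ``rotation`` is a proper rotation (det +1); applying
    ``mov @ rotation.T + translation`` superposes the mobile coordinates.
    ``rmsd`` is over the fit selection; ``per_residue_deviation`` covers all
    matched pairs after the transform.
    """

    rotation: np.ndarray            # (3, 3)
    translation: np.ndarray         # (3,)
    rmsd: float                     # Å, over fit_selection
    per_residue_deviation: np.ndarray   # Å, all matched pairs
    matched_pairs: list[tuple[int, int]]
    fit_selection: np.ndarray       # indices into matched_pairs used for the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def match_by_residue(ref: NodeSet, mov: NodeSet) -> tuple[list[tuple[int, int]], dict]:
    """Pair nodes of two conformations by (chain, resSeq, iCode).

    Returns the matched (ref_node_index, mov_node_index) list in reference
    order and a report of unmatched residues on each side. No sequence
    alignment is attempted: consistent author numbering is assumed.
    """
    mov_lookup: dict[tuple[str, int, str], int] = {}
    for j, key in enumerate(mov.residue_keys()):
        mov_lookup.setdefault(key, j)
    pairs = []
    unmatched_ref = []
    used = set()
    for i, key in enumerate(ref.residue_keys()):
        j = mov_lookup.get(key)
        if j is None:
            unmatched_ref.append(key)
        else:
            pairs.append((i, j))
            used.add(j)
    unmatched_mov = [
        key for j, key in enumerate(mov.residue_keys()) if j not in used
    ]
    if not pairs:
        raise ValidationError(
            "no residues in common between the two structures "
            "(disjoint chain/residue numbering)"
        )
    if unmatched_ref or unmatched_mov:
        logger.info(
            "matched %d pairs; %d reference and %d mobile residues unmatched",
            len(pairs), len(unmatched_ref), len(unmatched_mov),
        )
    return pairs, {"unmatched_ref": unmatched_ref, "unmatched_mov": unmatched_mov}


def _kabsch_rotation(mov_c: np.ndarray, ref_c: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimizing ||R·mov_c − ref_c|| (centered)."""
    cov = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] + s[2] * d <= 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "fit selection is collinear or degenerate: rotation is not unique"
        )
    correction = np.diag([1.0, 1.0, d])
    return vt.T @ correction @ u.T


def kabsch_superpose(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    fit_selection: np.ndarray | None = None,
    matched_pairs: list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of matched coordinate lists.

    ``ref_coords`` and ``mov_coords`` are (M, 3) arrays in matched order.
    The transform is fitted on ``fit_selection`` (indices into the matched
    list; default all pairs, which must contain >= 3 non-collinear points);
    per-residue deviations are then reported for ALL matched pairs.
    """
    ref_coords = np.asarray(ref_coords, dtype=float)
    mov_coords = np.asarray(mov_coords, dtype=float)
    if ref_coords.shape != mov_coords.shape or ref_coords.ndim != 2:
        raise ValidationError(
            f"matched coordinate lists must share shape (M, 3); got "
            f"{ref_coords.shape} vs {mov_coords.shape}"
        )
    m = ref_coords.shape[0]
    if fit_selection is None:
        fit_selection = np.arange(m)
    fit_selection = np.asarray(fit_selection, dtype=int)
    if fit_selection.size < 3:
        raise DegenerateGeometryError(
            f"need >= 3 pairs in the fit selection, got {fit_selection.size}"
        )
    ref_fit = ref_coords[fit_selection]
    mov_fit = mov_coords[fit_selection]
    ref_cent = ref_fit.mean(axis=0)
    mov_cent = mov_fit.mean(axis=0)
    rotation = _kabsch_rotation(mov_fit - mov_cent, ref_fit - ref_cent)
    translation = ref_cent - rotation @ mov_cent
    moved = mov_coords @ rotation.T + translation
    deviations = np.linalg.norm(moved - ref_coords, axis=1)
    rmsd = float(np.sqrt(np.mean(deviations[fit_selection] ** 2)))
    if matched_pairs is None:
        matched_pairs = [(i, i) for i in range(m)]
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd=rmsd,
        per_residue_deviation=deviations,
        matched_pairs=matched_pairs,
        fit_selection=fit_selection,
    )


def trimmed_superpose(
    ref_coords: np.ndarray,
    mov_coords: np.ndarray,
    trim_fraction: float = 0.1,
    matched_pairs: list[tuple[int, int]] | None = None,
) -> SuperpositionResult:
    """Superpose on the rigid core: fit all pairs, drop the worst
    ``trim_fraction``, refit once.

    With a localized deformation (one bent helix, one displaced loop) a
    whole-molecule fit smears the deviation everywhere; anchoring the fit on
    the low-deviation core concentrates it where the structure actually
    moved.
    """
    if not 0 <= trim_fraction < 1:
        raise ValidationError(f"trim_fraction must be in [0, 1), got {trim_fraction}")
    first = kabsch_superpose(ref_coords, mov_coords, matched_pairs=matched_pairs)
    m = len(first.per_residue_deviation)
    n_drop = int(np.ceil(trim_fraction * m))
    if n_drop == 0 or m - n_drop < 3:
        return first
    order = np.argsort(first.per_residue_deviation, kind="stable")
    keep = np.sort(order[: m - n_drop])
    return kabsch_superpose(
        ref_coords, mov_coords, fit_selection=keep, matched_pairs=matched_pairs
    )


def _half_axis(half: np.ndarray) -> np.ndarray:
    """Helix axis of one half, sign-aligned to the N→C direction."""
    if half.shape[0] < 4:
        raise DegenerateGeometryError(
            f"helix half with {half.shape[0]} residues; need >= 4 "
            "for an axis fit"
        )
    second_diff = half[:-2] + half[2:] - 2.0 * half[1:-1]
    span = np.linalg.norm(half - half.mean(axis=0), axis=1).max()
    if np.linalg.norm(second_diff, axis=1).max() < 1e-9 * max(span, 1.0):
        # straight segment: no curvature signal, fall back to PCA
        centered = half - half.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    else:
        _, _, vt = np.linalg.svd(second_diff, full_matrices=True)
        axis = vt[-1]        # normal of the plane of radial vectors
    if axis @ (half[-1] - half[0]) < 0:
        axis = -axis
    return axis


def helix_bend_angle(
    nodes: NodeSet | np.ndarray,
    helix_range: tuple[int, int],
    split: int,
) -> float:
    """Bend angle (degrees) between the two halves of a helix.

    Each half's axis comes from the second differences of its Cα positions:
    for an ideal helix, v_i = p_{i-1} + p_{i+1} − 2 p_i points exactly
    radially, so the axis is the normal of the plane the v_i span (smallest
    principal direction of the stacked v_i). This is exact for ideal helices
    of any length ≥ 4 and degrades gracefully with noise; for degenerate
    (straight-line) halves, where all v_i vanish, the dominant principal
    direction of the centered coordinates is used instead. Axes are
    sign-aligned to the N→C chain direction; the bend is the angle between
    them, in [0°, 180°). Both halves need at least 4 residues.
    """
    coords = nodes.coords if isinstance(nodes, NodeSet) else np.asarray(nodes, float)
    start, end = helix_range
    if not (0 <= start < split < end < coords.shape[0]):
        raise ValidationError(
            f"need start < split < end within 0..{coords.shape[0] - 1}; "
            f"got start={start}, split={split}, end={end}"
        )
    halves = (coords[start: split + 1], coords[split + 1: end + 1])
    axes = [_half_axis(half) for half in halves]
    cosine = float(np.clip(axes[0] @ axes[1], -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosine)))
    return angle if angle < 180.0 else 0.0


def deviation_table(
    ref: NodeSet, result: SuperpositionResult, thresholds: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Per-residue deviation table with low/moderate/high classes.

    ``thresholds`` are the (low->moderate, moderate->high) boundaries in Å;
    by default they are the tertiles of the observed deviations, so the
    classes are the familiar green/yellow/red thirds of a color-by-RMSD view.
    """
    dev = result.per_residue_deviation
    if thresholds is None:
        thresholds = tuple(np.quantile(dev, [1 / 3, 2 / 3]))
    lo, hi = thresholds
    classes = np.where(dev <= lo, "low", np.where(dev <= hi, "moderate", "high"))
    ref_idx = [p[0] for p in result.matched_pairs]
    in_fit = np.zeros(len(dev), dtype=bool)
    in_fit[result.fit_selection] = True
    return pd.DataFrame(
        {
            "ref_node_index": ref_idx,
            "chain": [ref.chain_ids[i] for i in ref_idx],
            "resSeq": [int(ref.residue_numbers[i]) for i in ref_idx],
            "deviation_A": dev,
            "class": classes,
            "in_fit": in_fit,
        }
    )
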