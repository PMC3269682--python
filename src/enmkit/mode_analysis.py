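"""Slow-mode analyses: domain fluctuation profiles, hinge detection, and
block-averaged cross-correlations.

The slowest non-rigid GNM mode partitions a protein into dynamic domains:
rigid units carry high squared-fluctuation plateaus and the hinges about
which they move sit at low-fluctuation local minima. Reading domain
boundaries "by eye" off a profile is made deterministic here via
moving-average smoothing plus a prominence threshold on local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import peak_prominences

from .errors import ValidationError
from .gnm import EnmParameters, GnmSpectrum, CrossCorrelationMap, mode_fluctuation
from .structures import DomainAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "HingeReport",
    "slow_mode_profile",
    "find_hinges",
    "block_correlation",
    "smooth_profile",
]

#: Default smoothing window (nodes) and prominence fraction for hinge calls.
HINGE_WINDOW_DEFAULT = 5
HINGE_PROMINENCE_DEFAULT = 0.05


@dataclass
class HingeReport:
    """Hinge residues called from a slow-mode fluctuation profile.

    Every hinge node is a local minimum of the smoothed profile whose
    prominence is at least ``min_prominence`` × max(profile); the list is
    sorted ascending by node index.
    """

    hinge_nodes: list[int]
    profile_used: np.ndarray        # the (raw) normalized profile analysed
    smoothed_profile: np.ndarray
    window: int
    min_prominence: float


def slow_mode_profile(
    spec: GnmSpectrum,
    annotation: DomainAnnotation | None = None,
    params: EnmParameters | None = None,
    mode: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Normalized squared-fluctuation profile of a slow mode, per segment.

    Returns the unit-sum profile and a table with one row per annotated
    segment (label, start, end, n_nodes, mean, median, max of the profile),
    supporting statements like "domain means high, hinge low". With no
    annotation the table holds a single whole-chain row.
    """
    _, profile = mode_fluctuation(spec, mode, params)
    if annotation is None:
        annotation = DomainAnnotation(
            segments=[("all", 0, profile.size - 1)], n_nodes=profile.size
        )
    rows = []
    for label, start, end in annotation.segments:
        seg = profile[start: end + 1]
        rows.append(
            {
                "label": label,
                "start": start,
                "end": end,
                "n_nodes": end - start + 1,
                "mean": float(seg.mean()),
                "median": float(np.median(seg)),
                "max": float(seg.max()),
            }
        )
    return profile, pd.DataFrame(rows)


def smooth_profile(profile: np.ndarray, window: int) -> np.ndarray:
    """Moving average with a window that shrinks symmetrically at the edges."""
    half = window // 2
    n = profile.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = profile[lo:hi].mean()
    return out


def _local_minima(x: np.ndarray) -> list[int]:
    """Strict local minima; plateaus count once, at their lowest-index node."""
    minima = []
    n = x.size
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        # plateau x[i..j]; a minimum needs strict descent on both sides
        if x[i - 1] > x[i] and j + 1 < n and x[j + 1] > x[i]:
            minima.append(i)
        i = j + 1
    return minima


def find_hinges(
    profile: np.ndarray,
    window: int = HINGE_WINDOW_DEFAULT,
    prominence: float = HINGE_PROMINENCE_DEFAULT,
) -> HingeReport:
    """Call hinge nodes as prominent local minima of the smoothed profile.

    ``window`` is an odd moving-average width in nodes; ``prominence`` is the
    minimum dip depth as a fraction of the profile maximum, so the call is
    invariant under uniform scaling of the profile. Plateau ties resolve to
    the lower node index.
    """
    profile = np.asarray(profile, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    if window > profile.size:
        raise ValidationError(
            f"window {window} exceeds profile length {profile.size}"
        )
    if not 0 <= prominence < 1:
        raise ValidationError(f"prominence must be in [0, 1), got {prominence}")

    smoothed = smooth_profile(profile, window)
    candidates = _local_minima(smoothed)
    threshold = prominence * float(smoothed.max())
    hinges = []
    if candidates:
        proms = peak_prominences(-smoothed, candidates)[0]
        hinges = [
            int(c) for c, p in zip(candidates, proms) if p >= threshold
        ]
    return HingeReport(
        hinge_nodes=sorted(hinges),
        profile_used=profile,
        smoothed_profile=smoothed,
        window=window,
        min_prominence=prominence,
    )


def block_correlation(
    cmap: CrossCorrelationMap, annotation: DomainAnnotation
) -> pd.DataFrame:
    """Segment×segment mean cross-correlations.

    Entry (a, b) is the mean of C_ij over i ∈ a, j ∈ b; diagonal blocks
    average i ≠ j pairs only (a single-node segment yields NaN there, with a
    warning). This restates a correlation map's block structure numerically:
    rigid domains show high within-block means and anti-correlated domain
    pairs show negative between-block means.
    """
    matrix = cmap.matrix
    labels = annotation.labels
    if annotation.n_nodes != matrix.shape[0]:
        raise ValidationError(
            f"annotation covers {annotation.n_nodes} nodes but the map has "
            f"{matrix.shape[0]}"
        )
    out = np.zeros((len(labels), len(labels)))
    for a, (la, sa, ea) in enumerate(annotation.segments):
        for b, (lb, sb, eb) in enumerate(annotation.segments):
            if ea < sa or eb < sb:
                raise ValidationError(f"empty segment in annotation: {la}, {lb}")
            block = matrix[sa: ea + 1, sb: eb + 1]
            if a == b:
                n = block.shape[0]
                if n < 2:
                    logger.warning(
                        "segment %r has a single node; its diagonal block mean "
                        "is undefined (NaN)", la,
                    )
                    out[a, b] = np.nan
                else:
                    out[a, b] = (block.sum() - np.trace(block)) / (n * (n - 1))
            else:
                out[a, b] = block.mean()
    return pd.DataFrame(out, index=labels, columns=labels)
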