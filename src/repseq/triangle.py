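"""Triangle (barycentric) analysis of clonal-group tissue distribution.

Each clonal group's clonotypes are attributed to the compartment of
observation (tumor / LN / PBMC, three LNs, or three tumor fragments); the
three compartment shares sum to 1 and place the group inside a triangle
whose vertices are the compartments. Groups are labeled by dominant isotype
(a strict >60% clonotype share, else "mixed"). Eccentricity — unequal
contribution of the compartments — is tested per group with a chi-squared
goodness-of-fit of the counts against the uniform expectation (df = 2), and
the set of groups is summarized by the unweighted mean center plus a pooled
test on summed counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .io import Clonotype
from .lineage import ClonalLineage

__all__ = ["TrianglePoint", "triangle_points", "dominant_isotype", "center_and_test"]

DOMINANT_CUTOFF = 0.6
LOW_COUNT_SIZE = 6  # below this the uniform expectation drops under 2 per cell


@dataclass(frozen=True)
class TrianglePoint:
    lineage_id: str
    counts: tuple[int, int, int]
    coords: tuple[float, float, float]
    dominant_isotype: str
    size: int
    chi2: float
    p: float
    low_count: bool


def dominant_isotype(members: Sequence[Clonotype], cutoff: float = DOMINANT_CUTOFF) -> str:
    """Isotype whose clonotype share strictly exceeds ``cutoff``, else "mixed"."""
    if not members:
        raise ValueError("empty clonal group")
    counts: dict[str, int] = {}
    for m in members:
        counts[m.isotype] = counts.get(m.isotype, 0) + 1
    iso, best = max(counts.items(), key=lambda t: (t[1], t[0]))
    return iso if best / len(members) > cutoff else "mixed"


def _point(
    lineage_id: str, members: Sequence[Clonotype], counts: np.ndarray, cutoff: float
) -> TrianglePoint | None:
    size = int(counts.sum())
    if size == 0:
        return None
    coords = counts / size
    chi2, p = stats.chisquare(counts)
    return TrianglePoint(
        lineage_id=lineage_id,
        counts=tuple(int(c) for c in counts),
        coords=tuple(float(c) for c in coords),
        dominant_isotype=dominant_isotype(members, cutoff),
        size=size,
        chi2=float(chi2),
        p=float(p),
        low_count=size < LOW_COUNT_SIZE,
    )


def triangle_points(
    lineages: Iterable[ClonalLineage],
    compartment_of: Callable[[Clonotype], str | Sequence[str]],
    compartments: tuple[str, str, str],
    cutoff: float = DOMINANT_CUTOFF,
) -> list[TrianglePoint]:
    """One barycentric point per clonal group.

    ``compartment_of`` maps a member clonotype to its compartment label (or
    to several labels when the clonotype was observed in more than one
    compartment; it then contributes one count to each). Members mapping
    outside the three ``compartments`` are ignored.
    """
    points: list[TrianglePoint] = []
    index = {c: i for i, c in enumerate(compartments)}
    for lin in lineages:
        counts = np.zeros(3, dtype=int)
        for m in lin.members:
            labels = compartment_of(m)
            if isinstance(labels, str):
                labels = [labels]
            for lab in labels:
                if lab in index:
                    counts[index[lab]] += 1
        pt = _point(lin.lineage_id, lin.members, counts, cutoff)
        if pt is not None:
            points.append(pt)
    return points


def center_and_test(points: Sequence[TrianglePoint]) -> dict:
    """Unweighted mean center of the points plus a pooled chi-squared test.

    The center is the plain mean of the barycentric coordinates (not
    weighted by group size). The pooled test sums the per-group counts and
    asks whether the three compartments contributed equally overall.
    """
    if not points:
        raise ValueError("no triangle points")
    coords = np.array([p.coords for p in points])
    center = coords.mean(axis=0)
    pooled = np.array([p.counts for p in points]).sum(axis=0)
    chi2, p = stats.chisquare(pooled)
    return {
        "center": tuple(float(c) for c in center),
        "chi2": float(chi2),
        "p": float(p),
        "n_groups": len(points),
        "pooled_counts": tuple(int(c) for c in pooled),
    }
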