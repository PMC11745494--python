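"""Clonality and isotype-composition summaries.

Clonality is 1 minus the normalized Shannon–Wiener index,
``1 − H / ln(richness)`` with ``H = −Σ f_k ln f_k``: 0 for a perfectly even
repertoire, approaching 1 as a single clone dominates. A single-clonotype
repertoire is maximally clonal by convention (1.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import Repertoire

__all__ = ["DiversitySummary", "clonality", "shannon", "isotype_fractions", "summarize"]


def shannon(rep: Repertoire) -> float:
    """Shannon entropy H = −Σ f ln f over renormalized frequencies (nats)."""
    if len(rep) == 0:
        raise ValueError("empty repertoire")
    total = sum(c.frequency for c in rep.clonotypes)
    return -sum(
        (c.frequency / total) * math.log(c.frequency / total)
        for c in rep.clonotypes
        if c.frequency > 0
    )


def clonality(rep: Repertoire) -> float:
    """1 − H/ln(richness); 1.0 for a single-clonotype repertoire."""
    if len(rep) == 0:
        raise ValueError("empty repertoire")
    if len(rep) == 1:
        return 1.0
    return 1.0 - shannon(rep) / math.log(len(rep))


def isotype_fractions(rep: Repertoire, weight: str = "umi") -> dict[str, float]:
    """Isotype composition summing to 1.

    ``weight="umi"`` uses frequency mass (the share of the repertoire each
    isotype accounts for); ``weight="clonotype"`` counts clonotypes.
    """
    if weight not in {"umi", "clonotype"}:
        raise ValueError("weight must be 'umi' or 'clonotype'")
    masses: dict[str, float] = {}
    for c in rep.clonotypes:
        w = c.frequency if weight == "umi" else 1.0
        masses[c.isotype] = masses.get(c.isotype, 0.0) + w
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("repertoire has zero total weight")
    return {iso: m / total for iso, m in masses.items()}


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    clonality: float
    shannon: float
    richness: int
    isotype_fractions: dict


def summarize(rep: Repertoire, weight: str = "umi") -> DiversitySummary:
    return DiversitySummary(
        sample_id=rep.sample_id,
        clonality=clonality(rep),
        shannon=shannon(rep),
        richness=len(rep),
        isotype_fractions=isotype_fractions(rep, weight=weight),
    )
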