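"""Pairwise repertoire-overlap statistics: F2, D, and R.

Overlap metrics depend on repertoire richness, so comparisons are normalized
by restricting each sample to the same number of top most frequent clonotypes
of each isotype (default N = 109) before computing the metric.

* F2 — clonotype-wise sum of geometric-mean frequencies of shared clonotypes,
  Σ sqrt(f_ik · f_jk), after renormalizing each (restricted) repertoire to
  sum 1. Weighted overlap; 1 iff the frequency vectors coincide.
* D — d_ij / (d_i · d_j): shared-clonotype count over the product of the two
  diversities (clonotype richnesses). Frequency-free overlap.
* R — Pearson correlation of log10 frequencies of shared clonotypes;
  undefined (flagged) below 3 shared clonotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io import Repertoire

__all__ = ["OverlapResult", "top_n_by_isotype", "f2", "d_metric", "r_metric", "overlap_table"]

DEFAULT_TOP_N = 109


@dataclass(frozen=True)
class OverlapResult:
    sample_i: str
    sample_j: str
    metric: str
    value: float | None
    n_shared: int
    n_top_used: int
    isotype: str = "all"
    undefined: bool = False


def top_n_by_isotype(
    rep: Repertoire, n: int = DEFAULT_TOP_N, isotype: str | None = None
) -> tuple[Repertoire, bool]:
    """The n most frequent clonotypes (of one isotype if given).

    Ties are broken deterministically by (umi_count desc, cdr3_nt asc).
    Returns (restricted repertoire, shortfall flag); the flag is True when
    fewer than n clonotypes were available.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = [c for c in rep.clonotypes if isotype is None or c.isotype == isotype]
    pool.sort(key=lambda c: (-c.frequency, -c.umi_count, c.cdr3_nt))
    top = tuple(pool[:n])
    shortfall = len(pool) < n
    meta = dict(rep.metadata)
    meta["top_n"] = n
    meta["isotype"] = isotype or "all"
    return Repertoire(top, meta), shortfall


def _renorm_freqs(rep: Repertoire) -> dict[tuple, float]:
    total = sum(c.frequency for c in rep.clonotypes)
    if total <= 0:
        raise ValueError("repertoire has zero total frequency")
    return {c.key: c.frequency / total for c in rep.clonotypes}


def f2(rep_i: Repertoire, rep_j: Repertoire) -> float:
    """F2 = Σ_shared sqrt(f_i · f_j) on renormalized frequency vectors."""
    if len(rep_i) == 0 or len(rep_j) == 0:
        raise ValueError("f2 requires non-empty repertoires")
    fi = _renorm_freqs(rep_i)
    fj = _renorm_freqs(rep_j)
    return float(sum(math.sqrt(fi[k] * fj[k]) for k in fi.keys() & fj.keys()))


def d_metric(rep_i: Repertoire, rep_j: Repertoire) -> float:
    """D = d_ij / (d_i · d_j); d are clonotype richnesses, d_ij the shared count."""
    if len(rep_i) == 0 or len(rep_j) == 0:
        raise ValueError("d_metric requires non-empty repertoires")
    keys_i = {c.key for c in rep_i.clonotypes}
    keys_j = {c.key for c in rep_j.clonotypes}
    return len(keys_i & keys_j) / (len(keys_i) * len(keys_j))


def r_metric(rep_i: Repertoire, rep_j: Repertoire) -> tuple[float | None, int]:
    """Pearson r of log10 frequencies over shared clonotypes.

    Returns (r, n_shared); r is None when fewer than 3 clonotypes are shared
    or either log-frequency vector is constant.
    """
    fi = _renorm_freqs(rep_i)
    fj = _renorm_freqs(rep_j)
    shared = sorted(fi.keys() & fj.keys())
    if len(shared) < 3:
        return None, len(shared)
    x = np.log10([fi[k] for k in shared])
    y = np.log10([fj[k] for k in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, len(shared)
    r, _ = stats.pearsonr(x, y)
    return float(r), len(shared)


def overlap_table(
    reps: dict[str, Repertoire],
    metrics: tuple[str, ...] = ("f2", "d", "r"),
    top_n: int | None = DEFAULT_TOP_N,
    by_isotype: bool = False,
    isotypes: tuple[str, ...] = ("IgM", "IgG", "IgA"),
) -> list[OverlapResult]:
    """All pairwise overlaps over a named set of repertoires.

    With ``by_isotype`` each isotype is restricted and compared separately
    (one result row per pair, metric, and isotype); otherwise the whole
    repertoire is restricted to its global top-N. ``top_n=None`` compares
    full repertoires.
    """
    results: list[OverlapResult] = []
    names = sorted(reps)
    iso_list: tuple[str | None, ...] = isotypes if by_isotype else (None,)
    for a_idx in range(len(names)):
        for b_idx in range(a_idx + 1, len(names)):
            a, b = names[a_idx], names[b_idx]
            for iso in iso_list:
                if top_n is not None:
                    ra, _ = top_n_by_isotype(reps[a], top_n, iso)
                    rb, _ = top_n_by_isotype(reps[b], top_n, iso)
                else:
                    ra, rb = reps[a], reps[b]
                    if iso is not None:
                        ra = Repertoire(
                            tuple(c for c in ra if c.isotype == iso), dict(ra.metadata)
                        )
                        rb = Repertoire(
                            tuple(c for c in rb if c.isotype == iso), dict(rb.metadata)
                        )
                if len(ra) == 0 or len(rb) == 0:
                    continue
                n_used = min(len(ra), len(rb))
                shared = {c.key for c in ra} & {c.key for c in rb}
                for metric in metrics:
                    if metric == "f2":
                        val: float | None = f2(ra, rb)
                        undef = False
                    elif metric == "d":
                        val = d_metric(ra, rb)
                        undef = False
                    elif metric == "r":
                        val, _ = r_metric(ra, rb)
                        undef = val is None
                    else:
                        raise ValueError(f"unknown metric {metric!r}")
                    results.append(
                        OverlapResult(
                            a, b, metric, val, len(shared), n_used, iso or "all", undef
                        )
                    )
    return results
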