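"""Expanded-clonotype detection from cellular replicates.

Plasma cells express orders of magnitude more immunoglobulin RNA than other
B cells, so a clonotype's frequency alone cannot distinguish genuine local
expansion from sampling noise; technical replicates at the cell-suspension
level calibrate that noise. Counts are first put on a common scale: each
clonotype's frequency in a normalized sample is multiplied by the total
number of unique UMIs across all sample groups and rounded ("pseudo-counts").
Per clonotype, summed pseudo-counts of group A versus group B are compared
with a conditional exact test on the clonotype total (binomial with a
group-size-proportional null; optionally beta-binomial when an
overdispersion is supplied), Benjamini–Hochberg corrected across clonotypes.
A clonotype is called expanded in A when FDR < 0.05 and logFC > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Repertoire

__all__ = [
    "ExpansionResult",
    "pseudo_counts",
    "test_expansion",
    "estimate_dispersion",
    "mutation_contrast",
]

LOGFC_PRIOR = 0.5


def pseudo_counts(rep: Repertoire, total_umi_all_groups: int) -> dict[tuple, int]:
    """count_k = round(f_k × total UMIs over all groups), per clonotype.

    The transform removes depth differences between samples (e.g. tumor
    fragments of unequal size) while keeping counts on the scale of the
    actual molecular sampling, which exact tests require.
    """
    if total_umi_all_groups <= 0:
        raise ValueError("total_umi_all_groups must be positive")
    total = sum(c.frequency for c in rep.clonotypes)
    return {
        c.key: int(round(c.frequency / total * total_umi_all_groups))
        for c in rep.clonotypes
    }


def _binom_two_sided(k: np.ndarray, n: np.ndarray, p: float | np.ndarray) -> np.ndarray:
    """Two-sided exact binomial p-value by doubling the smaller tail."""
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _betabinom_two_sided(
    k: np.ndarray, n: np.ndarray, p: float, phi: float
) -> np.ndarray:
    """Two-sided beta-binomial p-value (doubled smaller tail) with mean ``p``
    and a constant variance-inflation factor ``phi`` relative to binomial.

    The inflation is mapped per clonotype to the intra-class correlation
    rho = (phi − 1)/(n − 1), so that Var = n·p·(1−p)·phi for every total n.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    rho = np.clip((phi - 1.0) / np.maximum(n - 1.0, 1.0), 0.0, 0.999)
    out = np.empty_like(k, dtype=float)
    plain = rho <= 0
    if plain.any():
        out[plain] = _binom_two_sided(k[plain], n[plain], p)
    over = ~plain
    if over.any():
        conc = 1.0 / rho[over] - 1.0
        a, b = p * conc, (1.0 - p) * conc
        lower = stats.betabinom.cdf(k[over], n[over], a, b)
        upper = stats.betabinom.sf(k[over] - 1, n[over], a, b)
        out[over] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return out


def estimate_dispersion(count_rows: pd.DataFrame) -> float:
    """Moment estimator of replicate overdispersion (quasi-Poisson).

    ``count_rows``: clonotypes × replicate columns of pseudo-counts from one
    group. Returns the pooled variance-to-mean ratio Σvar / Σmean across
    clonotypes, floored at 1 (pure molecular sampling). The pseudo-count
    transform scales each sample's frequencies by the total UMIs of *all*
    groups, which inflates counts beyond the per-sample sampling depth by a
    roughly constant factor; that inflation — and any extra biological
    replicate-to-replicate variability — is exactly what this ratio picks
    up, so the downstream exact test stays calibrated.
    """
    mat = count_rows.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        return 1.0
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    ok = mean > 0
    if not ok.any() or mean[ok].sum() == 0:
        return 1.0
    return float(max(var[ok].sum() / mean[ok].sum(), 1.0))


@dataclass(frozen=True)
class ExpansionResult:
    key: tuple
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    logfc: float
    p: float
    fdr: float
    expanded: bool


def test_expansion(
    group_a: list[Repertoire],
    group_b: list[Repertoire],
    alpha_fdr: float = 0.05,
    dispersion: float | str = "auto",
    total_umi_all_groups: int | None = None,
) -> list[ExpansionResult]:
    """Per-clonotype exact test of expansion in group A versus group B.

    Each group is a list of replicate repertoires. Pseudo-counts are summed
    within groups and the clonotype total across groups is split under the
    null in proportion to group library sizes. ``dispersion`` is the
    variance-inflation factor of replicate pseudo-counts relative to pure
    molecular sampling: <= 1 (or 0) gives the conditional binomial exact
    test; larger values, or the default "auto" moment estimate from
    replicate variability, switch to a beta-binomial inflated by that
    factor. logFC is log2 of the ratio of mean per-replicate pseudo-counts
    with a prior count of 0.5; "expanded" means FDR < alpha and logFC > 0.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one replicate")
    if len(group_a) == 1 and len(group_b) == 1:
        import warnings

        warnings.warn("single replicate per group: sampling noise cannot be calibrated")
    if total_umi_all_groups is None:
        total_umi_all_groups = sum(r.total_umi for r in group_a + group_b)

    counts_a = [pseudo_counts(r, total_umi_all_groups) for r in group_a]
    counts_b = [pseudo_counts(r, total_umi_all_groups) for r in group_b]
    keys = sorted(set().union(*counts_a, *counts_b))

    a_mat = np.array([[c.get(k, 0) for c in counts_a] for k in keys], dtype=int)
    b_mat = np.array([[c.get(k, 0) for c in counts_b] for k in keys], dtype=int)
    a_sum, b_sum = a_mat.sum(axis=1), b_mat.sum(axis=1)
    present = (a_sum + b_sum) > 0
    keys = [k for k, ok in zip(keys, present) if ok]
    a_mat, b_mat = a_mat[present], b_mat[present]
    a_sum, b_sum = a_sum[present], b_sum[present]

    lib_a, lib_b = int(a_mat.sum()), int(b_mat.sum())
    p_null = lib_a / (lib_a + lib_b)
    total = a_sum + b_sum

    if dispersion == "auto":
        phi = max(
            estimate_dispersion(pd.DataFrame(a_mat)),
            estimate_dispersion(pd.DataFrame(b_mat)),
        )
    else:
        phi = float(dispersion)
    if phi > 1.0:
        pvals = _betabinom_two_sided(a_sum, total, p_null, phi)
    else:
        pvals = _binom_two_sided(a_sum, total, p_null)

    mean_a = a_mat.mean(axis=1)
    mean_b = b_mat.mean(axis=1)
    logfc = np.log2((mean_a + LOGFC_PRIOR) / (mean_b + LOGFC_PRIOR))
    fdr = multipletests(pvals, method="fdr_bh")[1]

    return [
        ExpansionResult(
            key=k,
            counts_a=tuple(int(x) for x in a_mat[i]),
            counts_b=tuple(int(x) for x in b_mat[i]),
            logfc=float(logfc[i]),
            p=float(pvals[i]),
            fdr=float(fdr[i]),
            expanded=bool(fdr[i] < alpha_fdr and logfc[i] > 0),
        )
        for i, k in enumerate(keys)
    ]


def mutation_contrast(
    expanded_mutations: list[int], other_mutations: list[int]
) -> dict:
    """Mean hypermutation load of expanded vs non-expanded clonotypes with a
    two-sided Mann–Whitney test.

    Returns a dict with the two means, U statistic and p; flagged undefined
    when either set is empty.
    """
    if not expanded_mutations or not other_mutations:
        return {
            "mean_expanded": float(np.mean(expanded_mutations)) if expanded_mutations else None,
            "mean_other": float(np.mean(other_mutations)) if other_mutations else None,
            "statistic": None,
            "p": None,
            "undefined": True,
        }
    u, p = stats.mannwhitneyu(expanded_mutations, other_mutations, alternative="two-sided")
    return {
        "mean_expanded": float(np.mean(expanded_mutations)),
        "mean_other": float(np.mean(other_mutations)),
        "statistic": float(u),
        "p": float(p),
        "undefined": False,
    }
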