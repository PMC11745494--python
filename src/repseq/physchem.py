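"""CDR-H3 physicochemical profiling.

Descriptors are computed over the five central amino acids of each CDR-H3
(the part most likely to contact antigen) for the top-100 most frequent
clonotypes of a sample, then averaged without frequency weighting:

* charge — (#K + #R) − (#D + #E); histidine excluded by default (pH-7 net
  charge convention), configurable.
* hydropathy — mean Kyte–Doolittle index.
* strength — predicted interaction strength: the count of strongly
  interacting residues {F, I, L, M, V, W, Y}.
* kf1..kf10 — mean Kidera factors. The ten factors are orthogonal,
  standardized summaries (mean 0, variance 1 over the 20 residues) of 188
  physical amino-acid properties; kf4 is inversely related to hydrophobicity,
  kf6 tracks partial specific volume.

The amino-acid property table ships as a TSV resource; the strongly
interacting set and charge convention are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Repertoire

__all__ = [
    "AAPropertyTable",
    "PhyschemProfile",
    "load_property_table",
    "central_window",
    "descriptor",
    "profile",
    "compare_groups",
    "DESCRIPTORS",
]

KIDERA_FACTORS = tuple(f"kf{i}" for i in range(1, 11))
#: descriptors reported by default (kf10 computed on request)
DESCRIPTORS = ("charge", "hydropathy", "strength") + KIDERA_FACTORS[:9]


@dataclass(frozen=True)
class AAPropertyTable:
    """Per-residue property table covering the 20 standard amino acids."""

    table: pd.DataFrame  # index: 1-letter residue; columns: kf1..kf10, hydropathy, charge, strong

    def __post_init__(self) -> None:
        if sorted(self.table.index) != sorted("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("property table must cover exactly the 20 standard residues")

    def column(self, name: str) -> pd.Series:
        return self.table[name]


def load_property_table() -> AAPropertyTable:
    """Load the packaged Kidera / Kyte–Doolittle property resource."""
    with resources.files("repseq").joinpath("data/aa_properties.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t").set_index("aa")
    return AAPropertyTable(df)


_TABLE: AAPropertyTable | None = None


def _default_table() -> AAPropertyTable:
    global _TABLE
    if _TABLE is None:
        _TABLE = load_property_table()
    return _TABLE


def central_window(cdr3_aa: str, w: int = 5) -> str:
    """The w central residues; start = floor((len − w)/2) for even overhang.

    Sequences shorter than w are returned whole.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    n = len(cdr3_aa)
    if n <= w:
        return cdr3_aa
    start = (n - w) // 2
    return cdr3_aa[start : start + w]


def descriptor(
    seq: str,
    name: str,
    table: AAPropertyTable | None = None,
    include_histidine_charge: bool = False,
) -> float:
    """One physicochemical descriptor of an amino-acid sequence.

    Raises ValueError on non-standard residues (no silent skipping).
    """
    if not seq:
        raise ValueError("empty sequence")
    tab = (table or _default_table()).table
    bad = set(seq) - set(tab.index)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    if name == "charge":
        charge = sum(tab.loc[a, "charge"] for a in seq)
        if include_histidine_charge:
            charge += seq.count("H")
        return float(charge)
    if name == "hydropathy":
        return float(np.mean([tab.loc[a, "hydropathy"] for a in seq]))
    if name == "strength":
        return float(sum(tab.loc[a, "strong"] for a in seq))
    if name in KIDERA_FACTORS:
        return float(np.mean([tab.loc[a, name] for a in seq]))
    raise ValueError(f"unknown descriptor {name!r}")


@dataclass(frozen=True)
class PhyschemProfile:
    """Mean CDR-H3 descriptors of a sample's top clonotypes."""

    sample_id: str
    mean_cdr3_len: float
    descriptors: dict[str, float]
    n_used: int
    n_short: int  # clonotypes whose CDR-H3 was shorter than the window


def profile(
    rep: Repertoire,
    top_n: int = 100,
    window: int = 5,
    descriptors: tuple[str, ...] = DESCRIPTORS,
    table: AAPropertyTable | None = None,
) -> PhyschemProfile:
    """Unweighted mean of per-clonotype central-window descriptors.

    The ``top_n`` most frequent clonotypes with an amino-acid CDR-H3 are
    used; descriptors are computed on the 5 central residues (whole CDR-H3
    when shorter than the window).
    """
    pool = [c for c in rep.clonotypes if c.cdr3_aa]
    pool.sort(key=lambda c: (-c.frequency, -c.umi_count, c.cdr3_nt))
    top = pool[:top_n]
    if not top:
        raise ValueError("no clonotypes with amino-acid CDR-H3")
    lens = [len(c.cdr3_aa) for c in top]
    n_short = sum(1 for L in lens if L < window)
    values: dict[str, list[float]] = {d: [] for d in descriptors}
    for c in top:
        win = central_window(c.cdr3_aa, window)
        for d in descriptors:
            values[d].append(descriptor(win, d, table=table))
    return PhyschemProfile(
        sample_id=rep.sample_id,
        mean_cdr3_len=float(np.mean(lens)),
        descriptors={d: float(np.mean(v)) for d, v in values.items()},
        n_used=len(top),
        n_short=n_short,
    )


def compare_groups(
    groups: dict[str, list[PhyschemProfile]],
    test: str = "t",
    correction: str = "holm",
) -> pd.DataFrame:
    """Descriptor-wise two-group comparison with multiplicity correction.

    ``groups`` maps two group labels to lists of per-sample profiles. Returns
    one row per descriptor (plus mean CDR-H3 length) with the statistic, raw
    p, and adjusted p (``bonferroni`` or ``holm``).
    """
    if len(groups) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    if test not in {"t", "mannwhitney"}:
        raise ValueError("test must be 't' or 'mannwhitney'")
    method = {"bonferroni": "bonferroni", "holm": "holm"}[correction]
    (name_a, profs_a), (name_b, profs_b) = groups.items()
    feature_names = ["mean_cdr3_len"] + list(profs_a[0].descriptors)

    def extract(profs: list[PhyschemProfile], feat: str) -> np.ndarray:
        if feat == "mean_cdr3_len":
            return np.array([p.mean_cdr3_len for p in profs])
        return np.array([p.descriptors[feat] for p in profs])

    rows = []
    for feat in feature_names:
        xa, xb = extract(profs_a, feat), extract(profs_b, feat)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            stat, p = 0.0, 1.0
        elif test == "t":
            stat, p = stats.ttest_ind(xa, xb)
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {
                "descriptor": feat,
                f"mean_{name_a}": float(np.mean(xa)),
                f"mean_{name_b}": float(np.mean(xb)),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method=method)[1]
    return out
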