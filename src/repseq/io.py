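"""AIRR-dialect clonotype table I/O, filtering, and replicate pooling.

The unit of analysis is the *clonotype*: a unique combination of CDR-H3
nucleotide sequence, V gene, and J gene. Isotype (constant-region class) is
deliberately excluded from the identity key, because one B-cell clone can be
observed with several isotypes after class switching; rows that share an
identity key but differ in ``c_call`` are merged on read.

A :class:`Repertoire` is one sample's set of clonotypes with frequencies
normalized to UMI (unique molecular identifier) counts. Replicates and
fragments are combined with :func:`pool_repertoires`, which averages each
clonotype's frequency across the files being pooled (absent = 0), so that
every input sample contributes equally regardless of sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Clonotype",
    "Repertoire",
    "FilterResult",
    "FormatError",
    "EmptyRepertoireError",
    "read_airr",
    "write_airr",
    "repertoire_from_frame",
    "apply_filters",
    "pool_repertoires",
]

#: ranking used to break isotype ties when merging rows (dominant first)
_ISOTYPE_ORDER = ("IgM", "IgG", "IgA", "unknown")

#: canonical AIRR column names used on write
_AIRR_COLUMNS = [
    "sequence_id",
    "junction",
    "junction_aa",
    "v_call",
    "j_call",
    "c_call",
    "duplicate_count",
    "sample_id",
    "patient_id",
    "tissue",
    "fragment_id",
    "replicate_id",
    "v_region_nt",
    "germline_mutations",
]


class FormatError(ValueError):
    """A mandatory column is missing or unparsable in an input table."""


class EmptyRepertoireError(ValueError):
    """The table contains no clonotypes with positive UMI count."""


def parse_isotype(c_call: object) -> str:
    """Map a constant-region gene call to an isotype class.

    ``IGHM`` -> IgM, ``IGHG*`` -> IgG, ``IGHA*`` -> IgA; anything else
    (including missing values, IGHD/IGHE) -> ``"unknown"``.
    """
    if c_call is None or (isinstance(c_call, float) and pd.isna(c_call)):
        return "unknown"
    s = str(c_call).upper()
    if s.startswith("IGHM") or s == "IGM":
        return "IgM"
    if s.startswith("IGHG") or s == "IGG":
        return "IgG"
    if s.startswith("IGHA") or s == "IGA":
        return "IgA"
    return "unknown"


@dataclass(frozen=True)
class Clonotype:
    """One V/J/CDR-H3-nucleotide-defined receptor record."""

    cdr3_nt: str
    v_gene: str
    j_gene: str
    cdr3_aa: str | None = None
    isotype: str = "unknown"
    umi_count: int = 0
    frequency: float = 0.0
    sample_id: str = ""
    patient_id: str = ""
    tissue: str = ""
    fragment_id: str = ""
    replicate_id: str = ""
    v_region_nt: str | None = None
    germline_mutations: int | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        """Clonotype identity: (CDR-H3 nucleotide, V gene, J gene)."""
        return (self.cdr3_nt, self.v_gene, self.j_gene)


@dataclass
class Repertoire:
    """A sample's clonotype set with UMI-normalized frequencies."""

    clonotypes: tuple[Clonotype, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clonotypes = tuple(self.clonotypes)
        keys = [c.key for c in self.clonotypes]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate clonotype identity keys in repertoire")

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self):
        return iter(self.clonotypes)

    @property
    def total_umi(self) -> int:
        return sum(c.umi_count for c in self.clonotypes)

    @property
    def sample_id(self) -> str:
        return str(self.metadata.get("sample_id", ""))

    def frequencies(self) -> dict[tuple[str, str, str], float]:
        return {c.key: c.frequency for c in self.clonotypes}

    def renormalized(self) -> "Repertoire":
        """Return a copy with frequencies rescaled to sum to 1."""
        total = sum(c.frequency for c in self.clonotypes)
        if total <= 0:
            raise EmptyRepertoireError("cannot renormalize zero total frequency")
        new = tuple(replace(c, frequency=c.frequency / total) for c in self.clonotypes)
        return Repertoire(new, dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.clonotypes):
            rows.append(
                {
                    "sequence_id": f"{self.sample_id or 'seq'}-{i}",
                    "junction": c.cdr3_nt,
                    "junction_aa": c.cdr3_aa,
                    "v_call": c.v_gene,
                    "j_call": c.j_gene,
                    "c_call": c.isotype,
                    "duplicate_count": c.umi_count,
                    "frequency": c.frequency,
                    "sample_id": c.sample_id,
                    "patient_id": c.patient_id,
                    "tissue": c.tissue,
                    "fragment_id": c.fragment_id,
                    "replicate_id": c.replicate_id,
                    "v_region_nt": c.v_region_nt,
                    "germline_mutations": c.germline_mutations,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FilterResult:
    """Outcome of :func:`apply_filters`: the filtered repertoire plus a flag.

    An excluded sample is not silently dropped; ``excluded`` is True and
    ``reason`` explains which rule fired.
    """

    repertoire: Repertoire
    excluded: bool
    reason: str | None = None


_DEFAULT_COLUMN_MAP = {
    "junction": "junction",
    "junction_aa": "junction_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "c_call": "c_call",
    "umi_count": "duplicate_count",
    "sample_id": "sample_id",
    "patient_id": "patient_id",
    "tissue": "tissue",
    "fragment_id": "fragment_id",
    "replicate_id": "replicate_id",
    "v_region_nt": "v_region_nt",
    "germline_mutations": "germline_mutations",
}

_MANDATORY = ("junction", "v_call", "j_call", "umi_count")


def _merge_isotype(candidates: Sequence[tuple[str, int]]) -> str:
    """Isotype of a merged clonotype: highest-UMI constituent wins, ties
    broken IgM > IgG > IgA > unknown."""
    known = [c for c in candidates if c[0] in _ISOTYPE_ORDER]
    if not known:
        return "unknown"
    return min(known, key=lambda t: (-t[1], _ISOTYPE_ORDER.index(t[0])))[0]


def repertoire_from_frame(
    df: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    metadata: Mapping | None = None,
) -> Repertoire:
    """Build a Repertoire from an AIRR Rearrangement-style DataFrame.

    Rows sharing an identity key (junction, v_call, j_call) are merged with
    summed UMI counts; see :func:`_merge_isotype` for the isotype of a merged
    record. Frequencies are computed as umi_count / total_umi.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    # `umi_count` may live in either duplicate_count or umi_count
    if cmap["umi_count"] not in df.columns and "umi_count" in df.columns:
        cmap["umi_count"] = "umi_count"
    for logical in _MANDATORY:
        if cmap[logical] not in df.columns:
            raise FormatError(f"missing mandatory column: {cmap[logical]!r} ({logical})")

    def col(logical: str, default=None) -> pd.Series:
        name = cmap[logical]
        if name in df.columns:
            return df[name]
        return pd.Series([default] * len(df), index=df.index)

    merged: dict[tuple[str, str, str], dict] = {}
    for idx in df.index:
        nt = str(col("junction")[idx])
        v = str(col("v_call")[idx])
        j = str(col("j_call")[idx])
        umi = int(col("umi_count")[idx])
        if umi < 0:
            raise FormatError("negative UMI count")
        key = (nt, v, j)
        iso = parse_isotype(col("c_call")[idx])
        aa = col("junction_aa")[idx]
        aa = None if aa is None or (isinstance(aa, float) and pd.isna(aa)) else str(aa)
        rec = merged.setdefault(
            key,
            {
                "aa": aa,
                "umi": 0,
                "isotypes": [],
                "sample_id": str(col("sample_id", "")[idx] or ""),
                "patient_id": str(col("patient_id", "")[idx] or ""),
                "tissue": str(col("tissue", "")[idx] or ""),
                "fragment_id": str(col("fragment_id", "")[idx] or ""),
                "replicate_id": str(col("replicate_id", "")[idx] or ""),
                "v_region_nt": None,
                "germline_mutations": None,
            },
        )
        rec["umi"] += umi
        rec["isotypes"].append((iso, umi))
        vreg = col("v_region_nt")[idx]
        if vreg is not None and not (isinstance(vreg, float) and pd.isna(vreg)):
            rec["v_region_nt"] = str(vreg)
        gm = col("germline_mutations")[idx]
        if gm is not None and not (isinstance(gm, float) and pd.isna(gm)):
            rec["germline_mutations"] = int(gm)

    total = sum(r["umi"] for r in merged.values())
    if total <= 0:
        raise EmptyRepertoireError("zero total UMI count")
    clones = tuple(
        Clonotype(
            cdr3_nt=k[0],
            v_gene=k[1],
            j_gene=k[2],
            cdr3_aa=r["aa"],
            isotype=_merge_isotype(r["isotypes"]),
            umi_count=r["umi"],
            frequency=r["umi"] / total,
            sample_id=r["sample_id"],
            patient_id=r["patient_id"],
            tissue=r["tissue"],
            fragment_id=r["fragment_id"],
            replicate_id=r["replicate_id"],
            v_region_nt=r["v_region_nt"],
            germline_mutations=r["germline_mutations"],
        )
        for k, r in merged.items()
    )
    meta = dict(metadata or {})
    for label in ("sample_id", "patient_id", "tissue", "fragment_id", "replicate_id"):
        vals = {getattr(c, label) for c in clones if getattr(c, label)}
        if len(vals) == 1 and label not in meta:
            meta[label] = vals.pop()
    return Repertoire(clones, meta)


def read_airr(path: str | Path, column_map: Mapping[str, str] | None = None) -> Repertoire:
    """Read one sample's AIRR Rearrangement TSV into a :class:`Repertoire`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"junction": str, "v_call": str, "j_call": str})
    return repertoire_from_frame(df, column_map=column_map, metadata={"source": str(path)})


def write_airr(rep: Repertoire, path: str | Path) -> None:
    """Write a Repertoire back to AIRR Rearrangement TSV."""
    df = rep.to_frame()
    cols = [c for c in _AIRR_COLUMNS + ["frequency"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def apply_filters(
    rep: Repertoire,
    min_umi_per_clonotype: int = 2,
    min_clonotypes: int = 50,
) -> FilterResult:
    """Apply the preprocessing rules: singleton exclusion and sample-size cut.

    Clonotypes backed by fewer than ``min_umi_per_clonotype`` UMIs are removed
    (the default 2 drops single-UMI clonotypes, which are excluded from
    individual-clonotype analyses; pass 1 to retain them, as lineage analysis
    does). If ``min_clonotypes`` or fewer clonotypes survive, the sample is
    flagged excluded — 51 survivors pass a cut of 50.
    """
    if min_umi_per_clonotype < 0 or min_clonotypes < 0:
        raise ValueError("thresholds must be non-negative")
    kept = tuple(c for c in rep.clonotypes if c.umi_count >= min_umi_per_clonotype)
    if not kept:
        empty = Repertoire((), dict(rep.metadata))
        return FilterResult(empty, True, "no clonotypes survive UMI filter")
    filtered = Repertoire(kept, dict(rep.metadata)).renormalized()
    if len(filtered) <= min_clonotypes:
        return FilterResult(
            filtered, True, f"{len(filtered)} clonotypes <= {min_clonotypes}"
        )
    return FilterResult(filtered, False)


def pool_repertoires(reps: Iterable[Repertoire]) -> Repertoire:
    """Pool replicates/fragments: frequency = mean across files (absent = 0).

    Averaging over a common clonotype universe gives every file equal weight
    irrespective of depth. Pooled UMI counts are summed. The result is
    renormalized defensively (means over a common universe already sum to 1).
    """
    reps = list(reps)
    if not reps:
        raise ValueError("pool_repertoires requires at least one repertoire")
    patients = {r.metadata.get("patient_id") for r in reps if r.metadata.get("patient_id")}
    if len(patients) > 1:
        warnings.warn(f"pooling repertoires from several patients: {sorted(patients)}")
    n = len(reps)
    freq_sum: dict[tuple[str, str, str], float] = {}
    umi_sum: dict[tuple[str, str, str], int] = {}
    proto: dict[tuple[str, str, str], Clonotype] = {}
    for r in reps:
        for c in r.clonotypes:
            freq_sum[c.key] = freq_sum.get(c.key, 0.0) + c.frequency
            umi_sum[c.key] = umi_sum.get(c.key, 0) + c.umi_count
            prev = proto.get(c.key)
            if prev is None or c.umi_count > prev.umi_count:
                proto[c.key] = c
    clones = tuple(
        replace(
            proto[k],
            umi_count=umi_sum[k],
            frequency=freq_sum[k] / n,
            sample_id="",
            replicate_id="",
        )
        for k in freq_sum
    )
    meta = {}
    for label in ("patient_id", "tissue", "fragment_id"):
        vals = {r.metadata.get(label) for r in reps}
        if len(vals) == 1 and None not in vals:
            meta[label] = vals.pop()
    meta["pooled_from"] = [r.sample_id for r in reps]
    return Repertoire(clones, meta).renormalized()
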