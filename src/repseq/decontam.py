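"""Cross-sample UMI-collision decontamination.

Identical UMI tags observed in different samples with (near-)identical
consensus sequences are almost certainly cross-sample contamination (index
hopping or well-to-well carry-over) rather than chance tag collisions. The
rule applied here: compare read counts of the colliding UMI; if one sample's
count exceeds another's by strictly more than ``ratio`` (default 5), the UMI
is dropped only from the lower-count sample(s); otherwise it cannot be
attributed and is dropped from all involved samples. Collisions between
clearly different sequences are genuine tag reuse and are kept everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import pandas as pd

__all__ = ["UmiRecord", "decontaminate", "collision_rate", "sequence_identity"]


@dataclass(frozen=True)
class UmiRecord:
    """A single unique-molecule observation."""

    sample_id: str
    umi: str
    sequence: str
    reads: int

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("reads must be >= 1")


def sequence_identity(a: str, b: str) -> float:
    """Global identity on an equal-length trim: matches / compared length."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _similar_groups(records: list[UmiRecord], min_identity: float) -> list[list[UmiRecord]]:
    """Single-linkage grouping of same-UMI records by sequence similarity."""
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if sequence_identity(records[i].sequence, records[j].sequence) >= min_identity:
            parent[find(i)] = find(j)
    groups: dict[int, list[UmiRecord]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec)
    return list(groups.values())


def decontaminate(
    records: Iterable[UmiRecord],
    ratio: float = 5.0,
    seq_similarity_min: float = 0.9,
) -> tuple[list[UmiRecord], pd.DataFrame]:
    """Apply the cross-sample UMI rule; return kept records and a removal log.

    For every UMI tag shared by >= 2 samples whose sequences are identical or
    near-identical (pairwise identity >= ``seq_similarity_min``): the
    max-read sample keeps the UMI only if its read count exceeds every other
    involved sample's by strictly more than ``ratio``; the others always lose
    it. If the max does not beat all others by > ratio (ties at exactly
    ``ratio`` included), the UMI is removed from all involved samples.

    The removal log has one row per removed record: umi, sample_id, reads,
    max_reads within the colliding group, and the decision taken.
    """
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    records = list(records)
    by_umi: dict[str, list[UmiRecord]] = {}
    for rec in records:
        by_umi.setdefault(rec.umi, []).append(rec)

    removed: set[int] = set()
    log_rows: list[dict] = []
    rec_index = {id(rec): i for i, rec in enumerate(records)}

    for umi, group in by_umi.items():
        if len({r.sample_id for r in group}) < 2:
            continue
        for sub in _similar_groups(group, seq_similarity_min):
            if len({r.sample_id for r in sub}) < 2:
                continue
            # collapse multiple records of one sample to their read sum
            reads_by_sample: dict[str, int] = {}
            for r in sub:
                reads_by_sample[r.sample_id] = reads_by_sample.get(r.sample_id, 0) + r.reads
            max_sample = max(reads_by_sample, key=lambda s: (reads_by_sample[s], s))
            max_reads = reads_by_sample[max_sample]
            winner_survives = all(
                max_reads > ratio * reads
                for s, reads in reads_by_sample.items()
                if s != max_sample
            )
            decision = "kept_in_max_sample" if winner_survives else "removed_from_all"
            for r in sub:
                if winner_survives and r.sample_id == max_sample:
                    continue
                removed.add(rec_index[id(r)])
                log_rows.append(
                    {
                        "umi": umi,
                        "sample_id": r.sample_id,
                        "reads": r.reads,
                        "max_reads": max_reads,
                        "max_sample": max_sample,
                        "decision": decision,
                    }
                )

    kept = [rec for i, rec in enumerate(records) if i not in removed]
    log = pd.DataFrame(
        log_rows,
        columns=["umi", "sample_id", "reads", "max_reads", "max_sample", "decision"],
    )
    return kept, log


def collision_rate(records: Iterable[UmiRecord]) -> pd.DataFrame:
    """Shared-UMI fraction (|A∩B| / |A∪B|) for every sample pair.

    Symmetric and in [0, 1]; disjoint UMI sets give 0, identical sets 1.
    """
    sets: dict[str, set[str]] = {}
    for rec in records:
        sets.setdefault(rec.sample_id, set()).add(rec.umi)
    rows = []
    for a, b in combinations(sorted(sets), 2):
        union = sets[a] | sets[b]
        shared = sets[a] & sets[b]
        rows.append(
            {
                "sample_i": a,
                "sample_j": b,
                "n_shared": len(shared),
                "n_union": len(union),
                "rate": len(shared) / len(union) if union else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "n_shared", "n_union", "rate"])
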