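"""Clonal-lineage inference and hypermutation phylogeny.

Clonotypes descended from one naive B cell share the germline V and J genes
and the junction length, and differ only by somatic hypermutation (SHM)
within the CDR-H3. Lineages are therefore inferred in two steps:

1. partition clonotypes by (V gene, J gene, CDR-H3 length) — the D segment
   is ignored, as its annotation is unreliable;
2. within each partition, single-linkage clustering of CDR-H3 nucleotide
   sequences at a normalized Hamming-distance threshold. The threshold is
   detected automatically as the local minimum of the distance-to-nearest
   distribution, which separates the SHM-variant mode (small distances) from
   the unrelated-junction mode; it typically lands at 0.15–0.20 distance
   (80–85% identity).

For each sufficiently large lineage (default >= 5 members) a rooted tree is
built: neighbor joining on pairwise normalized Hamming distances plus a
germline outgroup — the conjugate of the germline V and J segments with the
untemplated N region masked — which stands in for the most recent common
ancestor (MRCA) and roots the tree. Member depth is summarized as distance
to the root and its within-lineage rank; selection pressure as pooled
Nei–Gojobori dN/dS versus the MRCA sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj

from .io import Clonotype, Repertoire

__all__ = [
    "ThresholdResult",
    "ClonalLineage",
    "LineageTree",
    "DnDsResult",
    "hamming_distance",
    "nearest_distances",
    "detect_threshold",
    "build_lineages",
    "build_tree",
    "mutation_count",
    "rank_by_root_distance",
    "compare_tree_sets",
    "dnds",
]

FALLBACK_THRESHOLD = 0.15
MASK = "N"

_CODON_TABLE = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"
_BASES = "ACGT"


def hamming_distance(a: str, b: str, normalize: bool = True) -> float:
    """Hamming distance between equal-length sequences.

    Positions where either sequence carries the mask character ``N`` (no
    germline coverage, e.g. the untemplated junction middle of an outgroup)
    are excluded; normalization divides by the number of compared positions.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    covered = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == MASK or y == MASK:
            continue
        covered += 1
        diffs += x != y
    if not normalize:
        return float(diffs)
    if covered == 0:
        raise ValueError("no covered positions to compare")
    return diffs / covered


def _partitions(clonotypes: tuple[Clonotype, ...]) -> dict[tuple, list[Clonotype]]:
    parts: dict[tuple, list[Clonotype]] = {}
    for c in clonotypes:
        parts.setdefault((c.v_gene, c.j_gene, len(c.cdr3_nt)), []).append(c)
    return parts


def nearest_distances(rep: Repertoire) -> np.ndarray:
    """Each clonotype's normalized Hamming distance to its nearest
    non-identical neighbor within its V/J/length partition.

    Clonotypes with no neighbor in their partition contribute nothing.
    """
    out: list[float] = []
    for members in _partitions(rep.clonotypes).values():
        if len(members) < 2:
            continue
        seqs = [m.cdr3_nt for m in members]
        n = len(seqs)
        arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
        # pairwise normalized Hamming, vectorized per row
        for i in range(n):
            d = (arr != arr[i]).mean(axis=1)
            d[i] = np.inf
            nonzero = d[np.isfinite(d) & (d > 0)]
            if nonzero.size:
                out.append(float(nonzero.min()))
    return np.asarray(out)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    flagged: bool
    reason: str | None = None


def detect_threshold(
    distances: np.ndarray,
    search_range: tuple[float, float] = (0.05, 0.5),
    grid_size: int = 512,
) -> ThresholdResult:
    """Distance threshold = deepest local minimum of the distance-to-nearest
    density between its two largest modes.

    A Gaussian KDE with Silverman bandwidth is evaluated on [0, 1]; local
    maxima are located, the two with the highest density are taken as the
    SHM-variant and unrelated-junction modes, and the distance at the density
    minimum between them (restricted to ``search_range``) is returned. With
    fewer than 20 distances, a unimodal sample, or a degenerate sample the
    fallback 0.15 is returned with a flag.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size < 20:
        return ThresholdResult(FALLBACK_THRESHOLD, True, "fewer than 20 distances")
    if np.ptp(distances) == 0:
        return ThresholdResult(FALLBACK_THRESHOLD, True, "degenerate (constant) distances")
    try:
        kde = stats.gaussian_kde(distances, bw_method="silverman")
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        return ThresholdResult(FALLBACK_THRESHOLD, True, "KDE failed")
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    if dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [grid_size - 1]])
    if len(peaks) < 2:
        return ThresholdResult(FALLBACK_THRESHOLD, True, "unimodal distance distribution")
    top_two = sorted(peaks[np.argsort(dens[peaks])[-2:]])
    lo, hi = top_two
    # the second mode must be a real mode: non-negligible height and a
    # genuine dip between the two (guards against KDE ripple on unimodal data)
    minor = min(dens[lo], dens[hi])
    dip = dens[lo : hi + 1].min()
    if minor < 0.05 * max(dens[lo], dens[hi]) or dip > 0.9 * minor:
        return ThresholdResult(FALLBACK_THRESHOLD, True, "unimodal distance distribution")
    between = np.arange(lo, hi + 1)
    in_range = between[(grid[between] > search_range[0]) & (grid[between] < search_range[1])]
    if in_range.size == 0:
        return ThresholdResult(
            FALLBACK_THRESHOLD, True, "no minimum inside the search range"
        )
    t = float(grid[in_range[np.argmin(dens[in_range])]])
    return ThresholdResult(t, False)


@dataclass
class ClonalLineage:
    """A cluster of clonotypes sharing V, J, and CDR-H3 length, connected by
    single-linkage similarity above the identity threshold."""

    lineage_id: str
    members: tuple[Clonotype, ...]
    v_gene: str
    j_gene: str
    cdr3_len: int
    threshold_used: float
    germline_outgroup: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def make_outgroup(
    cdr3_len: int,
    v_junction: str | None,
    j_junction: str | None,
) -> str | None:
    """Germline outgroup: V 3' end ∥ masked N region ∥ J 5' start.

    ``v_junction`` is the germline nucleotide run the V segment contributes
    to the start of the junction, ``j_junction`` the run the J segment
    contributes to its end. The untemplated middle (and the D segment) has
    no germline assignment and is masked with ``N`` so it never enters
    distances involving the outgroup. Returns None when neither segment is
    known.
    """
    v = v_junction or ""
    j = j_junction or ""
    if not v and not j:
        return None
    if len(v) + len(j) > cdr3_len:
        # germline runs overlap the junction middle; trim both evenly
        excess = len(v) + len(j) - cdr3_len
        trim_v = min(len(v), (excess + 1) // 2)
        v = v[: len(v) - trim_v]
        j = j[excess - trim_v :]
    return v + MASK * (cdr3_len - len(v) - len(j)) + j


def build_lineages(
    rep: Repertoire,
    threshold: float | str = "auto",
    min_size: int = 1,
    germline_v: dict[str, str] | None = None,
    germline_j: dict[str, str] | None = None,
) -> tuple[list[ClonalLineage], ThresholdResult]:
    """Partition clonotypes into clonal lineages.

    ``threshold`` is a normalized Hamming *distance*: members are linked when
    their CDR-H3 distance is <= threshold (single linkage); ``"auto"``
    detects it from the distance-to-nearest distribution of ``rep`` (a
    patient-wise pooled repertoire is the intended input). Lineages smaller
    than ``min_size`` are dropped; singletons (size 1) are legitimate
    lineages at the default and are needed for the singles-vs-clonal
    contrast.
    """
    if threshold == "auto":
        tres = detect_threshold(nearest_distances(rep))
    else:
        tres = ThresholdResult(float(threshold), False, "user-specified")
    lineages: list[ClonalLineage] = []
    counter = itertools.count()
    for (v, j, length), members in sorted(_partitions(rep.clonotypes).items()):
        members = sorted(members, key=lambda c: (c.cdr3_nt, c.sample_id))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        if n > 1:
            arr = np.frombuffer(
                "".join(m.cdr3_nt for m in members).encode(), dtype="S1"
            ).reshape(n, -1)
            for i in range(n - 1):
                d = (arr[i + 1 :] != arr[i]).mean(axis=1)
                for off in np.where(d <= tres.threshold)[0]:
                    parent[find(i)] = find(i + 1 + off)
        clusters: dict[int, list[Clonotype]] = {}
        for i, m in enumerate(members):
            clusters.setdefault(find(i), []).append(m)
        outgroup = make_outgroup(
            length,
            (germline_v or {}).get(v),
            (germline_j or {}).get(j),
        )
        for root in sorted(clusters, key=lambda r: clusters[r][0].cdr3_nt):
            clust = clusters[root]
            if len(clust) < min_size:
                continue
            lineages.append(
                ClonalLineage(
                    lineage_id=f"L{next(counter):05d}",
                    members=tuple(clust),
                    v_gene=v,
                    j_gene=j,
                    cdr3_len=length,
                    threshold_used=tres.threshold,
                    germline_outgroup=outgroup,
                )
            )
    return lineages, tres


@dataclass
class LineageTree:
    """A germline-rooted tree over lineage members."""

    lineage_id: str
    members: tuple[Clonotype, ...]
    tree: object  # skbio.TreeNode rooted at the outgroup
    distance_to_root: dict[tuple, float] = field(default_factory=dict)
    ranks: dict[tuple, float] = field(default_factory=dict)


OUTGROUP_ID = "germline"


def build_tree(lineage: ClonalLineage, min_size: int = 5) -> LineageTree:
    """Neighbor-joining tree on pairwise normalized Hamming distances, rooted
    at the germline V∥J outgroup.

    Members are ordered lexicographically by CDR-H3 before the distance
    matrix is built, so the result is independent of input order; negative
    NJ branch lengths are clamped to zero. Distance to root is the tree path
    length from each member tip to the outgroup tip.
    """
    if lineage.size < min_size:
        raise ValueError(f"lineage {lineage.lineage_id} smaller than {min_size}")
    if lineage.germline_outgroup is None:
        raise ValueError("lineage has no germline outgroup")
    members = tuple(sorted(lineage.members, key=lambda c: (c.cdr3_nt, c.sample_id)))
    seqs = [lineage.germline_outgroup] + [m.cdr3_nt for m in members]
    ids = [OUTGROUP_ID] + [f"m{i}" for i in range(len(members))]
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = hamming_distance(seqs[i], seqs[j])
    tree = nj(DistanceMatrix(mat, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    og_tip = tree.find(OUTGROUP_ID)
    tree = tree.root_at(og_tip.parent) if og_tip.parent is not None else tree
    og_tip = tree.find(OUTGROUP_ID)
    dists: dict[tuple, float] = {}
    for i, m in enumerate(members):
        tip = tree.find(f"m{i}")
        dists[m.key] = float(tip.distance(og_tip))
    # round before ranking so numerically tied distances share a rank
    ranks = stats.rankdata(np.round([dists[m.key] for m in members], 9))
    rank_map = {m.key: float(r) for m, r in zip(members, ranks)}
    return LineageTree(lineage.lineage_id, members, tree, dists, rank_map)


def mutation_count(clonotype: Clonotype, reference: str) -> int:
    """Number of hypermutations of a clonotype against a reference sequence.

    If the input table carried a precomputed ``germline_mutations`` field it
    is returned verbatim; otherwise the (unnormalized) Hamming distance over
    reference-covered positions of the junction (plus the V region when
    ``v_region_nt`` is present and the reference is long enough) is used.
    """
    if clonotype.germline_mutations is not None:
        return clonotype.germline_mutations
    seq = clonotype.cdr3_nt
    if clonotype.v_region_nt and len(reference) == len(clonotype.v_region_nt) + len(seq):
        seq = clonotype.v_region_nt + seq
    if len(seq) != len(reference):
        raise ValueError("reference length does not match clonotype sequence")
    return int(hamming_distance(seq, reference, normalize=False))


def rank_by_root_distance(trees: list[LineageTree]) -> pd.DataFrame:
    """Per-clonotype average rank by distance to root across lineages.

    Within each lineage, members are ranked by distance to the root (average
    rank on ties); a clonotype appearing in several lineages receives the
    mean of its ranks. Keyed by (CDR-H3 aa, V, J) for matching between tree
    sets; the nucleotide sequence is carried along.
    """
    rows = []
    for t in trees:
        for m in t.members:
            rows.append(
                {
                    "cdr3_aa": m.cdr3_aa or "",
                    "v_gene": m.v_gene,
                    "j_gene": m.j_gene,
                    "cdr3_nt": m.cdr3_nt,
                    "lineage_id": t.lineage_id,
                    "rank": t.ranks[m.key],
                }
            )
    df = pd.DataFrame(rows, columns=["cdr3_aa", "v_gene", "j_gene", "cdr3_nt", "lineage_id", "rank"])
    if df.empty:
        return df.assign(avg_rank=pd.Series(dtype=float)).drop(columns=["rank"])
    agg = (
        df.groupby(["cdr3_aa", "v_gene", "j_gene"], as_index=False)["rank"]
        .mean()
        .rename(columns={"rank": "avg_rank"})
    )
    return agg


def compare_tree_sets(
    short_ranks: pd.DataFrame, long_ranks: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation of average root-distance ranks between two tree
    sets (e.g. short-read vs full-length), matched on CDR-H3 aa + V + J.

    Returns (r, p, n_matched).
    """
    merged = short_ranks.merge(
        long_ranks, on=["cdr3_aa", "v_gene", "j_gene"], suffixes=("_short", "_long")
    )
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} matched clonotypes; need >= 3")
    r, p = stats.pearsonr(merged["avg_rank_short"], merged["avg_rank_long"])
    return float(r), float(p), n


# --- Nei–Gojobori dN/dS -----------------------------------------------------


def _syn_fraction(codon: str) -> float:
    """Fraction of the 9 single-nucleotide changes of a codon that are
    synonymous (changes to stop codons count as nonsynonymous)."""
    aa = _CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if _CODON_TO_AA[mut] == aa:
                syn += 1
    return syn / 3.0


def _codon_paths(ref: str, obs: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) substitution counts over all
    mutational pathways between two codons."""
    diff_pos = [i for i in range(3) if ref[i] != obs[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = ref
        syn = nsyn = 0
        for pos in order:
            nxt = cur[:pos] + obs[pos] + cur[pos + 1 :]
            if _CODON_TO_AA[nxt] == _CODON_TO_AA[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        syn_tot += syn
        nsyn_tot += nsyn
        n_paths += 1
    return syn_tot / n_paths, nsyn_tot / n_paths


@dataclass(frozen=True)
class DnDsResult:
    dnds: float | None
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    undefined: bool
    n_members: int


def dnds(lineage: ClonalLineage, reference: str | None = None) -> DnDsResult:
    """Pooled Nei–Gojobori dN/dS of lineage members versus the MRCA sequence.

    The reference defaults to the lineage's germline outgroup; codons with
    masked (``N``) or non-ACGT positions in either sequence are skipped.
    Synonymous/nonsynonymous substitutions are counted per member against the
    reference with pathway averaging for multi-hit codons, pooled over the
    lineage, and dN/dS = (Nd/N)/(Sd/S). With zero synonymous substitutions
    the ratio is undefined and flagged (no pseudocounts).
    """
    ref = reference if reference is not None else lineage.germline_outgroup
    if ref is None:
        raise ValueError("no reference sequence available")
    if len(ref) % 3:
        raise ValueError("reference length must be a multiple of 3")
    nd = sd = 0.0
    n_sites = s_sites = 0.0
    for m in lineage.members:
        seq = m.cdr3_nt
        if len(seq) != len(ref):
            raise ValueError("member length does not match reference")
        for k in range(0, len(ref), 3):
            rc, oc = ref[k : k + 3], seq[k : k + 3]
            if any(b not in _BASES for b in rc) or any(b not in _BASES for b in oc):
                continue
            fs = _syn_fraction(rc)
            s_sites += fs
            n_sites += 3 - fs
            s, n = _codon_paths(rc, oc)
            sd += s
            nd += n
    if sd == 0 or s_sites == 0 or n_sites == 0:
        return DnDsResult(None, nd, sd, n_sites, s_sites, True, lineage.size)
    ratio = (nd / n_sites) / (sd / s_sites)
    return DnDsResult(float(ratio), nd, sd, n_sites, s_sites, False, lineage.size)
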