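"""Synthetic multi-tissue BCR repertoire generator.

Emulates the study design the analyses assume: several patients, each with
tumor tissue cut into three fragments, three draining-LN pieces, and PBMC,
every fragment split into two cell-suspension replicates. Structure put into
the data, all seeded and recorded in a ground-truth ledger:

* junctions assembled as germline V 3' end ∥ untemplated N codons ∥ germline
  J 5' start from a packaged pseudo-germline reference (~10 alleles each);
* clonal lineages grown as mutation trees with Poisson per-branch junction
  substitutions (somatic hypermutation);
* tissue sharing controlled by a symmetric pairwise probability matrix;
* per-clone expression weights log-normal with configurable sigma, emulating
  the plasma-cell dominance of RNA-based repertoires (hundreds-fold IGH
  expression differences);
* per-fragment log-normal weight jitter (spatial heterogeneity), shared by
  the two replicates of a fragment;
* planted expansions (weight × fold in one target fragment) and planted
  cross-sample UMI contamination.

Replicate sampling is multinomial over clone expression weights, so
replicates differ only by molecular sampling noise — exactly the null the
expansion test calibrates against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PlantedExpansion",
    "SimResult",
    "simulate",
    "repertoires_by_sample",
    "worked_fixtures",
    "GERMLINE_V_JUNCTION",
    "GERMLINE_J_JUNCTION",
]

# Pseudo-germline junction contributions. V alleles end with the conserved
# Cys codon (TGT) plus two framework codons; J alleles close with the
# conserved Trp codon (TGG). No IMGT download; these are packaged constants.
GERMLINE_V_JUNCTION: dict[str, str] = {
    "IGHV1-1*01": "TGTGCGAGA",
    "IGHV1-2*01": "TGTGCGAAA",
    "IGHV2-1*01": "TGTACGACA",
    "IGHV3-1*01": "TGTGCCAGG",
    "IGHV3-2*01": "TGTGCTCGA",
    "IGHV4-1*01": "TGTGTGAGA",
    "IGHV4-2*01": "TGTGCGGGA",
    "IGHV5-1*01": "TGTCAGAGA",
    "IGHV6-1*01": "TGTGGGAGA",
    "IGHV7-1*01": "TGTGCACGA",
}
GERMLINE_J_JUNCTION: dict[str, str] = {
    "IGHJ1*01": "TTTGACTGG",
    "IGHJ2*01": "TATGATTGG",
    "IGHJ3*01": "TTCGATTGG",
    "IGHJ4*01": "TACGACTGG",
    "IGHJ5*01": "TTTGATTGG",
    "IGHJ6*01": "TACGGGTGG",
    "IGHJ7*01": "TTCGGCTGG",
    "IGHJ8*01": "TATGGTTGG",
    "IGHJ9*01": "TTTGGCTGG",
    "IGHJ10*01": "TACGCTTGG",
}

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_AA = {}


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


@dataclass(frozen=True)
class PlantedExpansion:
    """Multiply ``n_clones`` singleton clones' weights by ``fold`` in one
    target fragment of one tissue."""

    n_clones: int = 10
    fold: float = 8.0
    tissue: str = "tum"
    fragment: int = 1


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    n_patients: int = 1
    tissues: dict = field(default_factory=lambda: {"tum": 3, "LN": 3, "PBMC": 1})
    replicates: int = 2
    n_naive_clones: int = 400
    lineage_fraction: float = 0.15
    lineage_extra_mean: float = 4.0  # mean extra members per seeded lineage (geometric)
    branch_mutations_mean: float = 2.0  # Poisson junction substitutions per branch
    sharing: dict = field(
        default_factory=lambda: {
            frozenset({"tum", "LN"}): 0.3,
            frozenset({"tum", "PBMC"}): 0.05,
            frozenset({"LN", "PBMC"}): 0.1,
        }
    )
    isotype_mixture: dict = field(
        default_factory=lambda: {
            "tum": {"IgM": 0.15, "IgG": 0.45, "IgA": 0.40},
            "LN": {"IgM": 0.35, "IgG": 0.35, "IgA": 0.30},
            "PBMC": {"IgM": 0.30, "IgG": 0.30, "IgA": 0.40},
            "norm": {"IgM": 0.30, "IgG": 0.30, "IgA": 0.40},
        }
    )
    expression_sigma: float = 1.5
    fragment_sigma: float = 0.8
    umi_per_sample: int = 3000
    cdr3_len_aa: tuple = (8, 20)
    isotype_switch_prob: float = 0.3  # chance a lineage member redraws its isotype
    expansions: list = field(default_factory=list)
    contamination_rate: float = 0.0
    reads_per_umi_mean: float = 6.0
    umi_length: int = 12
    emit_umi_tables: bool = False

    def validate(self) -> None:
        for pair, p in self.sharing.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sharing probability out of [0,1] for {set(pair)}")
        for tis, mix in self.isotype_mixture.items():
            if abs(sum(mix.values()) - 1) > 1e-9:
                raise ValueError(f"isotype mixture for {tis} does not sum to 1")
        if self.lineage_fraction * self.lineage_extra_mean >= 5:
            raise ValueError("infeasible config: lineage mass exceeds clone count")
        if self.replicates < 1 or self.n_naive_clones < 1:
            raise ValueError("replicates and n_naive_clones must be >= 1")


@dataclass
class SimResult:
    airr: pd.DataFrame
    umi: pd.DataFrame | None
    truth: dict  # "clones", "expansions", "contamination" DataFrames
    germline_v: dict
    germline_j: dict
    config: SimConfig


def _random_junction(rng: np.random.Generator, v: str, j: str, len_aa: int) -> str:
    """Germline V-end ∥ non-stop random codons ∥ germline J-start."""
    v_part, j_part = GERMLINE_V_JUNCTION[v], GERMLINE_J_JUNCTION[j]
    n_codons = len_aa - (len(v_part) + len(j_part)) // 3
    mid = []
    while len(mid) < n_codons:
        codon = "".join(rng.choice(_BASES, 3))
        if codon not in _STOPS:
            mid.append(codon)
    return v_part + "".join(mid) + j_part


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Apply n point substitutions, resampling any that create a stop codon."""
    s = list(seq)
    for _ in range(n_mut):
        for _attempt in range(20):
            pos = int(rng.integers(len(s)))
            new = rng.choice([b for b in "ACGT" if b != s[pos]])
            old = s[pos]
            s[pos] = new
            codon_start = pos - pos % 3
            if "".join(s[codon_start : codon_start + 3]) in _STOPS:
                s[pos] = old
                continue
            break
    return "".join(s)


def simulate(config: SimConfig) -> SimResult:
    """Generate AIRR clonotype tables (one row per clonotype per sample), an
    optional UMI-level table, and the ground-truth ledger. Deterministic
    under a fixed ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    v_names = sorted(GERMLINE_V_JUNCTION)
    j_names = sorted(GERMLINE_J_JUNCTION)
    tissue_names = list(config.tissues)

    clone_rows: list[dict] = []
    clones: list[dict] = []
    lineage_counter = 0
    for p in range(config.n_patients):
        patient = f"p{p + 1}"
        n_lineage_seeds = int(round(config.n_naive_clones * config.lineage_fraction))
        for ci in range(config.n_naive_clones):
            v = v_names[int(rng.integers(len(v_names)))]
            j = j_names[int(rng.integers(len(j_names)))]
            len_aa = int(rng.integers(config.cdr3_len_aa[0], config.cdr3_len_aa[1] + 1))
            junction = _random_junction(rng, v, j, len_aa)
            primary = tissue_names[int(rng.integers(len(tissue_names)))]
            present = {primary}
            for other in tissue_names:
                if other == primary:
                    continue
                pr = config.sharing.get(frozenset({primary, other}), 0.0)
                if rng.random() < pr:
                    present.add(other)
            mix = config.isotype_mixture[primary]
            isotype = rng.choice(list(mix), p=list(mix.values()))
            seeds_lineage = ci < n_lineage_seeds
            lineage_id = ""
            if seeds_lineage:
                lineage_counter += 1
                lineage_id = f"{patient}-lin{lineage_counter}"
            naive = {
                "clone_id": f"{patient}-c{ci}",
                "patient_id": patient,
                "junction": junction,
                "v_call": v,
                "j_call": j,
                "isotype": str(isotype),
                "primary_tissue": primary,
                "tissues": ",".join(sorted(present)),
                "present": present,
                "lineage_id": lineage_id,
                "true_mutations": 0,
                "weight": float(rng.lognormal(0.0, config.expression_sigma)),
            }
            clones.append(naive)
            if seeds_lineage:
                extra = 1 + int(rng.geometric(1.0 / config.lineage_extra_mean))
                family = [naive]
                for mi in range(extra):
                    parent = family[int(rng.integers(len(family)))]
                    n_mut = int(rng.poisson(config.branch_mutations_mean))
                    mutated = _mutate(rng, parent["junction"], max(n_mut, 1))
                    member_present = {primary}
                    for other in tissue_names:
                        if other == primary:
                            continue
                        pr = config.sharing.get(frozenset({primary, other}), 0.0)
                        if rng.random() < pr:
                            member_present.add(other)
                    iso = parent["isotype"]
                    if rng.random() < config.isotype_switch_prob:
                        iso = str(rng.choice(list(mix), p=list(mix.values())))
                    member = {
                        "clone_id": f"{naive['clone_id']}.m{mi}",
                        "patient_id": patient,
                        "junction": mutated,
                        "v_call": v,
                        "j_call": j,
                        "isotype": iso,
                        "primary_tissue": primary,
                        "tissues": ",".join(sorted(member_present)),
                        "present": member_present,
                        "lineage_id": lineage_id,
                        "true_mutations": sum(
                            a != b for a, b in zip(mutated, naive["junction"])
                        ),
                        "weight": float(rng.lognormal(0.0, config.expression_sigma)),
                    }
                    clones.append(member)
                    family.append(member)

    clone_rows = [{k: v for k, v in c.items() if k != "present"} for c in clones]

    # planted expansions: singleton clones present in the target tissue
    expansion_rows: list[dict] = []
    boost: dict[tuple[str, str, int], float] = {}  # (clone_id, tissue, fragment) -> fold
    for exp in config.expansions:
        candidates = [
            c for c in clones if not c["lineage_id"] and exp.tissue in c["present"]
        ]
        chosen_idx = rng.choice(len(candidates), size=min(exp.n_clones, len(candidates)), replace=False)
        for i in np.sort(chosen_idx):
            c = candidates[int(i)]
            boost[(c["clone_id"], exp.tissue, exp.fragment)] = exp.fold
            expansion_rows.append(
                {
                    "clone_id": c["clone_id"],
                    "tissue": exp.tissue,
                    "fragment": exp.fragment,
                    "fold": exp.fold,
                }
            )

    airr_rows: list[dict] = []
    umi_rows: list[dict] = []
    for p in range(config.n_patients):
        patient = f"p{p + 1}"
        pclones = [c for c in clones if c["patient_id"] == patient]
        for tissue, n_frag in config.tissues.items():
            in_tissue = [c for c in pclones if tissue in c["present"]]
            if not in_tissue:
                continue
            for frag in range(1, n_frag + 1):
                jitter = rng.lognormal(0.0, config.fragment_sigma, size=len(in_tissue))
                weights = np.array([c["weight"] for c in in_tissue]) * jitter
                for idx, c in enumerate(in_tissue):
                    fold = boost.get((c["clone_id"], tissue, frag))
                    if fold:
                        weights[idx] *= fold
                probs = weights / weights.sum()
                for rep in range(1, config.replicates + 1):
                    counts = rng.multinomial(config.umi_per_sample, probs)
                    sample_id = f"{patient}_{tissue}{frag}_r{rep}"
                    for idx in np.nonzero(counts)[0]:
                        c = in_tissue[int(idx)]
                        airr_rows.append(
                            {
                                "sequence_id": f"{sample_id}-{c['clone_id']}",
                                "junction": c["junction"],
                                "junction_aa": _translate(c["junction"]),
                                "v_call": c["v_call"],
                                "j_call": c["j_call"],
                                "c_call": {"IgM": "IGHM", "IgG": "IGHG1", "IgA": "IGHA1"}[
                                    c["isotype"]
                                ],
                                "duplicate_count": int(counts[idx]),
                                "sample_id": sample_id,
                                "patient_id": patient,
                                "tissue": tissue,
                                "fragment_id": f"{tissue}{frag}",
                                "replicate_id": f"r{rep}",
                                "germline_mutations": c["true_mutations"],
                                "clone_id": c["clone_id"],
                            }
                        )
                    if config.emit_umi_tables:
                        for idx in np.nonzero(counts)[0]:
                            c = in_tissue[int(idx)]
                            for _u in range(int(counts[idx])):
                                tag = "".join(rng.choice(_BASES, config.umi_length))
                                umi_rows.append(
                                    {
                                        "sample_id": sample_id,
                                        "umi": tag,
                                        "sequence": c["junction"],
                                        "reads": 3 + int(rng.poisson(config.reads_per_umi_mean)),
                                        "clone_id": c["clone_id"],
                                    }
                                )

    contamination_rows: list[dict] = []
    if config.emit_umi_tables and config.contamination_rate > 0 and umi_rows:
        samples = sorted({r["sample_id"] for r in umi_rows})
        n_contam = int(round(config.contamination_rate * len(umi_rows)))
        src_idx = rng.choice(len(umi_rows), size=n_contam, replace=False)
        for i in np.sort(src_idx):
            src = umi_rows[int(i)]
            others = [s for s in samples if s != src["sample_id"]]
            dst = others[int(rng.integers(len(others)))]
            # carried-over molecules re-amplify weakly: well under the source
            reads = max(1, int(round(src["reads"] / (6 + rng.random() * 4))))
            umi_rows.append(
                {
                    "sample_id": dst,
                    "umi": src["umi"],
                    "sequence": src["sequence"],
                    "reads": reads,
                    "clone_id": src["clone_id"],
                }
            )
            contamination_rows.append(
                {
                    "umi": src["umi"],
                    "from_sample": src["sample_id"],
                    "to_sample": dst,
                    "source_reads": src["reads"],
                    "contam_reads": reads,
                }
            )

    airr = pd.DataFrame(airr_rows)
    umi = pd.DataFrame(umi_rows) if config.emit_umi_tables else None
    truth = {
        "clones": pd.DataFrame(clone_rows),
        "expansions": pd.DataFrame(
            expansion_rows, columns=["clone_id", "tissue", "fragment", "fold"]
        ),
        "contamination": pd.DataFrame(
            contamination_rows,
            columns=["umi", "from_sample", "to_sample", "source_reads", "contam_reads"],
        ),
    }
    return SimResult(airr, umi, truth, dict(GERMLINE_V_JUNCTION), dict(GERMLINE_J_JUNCTION), config)


def repertoires_by_sample(airr: pd.DataFrame) -> dict:
    """Split a simulated (or read) AIRR table into per-sample Repertoires."""
    from .io import repertoire_from_frame

    return {
        sample: repertoire_from_frame(group, metadata={"sample_id": sample})
        for sample, group in airr.groupby("sample_id")
    }


def worked_fixtures() -> dict:
    """The hand-checkable toy datasets used across module examples.

    * ``f2_toy``: two 2-clonotype samples sharing one clonotype with
      frequencies 0.5 and 0.2 — F2 = sqrt(0.1) ≈ 0.31623.
    * ``triangle_toy``: a 10-member clonal group split 6/3/1 over
      tum/LN/PBMC — chi² = 3.8, p ≈ 0.1496.
    * ``umi_collision``: one UMI tag in two samples with identical sequence
      and 12 vs 2 reads — ratio 6 > 5, removed from the low-read sample only.
    """
    f2_toy = pd.DataFrame(
        [
            ("A-1", "TGTGCGAGAGATTGG", "IGHV1-1*01", "IGHJ1*01", "IGHG1", 5, "A"),
            ("A-2", "TGTGCGAGAGCTTGG", "IGHV1-1*01", "IGHJ1*01", "IGHG1", 5, "A"),
            ("B-1", "TGTGCGAGAGATTGG", "IGHV1-1*01", "IGHJ1*01", "IGHG1", 2, "B"),
            ("B-3", "TGTGCGAGAGGGTGG", "IGHV1-1*01", "IGHJ1*01", "IGHA1", 8, "B"),
        ],
        columns=["sequence_id", "junction", "v_call", "j_call", "c_call", "duplicate_count", "sample_id"],
    )
    tissues = ["tum"] * 6 + ["LN"] * 3 + ["PBMC"]
    triangle_toy = pd.DataFrame(
        {
            "sequence_id": [f"t-{i}" for i in range(10)],
            "junction": ["TGTGCGAGA" + m + "TTTGACTGG" for m in
                         ["AAA", "AAC", "AAG", "ACA", "ACC", "ACG", "AGA", "AGC", "AGG", "ATA"]],
            "v_call": "IGHV1-1*01",
            "j_call": "IGHJ1*01",
            "c_call": "IGHG1",
            "duplicate_count": 2,
            "sample_id": [f"p1_{t}1_r1" for t in tissues],
            "tissue": tissues,
        }
    )
    umi_collision = pd.DataFrame(
        [
            ("sample1", "AACGTACGTAGC", "TGTGCGAGAGATTGG", 12),
            ("sample2", "AACGTACGTAGC", "TGTGCGAGAGATTGG", 2),
        ],
        columns=["sample_id", "umi", "sequence", "reads"],
    )
    return {"f2_toy": f2_toy, "triangle_toy": triangle_toy, "umi_collision": umi_collision}
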