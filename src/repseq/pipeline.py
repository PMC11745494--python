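"""End-to-end orchestration: decontaminate → filter → pool → overlap /
diversity / physchem → lineages → triangle → expansion, from a single
declarative config, with a run manifest for reproducibility.

Every stage writes a TSV under the output directory; the manifest records
the parameters, input checksums, and output checksums, so a rerun with the
same config can be verified byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .decontam import UmiRecord, decontaminate
from .diversity import summarize
from .expansion import mutation_contrast, test_expansion
from .io import Repertoire, apply_filters, repertoire_from_frame
from .lineage import build_lineages, build_tree, dnds, rank_by_root_distance
from .overlap import overlap_table
from .physchem import profile
from .simulate import SimConfig, repertoires_by_sample, simulate
from .triangle import center_and_test, triangle_points

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative pipeline parameters; defaults follow the analysis
    conventions (top-109 per isotype, top-100 physchem, >60% dominant
    isotype, ratio-5 decontamination, FDR 0.05)."""

    out_dir: str = "repseq_out"
    airr_paths: list = field(default_factory=list)
    umi_table: str | None = None
    sim: dict | None = None  # SimConfig kwargs; used when airr_paths is empty
    seed: int = 0
    min_umi_per_clonotype: int = 2
    min_clonotypes: int = 50
    top_n: int = 109
    physchem_top_n: int = 100
    window: int = 5
    decontam_ratio: float = 5.0
    dominant_cutoff: float = 0.6
    lineage_threshold: object = "auto"
    min_tree_size: int = 5
    fdr: float = 0.05
    compartments: tuple = ("tum", "LN", "PBMC")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for p in cfg.airr_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if cfg.umi_table and not Path(cfg.umi_table).exists():
            raise FileNotFoundError(f"input path does not exist: {cfg.umi_table}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = path

    stage = "load"
    try:
        if config.airr_paths:
            frames = [pd.read_csv(p, sep="\t") for p in config.airr_paths]
            airr = pd.concat(frames, ignore_index=True)
            germline_v = germline_j = None
        else:
            sim_kwargs = dict(config.sim or {})
            sim_kwargs.setdefault("seed", config.seed)
            if "expansions" in sim_kwargs:
                from .simulate import PlantedExpansion

                sim_kwargs["expansions"] = [
                    PlantedExpansion(**e) for e in sim_kwargs["expansions"]
                ]
            if "sharing" in sim_kwargs:
                sim_kwargs["sharing"] = {
                    frozenset(k.split("-")): v for k, v in sim_kwargs["sharing"].items()
                }
            result = simulate(SimConfig(**sim_kwargs))
            airr = result.airr
            germline_v, germline_j = result.germline_v, result.germline_j
            write("simulated_airr.tsv", airr)
            if result.umi is not None:
                write("simulated_umi.tsv", result.umi)

        stage = "decontam"
        if config.umi_table:
            umi_df = pd.read_csv(config.umi_table, sep="\t")
            records = [
                UmiRecord(r.sample_id, r.umi, r.sequence, int(r.reads))
                for r in umi_df.itertuples()
            ]
            kept, log = decontaminate(records, ratio=config.decontam_ratio)
            write("decontam_removals.tsv", log)

        stage = "filter"
        reps = repertoires_by_sample(airr)
        filter_rows, kept_reps = [], {}
        for sample, rep in sorted(reps.items()):
            res = apply_filters(rep, config.min_umi_per_clonotype, config.min_clonotypes)
            filter_rows.append(
                {
                    "sample_id": sample,
                    "n_clonotypes": len(res.repertoire),
                    "excluded": res.excluded,
                    "reason": res.reason or "",
                }
            )
            if not res.excluded:
                kept_reps[sample] = res.repertoire
        write("filter_report.tsv", pd.DataFrame(filter_rows))
        if not kept_reps:
            raise ValueError("all samples excluded by preprocessing filters")

        stage = "overlap"
        rows = [
            {
                "sample_i": r.sample_i,
                "sample_j": r.sample_j,
                "metric": r.metric,
                "isotype": r.isotype,
                "value": r.value,
                "n_shared": r.n_shared,
                "n_top_used": r.n_top_used,
                "undefined": r.undefined,
            }
            for r in overlap_table(kept_reps, top_n=config.top_n)
        ]
        write("overlap.tsv", pd.DataFrame(rows))

        stage = "diversity"
        div_rows = []
        for sample, rep in sorted(kept_reps.items()):
            s = summarize(rep)
            row = {
                "sample_id": sample,
                "clonality": s.clonality,
                "shannon": s.shannon,
                "richness": s.richness,
            }
            row.update({f"frac_{k}": v for k, v in sorted(s.isotype_fractions.items())})
            div_rows.append(row)
        write("diversity.tsv", pd.DataFrame(div_rows))

        stage = "physchem"
        phys_rows = []
        for sample, rep in sorted(kept_reps.items()):
            pr = profile(rep, top_n=config.physchem_top_n, window=config.window)
            row = {"sample_id": sample, "mean_cdr3_len": pr.mean_cdr3_len, "n_used": pr.n_used}
            row.update(pr.descriptors)
            phys_rows.append(row)
        write("physchem.tsv", pd.DataFrame(phys_rows))

        stage = "lineages"
        # lineage analysis keeps singletons and pools patient-wise
        by_patient: dict[str, list[Repertoire]] = {}
        for sample, rep in sorted(reps.items()):
            patient = str(rep.metadata.get("patient_id", "")) or sample.split("_")[0]
            by_patient.setdefault(patient, []).append(rep)
        lineage_rows, tree_rows, newicks = [], [], []
        tissue_of_key: dict[tuple, set] = {}
        all_lineages = []
        for patient, plist in sorted(by_patient.items()):
            merged_rows = pd.concat([r.to_frame() for r in plist], ignore_index=True)
            pooled = repertoire_from_frame(
                merged_rows, metadata={"sample_id": patient, "patient_id": patient}
            )
            for r in plist:
                for c in r:
                    tissue_of_key.setdefault(c.key, set()).add(c.tissue)
            lineages, tres = build_lineages(
                pooled,
                threshold=config.lineage_threshold,
                germline_v=germline_v,
                germline_j=germline_j,
            )
            all_lineages.extend(lineages)
            for lin in lineages:
                lineage_rows.append(
                    {
                        "patient_id": patient,
                        "lineage_id": lin.lineage_id,
                        "size": lin.size,
                        "v_gene": lin.v_gene,
                        "j_gene": lin.j_gene,
                        "cdr3_len": lin.cdr3_len,
                        "threshold": lin.threshold_used,
                        "threshold_flagged": tres.flagged,
                    }
                )
                if lin.size >= config.min_tree_size and lin.germline_outgroup:
                    tree = build_tree(lin, min_size=config.min_tree_size)
                    dn = dnds(lin)
                    newicks.append(str(tree.tree).strip())
                    for m in lin.members:
                        tree_rows.append(
                            {
                                "lineage_id": lin.lineage_id,
                                "cdr3_nt": m.cdr3_nt,
                                "distance_to_root": tree.distance_to_root[m.key],
                                "rank": tree.ranks[m.key],
                                "dnds": dn.dnds if not dn.undefined else "",
                            }
                        )
        write("lineages.tsv", pd.DataFrame(lineage_rows))
        write("trees.tsv", pd.DataFrame(tree_rows))
        (out / "trees.nwk").write_text("\n".join(newicks) + ("\n" if newicks else ""))
        outputs["trees.nwk"] = out / "trees.nwk"

        stage = "triangle"
        points = triangle_points(
            [l for l in all_lineages if l.size >= 2],
            compartment_of=lambda c: sorted(tissue_of_key.get(c.key, set())),
            compartments=tuple(config.compartments),
            cutoff=config.dominant_cutoff,
        )
        tri_rows = [
            {
                "lineage_id": p.lineage_id,
                "count_" + config.compartments[0]: p.counts[0],
                "count_" + config.compartments[1]: p.counts[1],
                "count_" + config.compartments[2]: p.counts[2],
                "dominant_isotype": p.dominant_isotype,
                "size": p.size,
                "chi2": p.chi2,
                "p": p.p,
                "low_count": p.low_count,
            }
            for p in points
        ]
        write("triangle.tsv", pd.DataFrame(tri_rows))
        summary = center_and_test(points) if points else {}

        stage = "expansion"
        frag_groups: dict[tuple, list[Repertoire]] = {}
        for sample, rep in sorted(kept_reps.items()):
            key = (
                str(rep.metadata.get("patient_id", "")),
                str(rep.metadata.get("tissue", "")),
                str(rep.metadata.get("fragment_id", "")),
            )
            frag_groups.setdefault(key, []).append(rep)
        exp_rows = []
        frag_keys = sorted(frag_groups)
        for i in range(len(frag_keys)):
            for j in range(i + 1, len(frag_keys)):
                a, b = frag_keys[i], frag_keys[j]
                if a[0] != b[0] or a[1] != b[1] or a[1] != "tum":
                    continue
                results = test_expansion(
                    frag_groups[a], frag_groups[b], alpha_fdr=config.fdr
                )
                for r in results:
                    exp_rows.append(
                        {
                            "patient_id": a[0],
                            "fragment_a": a[2],
                            "fragment_b": b[2],
                            "cdr3_nt": r.key[0],
                            "v_gene": r.key[1],
                            "j_gene": r.key[2],
                            "logfc": r.logfc,
                            "p": r.p,
                            "fdr": r.fdr,
                            "expanded": r.expanded,
                        }
                    )
        write("expansion.tsv", pd.DataFrame(exp_rows))
    except StageError:
        raise
    except Exception as exc:  # halt with the stage name; partial outputs remain
        raise StageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "triangle_summary": summary,
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
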