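# repseq

Multi-tissue B-cell receptor (BCR) repertoire analysis for immunologists
studying how B cells are shared between a tumor, its draining lymph nodes
(LNs), and peripheral blood. Starting from AIRR-style clonotype tables
(one row per CDR-H3/V/J clonotype per sample, quantified by unique
molecular identifiers), the library covers the full analysis chain:

* **UMI decontamination** — a UMI tag seen in several samples with the same
  consensus sequence is contamination; read-count ratios (> 5×) decide
  which sample keeps it.
* **Preprocessing** — singleton-UMI exclusion, ≤ 50-clonotype sample cut,
  replicate pooling by mean frequency.
* **Overlap and diversity** — F2 = Σ√(fᵢfⱼ) over shared clonotypes, the
  frequency-free D = d_ij/(dᵢdⱼ), log-frequency correlation R, all on
  matched top-N-per-isotype subsets (N = 109); clonality
  1 − H/ln(richness); isotype composition.
* **CDR-H3 physicochemistry** — charge, Kyte–Doolittle hydropathy,
  predicted interaction strength, and Kidera factors kf1–kf9 on the five
  central residues of the top-100 clonotypes.
* **Clonal lineages and phylogeny** — V/J/length partition, automatic
  identity threshold from the distance-to-nearest distribution,
  single-linkage lineages, neighbor-joining trees rooted on a germline V∥J
  outgroup, distance-to-root ranks, and Nei–Gojobori dN/dS versus the MRCA.
* **Tissue triangles** — clonal-group composition across three compartments
  as barycentric coordinates, dominant-isotype labels (> 60%), and
  chi-squared eccentricity tests.
* **Expanded clonotypes** — replicate-calibrated exact tests on
  UMI-normalized pseudo-counts; expanded ⇔ FDR < 0.05 and logFC > 0; plus
  the hypermutation contrast between expanded and non-expanded clonotypes.
* **Synthetic cohorts** — a seeded generator of multi-patient,
  multi-fragment, duplicate-replicate repertoires with controlled tissue
  sharing, SHM lineages, plasma-cell expression overdispersion, planted
  expansions, and planted contamination, with a ground-truth ledger.

See `docs/methods.md` for the models and conventions, and `examples/` for
one narrative script per capability.

## Worked example

```python
from repseq.overlap import f2
from repseq.simulate import SimConfig, simulate, repertoires_by_sample

res = simulate(SimConfig(seed=42, n_naive_clones=300))
reps = repertoires_by_sample(res.airr)
tum = reps["p1_tum1_r1"]
for other in ("p1_tum1_r2", "p1_tum2_r1", "p1_LN1_r1", "p1_PBMC1_r1"):
    print(other, round(f2(tum, reps[other]), 3))
```

prints

```
p1_tum1_r2 0.979
p1_tum2_r1 0.816
p1_LN1_r1 0.322
p1_PBMC1_r1 0.038
```

Replicates of one tumor fragment overlap almost completely (F2 ≈ 0.98 —
only molecular sampling noise separates them), fragments of one tumor less
(0.82, spatial heterogeneity), and the tumor shares far more of its
repertoire with the draining LN (0.32) than with blood (0.04) — the
clone-sharing structure the cohort was generated with, recovered from the
sampled repertoires. Running `examples/01_overlap_and_clonality.py` prints
this table together with D, R, and per-sample clonality.

A complete run — decontamination, filtering, overlap, diversity,
physicochemistry, lineages and trees, triangles, expansion — is one call:

```sh
repseq run --config run.yaml     # or: repseq simulate --seed 1 --out sim/
```

where `run.yaml` names either input AIRR TSVs or a simulation block; every
stage writes a TSV plus a `manifest.json` of parameters and output
checksums (reruns are byte-identical).

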