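# Methods

`repseq` analyzes immunoglobulin heavy-chain (IGH) repertoires sampled from
several compartments of the same patient — tumor fragments, draining lymph
node (LN) pieces, peripheral blood (PBMC), adjacent normal tissue — each
fragment split into two cell-suspension replicates and quantified by unique
molecular identifiers (UMIs). This note documents the models, conventions,
and numerical choices behind each stage, and what the synthetic-data tests
do and do not establish about real data.

## Units of analysis

A **clonotype** is the triple (CDR-H3 nucleotide sequence, V gene, J gene).
The constant-region class (isotype) is excluded from the identity key
because class switching changes it within one B-cell clone; input rows that
share a key but differ in `c_call` are merged with summed UMI counts, and
the merged record takes the isotype of its highest-UMI constituent (ties
broken IgM > IgG > IgA — deterministic, dominant-expression logic).
Frequencies are UMI fractions within a sample. All sequence coordinates are
0-based, half-open.

## Preprocessing

* **UMI decontamination.** A UMI tag observed in two or more samples with
  identical or near-identical consensus sequences is treated as cross-sample
  contamination. If the highest read count exceeds every other involved
  sample's count by strictly more than `ratio` (default 5), the UMI is
  removed from the low-count samples only; otherwise (including a ratio of
  exactly 5) from all involved samples. With three or more samples the
  max-read sample must beat *all* others — the conservative generalization
  of the pairwise rule. "Near-identical" is operationalized as global
  identity ≥ 0.9 on an equal-length trim (configurable; there is no
  canonical cutoff) with single-linkage grouping of same-tag records.
* **Clonotype filters.** Clonotypes backed by a single UMI are removed for
  individual-clonotype analyses (they may be cDNA-synthesis errors) but kept
  for lineage analysis, where sample size matters more than per-record
  purity. Samples with 50 or fewer surviving clonotypes are flagged
  excluded — flagged, not silently dropped, so exclusion is auditable.
* **Pooling.** Replicates/fragments are pooled by averaging each
  clonotype's frequency over the files being pooled, with absence counted
  as frequency 0. A mean over a common clonotype universe already sums
  to 1; the result is renormalized anyway as a numerical guard. Pooled
  frequencies give every file equal weight regardless of sequencing depth.

## Overlap and diversity

Overlap metrics depend on repertoire richness, so pairwise comparisons
restrict both samples to the same number of top clonotypes per isotype
(default N = 109); if fewer are available, all are used and a shortfall flag
is set rather than excluding the sample. Ties at rank N break by
(UMI count desc, CDR-H3 lexicographic) for determinism.

* **F2** = Σ_shared √(f_i·f_j) on renormalized top-N frequency vectors.
  Frequency-weighted; equals 1 iff the vectors coincide (Cauchy–Schwarz).
* **D** = d_ij/(d_i·d_j) — shared count over the product of richnesses;
  frequency-free.
* **R** — Pearson correlation of log10 frequencies of shared clonotypes
  (the convention of the standard repertoire toolkits); undefined and
  flagged below 3 shared clonotypes. The same top-N restriction is applied
  to all three metrics.
* **Clonality** = 1 − H/ln(richness), H the Shannon entropy in nats; 0 for
  a perfectly even repertoire, defined as 1.0 for a single-clonotype
  repertoire (the maximally clonal limit). Base cancels in the ratio.
* **Isotype fractions** default to frequency mass ("percentage of the
  repertoire"); clonotype counting is available. Unknown isotypes are kept
  in repertoires but excluded from per-isotype analyses.

## CDR-H3 physicochemistry

Descriptors are computed on the five central residues of each CDR-H3 — the
loop apex most likely to contact antigen — for the top-100 clonotypes, then
averaged unweighted (each clonotype counts once regardless of frequency).
The central window starts at floor((len − w)/2), the left-biased convention
of common toolkits; shorter sequences are used whole.

* charge = (#K + #R) − (#D + #E); histidine excluded under the pH-7 net
  charge convention (configurable).
* hydropathy = mean Kyte–Doolittle index.
* predicted interaction strength = count of strongly interacting residues
  {F, I, L, M, V, W, Y}; no standard closed-form definition exists, so the
  residue set is a packaged, overridable resource.
* kf1–kf10 = mean Kidera factors — ten orthogonal scores that compress 188
  physical amino-acid properties, standardized to mean 0 and variance 1
  over the 20 residues. The packaged table is asserted against that
  standardization (tolerance 0.05) and its kf4 column against the Kidera
  hydrophobicity scale packaged independently in biopython, guarding
  against transcription errors. kf1–kf9 are reported by default.

Non-standard residues raise an error rather than being skipped silently.
Group comparisons use two-sided t or Mann–Whitney tests per descriptor with
Bonferroni or Holm correction.

## Clonal lineages and hypermutation phylogeny

Lineages are inferred per patient on pooled repertoires (singletons
retained): partition by (V, J, CDR-H3 length) — the D segment is too
unreliable to use — then single-linkage clustering of junctions at a
normalized Hamming-distance threshold. Because all members of a partition
share length, no alignment is needed.

The threshold is the local minimum of the distance-to-nearest distribution:
each clonotype's distance to its nearest non-identical neighbor within its
partition is collected; a Gaussian KDE (Silverman bandwidth, 512-point grid
on [0, 1]) separates the SHM-variant mode from the unrelated-junction mode,
and the deepest minimum between the two largest modes, restricted to
(0.05, 0.5), is returned. Typical values are 0.15–0.20 (80–85% identity).
Guards: fewer than 20 distances, a constant sample, a second mode below 5%
of the main mode's height, or no genuine dip (minimum above 90% of the
smaller mode) all fall back to 0.15 with a flag.

Trees are built for lineages of five or more members: neighbor joining
(scikit-bio) on pairwise normalized Hamming distances, with a germline
outgroup — the conjugate of the germline V 3' end and J 5' start, the
untemplated middle masked as `N` and excluded from every distance involving
the outgroup — standing in for the most recent common ancestor (MRCA) and
rooting the tree. Members are sorted lexicographically before the distance
matrix is assembled, so trees are independent of input order; negative NJ
branch lengths are clamped to zero; distances to root are rounded to 1e-9
before ranking so numerical ties share an average rank. Maximum-likelihood
inference (GTR+Γ) is out of scope; NJ on Hamming distances is deterministic
and sufficient for the rank and dN/dS analyses built on the trees, but
branch lengths should not be read as substitution-model estimates — a
deliberate fidelity caveat.

Hypermutation load is the Hamming distance to the reference over
reference-covered positions (junction only for short-read data; V region
plus junction when available), or a precomputed `germline_mutations` column
verbatim when the input table carries one.

**dN/dS** is Nei–Gojobori counting pooled over the lineage against the MRCA
sequence: synonymous site fractions per reference codon, pathway averaging
for multi-hit codons (changes through stop codons counted as
nonsynonymous), dN/dS = (Nd/N)/(Sd/S). Zero synonymous substitutions yield
an undefined flag — no pseudocounts, because a fabricated denominator would
manufacture selection signals. Codons containing masked positions are
skipped. Pooling per tree (rather than per branch) matches the scale at
which selection is interpreted here.

## Tissue-distribution (triangle) analysis

Each clonal group's members are attributed to their compartments of
observation; a clonotype seen in k compartments contributes one count to
each — the only counting rule under which the three shares sum to 1. The
shares are barycentric coordinates in a triangle whose vertices are the
compartments (tum/LN/PBMC, three LNs, or three tumor fragments). Groups are
labeled by dominant isotype when one isotype strictly exceeds 60% of member
clonotypes, else "mixed". Per-group eccentricity is a chi-squared
goodness-of-fit of the counts against uniform (df = 2; groups smaller than
6 are flagged low-count since expected cells drop below 2); the group set
is summarized by the unweighted mean of coordinates plus a pooled
chi-squared on summed counts.

## Expanded-clonotype detection

Counts are first placed on a common scale: pseudo-count = round(frequency ×
total UMIs over all sample groups). This removes depth differences (e.g.
unequal fragment sizes) but inflates counts beyond the per-sample molecular
sampling depth by a roughly constant factor. Per clonotype, summed group-A
versus group-B pseudo-counts are compared by a conditional exact test on
the clonotype total, with the null split proportional to group library
sizes: a binomial when the dispersion is 1 (pure sampling), otherwise a
beta-binomial whose per-clonotype intra-class correlation is chosen to give
a constant variance-inflation factor. That factor defaults to a moment
estimate — the pooled variance-to-mean ratio of pseudo-counts across
replicates — which absorbs both the scale inflation of the transform and
any extra biological replicate variability; with only two replicates per
group, tagwise dispersion estimation is not supportable, which is why a
single pooled factor replaces the original negative-binomial machinery.
Two-sided p-values double the smaller tail; BH-FDR across clonotypes;
logFC = log2((meanA + 0.5)/(meanB + 0.5)) with the 0.5 prior stabilizing
zeros; "expanded" means FDR < 0.05 and logFC > 0. Hypermutation loads of
expanded versus non-expanded clonotypes are contrasted by two-sided
Mann–Whitney.

## Synthetic cohorts

The generator emulates the replicated multi-tissue design: junctions are
germline V-end ∥ random non-stop codons ∥ germline J-start over a packaged
pseudo-germline set (10 V, 10 J alleles; no external reference download);
lineages grow as mutation trees with Poisson(2) junction substitutions per
branch (stop codons resampled); tissue co-occurrence follows a symmetric
sharing matrix (defaults: tum–LN 0.3, tum–PBMC 0.05, LN–PBMC 0.1, chosen to
mirror the qualitative ordering the analyses should recover); per-clone
expression weights are log-normal with σ = 1.5, emulating the
plasma-cell-driven hundreds-fold spread of IGH expression in RNA-based
repertoires; fragments jitter clone weights log-normally (σ = 0.8, shared
by a fragment's two replicates) to create spatial heterogeneity; replicate
sampling is multinomial (default 3,000 UMIs/sample, raised to 25,000 for
expansion benchmarks so per-clonotype counts support exact testing).
Planted expansions multiply chosen singleton clones' weights in one target
fragment; planted contamination copies UMI records into another sample at a
fraction of the source read count. Everything is recorded in a ground-truth
ledger and is deterministic under a fixed seed.

What the generator does *not* model: AID hotspot motifs and biased SHM
spectra, class-switch ordering, indels in junctions, V-allele polymorphism,
sequencing error within UMI consensuses, and realistic germline diversity.
Passing tests therefore establish that the implementations compute their
definitions correctly and recover planted structure under idealized
sampling — not that the biological effect sizes seen in patient data would
be reproduced.

## Problem sizes and determinism

Stochastic checks use cohorts of 300–1,000 clones, 50–100 seeds per
property, and 2,000-point distance samples for threshold recovery — sizes
at which each property is decided in seconds while keeping every planted
signal comfortably above sampling noise. All randomness flows through
`numpy.random.default_rng` seeds; the pipeline writes a manifest of
parameter values and output checksums, and reruns with the same config are
byte-identical.

## Known limitations

* NJ trees approximate, but are not, ML phylogenies; rank-based tree
  comparisons are the intended use.
* The junction-only mode underestimates hypermutation (V-region mutations
  are invisible) — the reason full-length data, when present, are used for
  mutation counts.
* The constant variance-inflation model of replicate noise is a first-order
  approximation; strongly clonotype-specific overdispersion would call for
  more replicates than the two this design provides.
* The decontamination similarity cutoff (0.9) is a pragmatic default, not a
  derived quantity; collisions between truly distinct molecules with the
  same tag are kept by design.
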