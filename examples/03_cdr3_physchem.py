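"""CDR-H3 physicochemical profiles (charge, hydropathy, strength, Kidera
factors) of the top-100 clonotypes, compared between tumor and PBMC.
"""

from repseq.io import pool_repertoires
from repseq.physchem import compare_groups, profile
from repseq.simulate import SimConfig, repertoires_by_sample, simulate

res = simulate(SimConfig(seed=7, n_patients=6, n_naive_clones=300))
reps = repertoires_by_sample(res.airr)

# one pooled repertoire per patient and tissue (replicates and fragments are
# not independent observations)
def pooled_profiles(tissue):
    out = []
    patients = sorted({s.split("_")[0] for s in reps})
    for p in patients:
        members = [r for s, r in sorted(reps.items()) if s.startswith(f"{p}_{tissue}")]
        out.append(profile(pool_repertoires(members), top_n=100))
    return out

tumor, pbmc = pooled_profiles("tum"), pooled_profiles("PBMC")
print(f"{len(tumor)} tumor and {len(pbmc)} PBMC patient-level profiles")
print(f"example tumor profile: mean CDR-H3 length {tumor[0].mean_cdr3_len:.1f} aa, "
      f"kf4 {tumor[0].descriptors['kf4']:+.3f}, charge {tumor[0].descriptors['charge']:+.2f}")

table = compare_groups({"tumor": tumor, "PBMC": pbmc}, test="t", correction="holm")
print("\n", table.round(4).to_string(index=False))
print(
    "\nEach row is one descriptor averaged over the 5 central CDR-H3 residues"
    "\nof the top-100 clonotypes per patient-level repertoire; p_adjusted is"
    "\nHolm-corrected. The generator draws CDR-H3s identically in all tissues,"
    "\nso any significant row is a false positive — across thirteen"
    "\ndescriptors and six patients per group an occasional one is expected."
)
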