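"""Permutation network-comparison test between two groups.

Two groups share every edge except one planted difference (partial
correlation 0 vs 0.35).  The test re-estimates both networks under
random reassignment of the pooled participants: M is the maximum
edge-weight difference (structure invariance), S the difference in
global strength; edge-level p-values are FDR-adjusted.
"""

from netpsych import nct_run
from netpsych.simulate import DEFAULT_STUDY_EDGES, PrecisionSpec, grouped_dataset

base = PrecisionSpec(8, DEFAULT_STUDY_EDGES)
data = grouped_dataset(
    {"a": 500, "b": 500}, base, delta_edges={"b": [(2, 4, 0.35)]}, seed=3
)
groups = data.split_by("group")
res = nct_run(groups["a"], groups["b"], n_perm=1000, seed=4)

print(f"M (max edge difference) = {res.M_observed:.3f}, p = {res.p_M:.4f}")
print(f"S (global strength diff) = {res.S_observed:.3f}, p = {res.p_S:.4f}")
print(f"global strengths: A = {res.global_strength_A:.2f}, "
      f"B = {res.global_strength_B:.2f}\n")
et = res.edge_tests
flagged = et[et.pvalue_fdr < 0.05]
print("edges significant after FDR correction:")
print(flagged.round(3).to_string(index=False))
print("\nThe planted X2--X4 difference should be the (only) flagged edge;")
print("a small p for M says the two structures differ beyond resampling noise.")
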