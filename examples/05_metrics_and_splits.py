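"""Evaluation metrics and similarity-cluster-based dataset splits.

Demonstrates the recovery rate, the aligned-subsequence similarity behind
IntDiv, base-pair F1 between two secondary structures, and how items are
clustered on a similarity matrix and split so that no cluster straddles
train/validation/test.
"""

import numpy as np

import ribodesign as rd

print("recovery('GGCAU', 'GGAAU') =", rd.recovery_rate("GGCAU", "GGAAU"))
print("pairwise_sim('ACGU', 'ACG') =", rd.pairwise_sim("ACGU", "ACG"),
      " (LCS length over the shorter sequence)")
print("int_div({AAAA, CCCC}) =", rd.int_div(["AAAA", "CCCC"]),
      " (self-pairs included in the |G|^2 normalizer)")

ref = rd.parse_dotbracket("(((...)))")
pred = rd.parse_dotbracket("((.....))")
p, r, f1 = rd.basepair_f1(pred, ref)
print(f"base-pair F1: precision={p:.2f} recall={r:.2f} F1={f1:.2f}")
for n in (50, 51, 100, 101):
    print(f"length {n} nt -> {rd.length_category(n)}")

# two tight similarity blocks -> two clusters at threshold 0.5
sim = np.full((6, 6), 0.1)
sim[:3, :3] = 0.9
sim[3:, 3:] = 0.9
np.fill_diagonal(sim, 1.0)
clusters = rd.agglomerative_cluster(sim, threshold=0.5,
                                    item_ids=[f"rna{i}" for i in range(6)])
print(f"\nclusters at threshold 0.5: {clusters.n_clusters} "
      f"(labels {clusters.labels.tolist()})")

many = rd.ClusterAssignment([f"rna{i}" for i in range(100)], np.arange(100), 0.8)
split = rd.make_splits(many, rd.SplitSpec(test_frac=0.15, valid_frac=0.10),
                       np.random.default_rng(0))
counts = {p: sum(v == p for v in split.values()) for p in ("train", "valid", "test")}
print("100 singleton clusters split 15%/10% ->", counts)

four = rd.make_nonoverlapping_splits(many, n_splits=4, rng=np.random.default_rng(1))
print("4 nonoverlapping eval sets, overlaps found:", rd.check_disjoint(four))
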