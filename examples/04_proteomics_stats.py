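"""Differential analysis of a low-input proteome matrix.

Generates a synthetic protein x sample log2 intensity matrix (two groups
of four replicates, 100 proteins carrying a planted 2.0 log2 fold change,
missing-not-at-random dropout), then runs the standard workflow: 30%
valid-value filter, downshifted-normal imputation (width 0.3, downshift
1.8), s0-moderated t-test (s0 = 0.1) with permutation-based FDR 5%, and
Fisher-exact term enrichment of the hits.
"""

import numpy as np

import celldissect as cd
from celldissect.proteomics import ProteinMatrix

spec = cd.ProteomeFixtureSpec(seed=1)
matrix, groups, truth = cd.make_proteome_fixture(spec)
print(f"matrix: {matrix.shape[0]} proteins x {matrix.shape[1]} samples, "
      f"{matrix.isna().mean().mean():.1%} missing")

pm = cd.filter_matrix(ProteinMatrix(matrix, groups), max_missing_frac=0.30)
print(f"after 30% valid-value filter: {pm.values.shape[0]} proteins")
pm = cd.impute_downshift(pm, width=0.3, downshift=1.8, seed=1)

res = cd.permutation_fdr(pm, "s0_ttest", target_fdr=0.05, s0=0.1, seed=1)
sig = set(res.significant)
planted = set(truth["protein"]) & set(pm.values.index)
tp = len(sig & planted)
print(f"{len(sig)} significant at permutation FDR 5% "
      f"({res.n_permutations} label permutations)")
print(f"sensitivity {tp / len(planted):.2f}, "
      f"false discoveries {len(sig - planted)} of {len(sig)}")

# enrichment: a term containing only planted proteins vs. random terms
rng = np.random.default_rng(1)
bg = set(pm.values.index)
terms = {"planted_pathway": set(list(planted)[:40])}
for j in range(5):
    terms[f"random_term_{j}"] = set(rng.choice(sorted(bg), 40, replace=False))
for r in cd.fisher_enrichment(sig, bg, terms):
    print(f"{r.term:18s} p={r.p_value:9.2e} q={r.q_value:9.2e} "
          f"{'ENRICHED' if r.enriched else ''}")
# The planted pathway comes out with a vanishing q-value while random
# terms stay flat: the hits concentrate exactly where the effects were put.
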