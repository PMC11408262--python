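"""Generate a labelled synthetic cohort and test the profile effect.

Builds a small expression matrix with an ordered mean-expression effect
across the three personality profiles (creative > organized > unregulated),
quantile-normalizes it, selects the most variable genes, and runs the
bootstrap profile ANOVA.
"""

import personet as pn

cfg = pn.SynthConfig(
    n_subjects=120,
    profile_sizes={"creative": 33, "organized": 63, "unregulated": 24},
    n_genes=2000, n_responsive=500, n_biclusters=4,
    bicluster_genes=60, bicluster_subjects=40, rng_seed=7)
matrix, labels, truth = pn.gen_expression(cfg)
print(f"cohort: {matrix.shape[0]} subjects x {matrix.shape[1]} genes")

normalized = pn.quantile_normalize(matrix)
top = pn.select_variable_genes(normalized, 500)
overlap = len(set(top) & set(truth["responsive_genes"]))
print(f"variable-gene selection recovered {overlap}/500 responsive genes")

boot = pn.bootstrap_profile_anova(normalized.loc[:, top], labels,
                                  n_boot=30, seed=7)
print(f"bootstrap ANOVA mean F = {boot.mean_F:.1f} "
      f"(95% CI {boot.ci_low:.1f}-{boot.ci_high:.1f})")
for pair, r in boot.pairwise_r.items():
    print(f"  effect size r ({pair}) = {r:+.3f}")
print("negative r means the first-named profile expresses higher: the "
      "ordered planted effect (creative > organized > unregulated) shows as "
      "the creative-vs-unregulated contrast having the largest magnitude.")
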