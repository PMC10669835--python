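"""Diversity table, F-statistics, relatedness and AMOVA for the parental
populations, in the style of spreadsheet population-genetics reports."""

import crocdiag as cd

cfg = cd.SimConfig(n_loci=1200, missing_rate=0.02, seed=3)
m, _ = cd.simulate_parentals(cfg)

div = cd.diversity_table(m)
print("per-population diversity (Mean rows):")
print(div.summary.round(3).xs("Mean", level="stat"))
print("\nHe is expected heterozygosity 1 - sum p^2; F = (He - Ho)/He; "
      f"F undefined (monomorphic) at {div.n_f_undefined} loci per population.")

fs = cd.f_statistics(m, n_permutations=99, seed=3)
print(f"\noverall FST = {fs.fst_overall:.3f}")
print("pairwise FST:\n", fs.fst_pairwise.round(3))
print("permutation p:\n", fs.p_pairwise.round(3))

csi = list(m.samples.index[m.samples["population"] == "CSI"])
r, mean_r = cd.relatedness_qg(m, csi)
print(f"\nmean pairwise Queller–Goodnight relatedness within CSI: {mean_r:.3f} "
      "(centres near 0 under random mating)")

dist = cd.hamming_matrix(m)
pops = {p: list(g) for p, g in m.samples.groupby("population").groups.items()}
am = cd.amova_two_level(dist, pops, n_permutations=99, seed=3)
print(f"\nAMOVA: {am.pct_among:.1f}% of variance among populations, "
      f"{am.pct_within:.1f}% within (Phi = {am.phi:.3f}, p = {am.p:.3f})")
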