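"""The classical baseline: intra- vs inter-individual change testing.

Intra-individual changes (late minus early per subject) are compared
against an age-matched inter-individual background (subjects within 2
years of each other) per gene, with Benjamini-Hochberg FDR control.
"""

import threeca as t

matrix, truth = t.simulate_paired_expression(t.SimulationConfig(seed=19))
plan = t.build_pairing(matrix.meta, max_age_diff=2)
print(f"{len(plan.intra)} intra-individual pairs, "
      f"{len(plan.inter)} inter-individual background pairs (<= 2 years)")

res = t.intra_vs_inter_test(matrix, plan, test="wilcoxon_ranksum")
print(f"genes at p < 0.05: {(res['p'] < 0.05).sum()} of {len(res)}")
print(f"genes surviving FDR (q < 0.05): {(res['q'] < 0.05).sum()}")
planted = (truth["planted_set"] != "").to_numpy()
q_hits = (res["q"] < 0.05).to_numpy()
print(f"planted among FDR discoveries: {(q_hits & planted).sum()}")
print(f"null-gene rejection at p < 0.05: "
      f"{(res['p'].to_numpy()[~planted] < 0.05).mean():.3f}")
# At n = 10 pairs the baseline recovers under half of the 100 planted
# genes after FDR, and its null rejection exceeds the nominal 5%: the
# inter-individual background carries subject-level variance that the
# intra changes do not, so the two change sets differ in scale even for
# unchanged genes.  The vector scoring instead bounds that variance
# explicitly through the v component.
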