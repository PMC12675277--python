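"""qPCR relative expression with two reference genes and a group comparison.

Two genotypes with a true four-fold expression difference are simulated as
crossing points, converted to relative expression levels (delta-Ct with two
references) and compared with the Kruskal-Wallis rank test.
"""

from ckflux import compute_rel_table, group_compare, simulate_qpcr_plate

true_rel = {f"wt{i}": 1.0 for i in range(1, 7)} | {f"mut{i}": 4.0 for i in range(1, 7)}
genotypes = {k: ("wild type" if k.startswith("wt") else "mutant") for k in true_rel}
plate, truth = simulate_qpcr_plate(true_rel, noise_sd=0.3, seed=5, genotypes=genotypes)

rel = compute_rel_table(plate)
print(rel[["sample_id", "genotype", "cp_target", "rel"]].round(3).to_string(index=False))

groups = {g: sub["rel"].tolist() for g, sub in rel.groupby("genotype")}
cmp = group_compare(groups)
print(f"\nKruskal-Wallis H = {cmp.statistic:.3f}, P = {cmp.pvalue:.4f} ({cmp.significance})")
print()
print("REL ~ 1 for the wild type and ~4 for the mutant (0.3-cycle noise);")
print("the rank test flags the four-fold difference as significant.")
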