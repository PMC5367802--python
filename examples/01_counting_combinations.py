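"""How many genotype combinations can a study contain?

C(n, r) counts the ways to pick r of n SNPs; each picked SNP contributes one
of its three genotypes, hence the extra 3^r when combinations are built from
SNP genotypes rather than bare variants.
"""

from exclucomb import theoretical_combination_count

n, r = 803, 3
print(f"{n} SNPs, {r}-genotype combinations:",
      f"{theoretical_combination_count(n, r, genotyped=True):,}")
print("  (the number of cells a three-genotype scan of an 803-SNP panel classifies)")

n, r = 100, 10
print(f"{n} variants, {r}-variant combinations:",
      f"{theoretical_combination_count(n, r, genotyped=False):.3g}")
print("  (why exhaustive deep scans stop being feasible long before genome scale)")
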