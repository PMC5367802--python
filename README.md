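# exclucomb

Mining case/control SNP genotype matrices for **combinations of genotypes
that occur exclusively in patients**, clustering them, and testing
cluster–disorder association by label permutation.

In a genetically heterogeneous polygenic disorder, the variant combination
behind any one patient's disease may be shared by only a handful of other
patients — too few for any single combination to reach significance. This
package implements the complementary strategy: enumerate combinations of
SNP genotypes, keep those carried by at least one patient and by **no
control**, pool them into clusters sharing a defining feature (a common
anchor genotype, a low-p seed genotype, or a pathway annotation), and test
each cluster with a case/control label-permutation test, correcting across
clusters by Benjamini–Hochberg.

## The objects and the statistics

With `n` biallelic SNPs there are `C(n, r) · 3^r` possible combinations of
`r` SNP genotypes (each SNP contributes one of ref-hom / het / alt-hom). A
subject *carries* a combination when their genotype matches every one of
its atoms; missing genotypes never match. The scanner emits the
**subset-minimal patient-exclusive combinations**: exclusive combinations
none of whose proper sub-combinations is already exclusive — found
level-wise, removing exclusive combinations from the expansion frontier
because all their supersets would be patient-specific automatically.

A cluster's statistic is the number of patients carrying ≥ 1 member
combination. Its permutation p-value is the fraction of `B` random
relabelings (group sizes preserved, the scan and cluster rule re-derived
under pseudo-labels) in which as many or more pseudo-patients achieve the
same, `p = count_ge / B`.

## Worked example

From `examples/02_exclusive_scan.py` — four subjects, three SNPs:

```text
k=2  rs001:0+rs002:1    patients: P1, P2
k=2  rs001:0+rs003:0    patients: P2
k=2  rs002:1+rs003:2    patients: P1
```

No single genotype is patient-exclusive in this dataset, but three genotype
pairs are carried only by patients; each line names the pair and its
patient carriers. From `examples/04_cluster_permutation_test.py` — a
simulated 180-subject study with a planted anchored cluster:

```text
cluster members: 10, patient carriers: 39 (controls: 0)
observed statistic: 39 patients; permutation p = 0/500 = 0.0
```

39 of 60 patients — and zero controls — carry a combination from the
anchor-defined cluster; no shuffled labeling among 500 matched that, so the
permutation p is below 1/500.

The other examples cover the combination-count arithmetic
(`01_counting_combinations.py`), the exhaustive shared / patient-only /
control-only accounting with the multiplicity histogram
(`03_partition_accounting.py`), and end-to-end recovery of planted signal
(`05_simulate_and_recover.py`).

A thin CLI wraps the same library calls:

```sh
exclucomb simulate --n-patients 60 --n-controls 120 --n-snps 40 \
    --plant 0:1,2,8,4 --seed 21 --out run/
exclucomb scan --genotypes run/genotypes.tsv --max-k 2 --min-support 3 --out run/
exclucomb permtest --genotypes run/genotypes.tsv --anchor 0:1 -B 500 --out run/
```

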