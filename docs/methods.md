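# Methods

## The problem and the model

In a genetically heterogeneous polygenic disorder no single variant — and
possibly no single *combination* of variants — is shared by enough patients
to reach significance on its own. The strategy implemented here attacks the
problem from the exclusivity side: enumerate combinations of SNP genotypes
(one of the three diploid genotypes at each of several biallelic SNPs),
separate those carried by at least one patient and by no control from those
shared with controls, pool patient-exclusive combinations into clusters that
share a defining feature, and ask by permutation whether the number of
patients covered by a cluster could arise when case/control labels carry no
information.

A *genotype atom* is a pair (SNP, genotype code) with codes 0 (reference
homozygote), 1 (heterozygote), 2 (alternate homozygote); missing genotypes
(code −1) never match any atom, so a subject with missing data at a SNP is
conservatively a non-carrier of every atom there. A *combination* is a set
of atoms on distinct SNPs; its carrier set is the intersection of the atom
carrier sets. With `n` SNPs there are `C(n, r) · 3^r` possible r-atom
combinations (`theoretical_combination_count`; exact integer arithmetic).

## The exclusive scan

`exclusive_scan` emits exactly the **subset-minimal** patient-exclusive
combinations up to a configured size `max_k`: exclusive combinations whose
every proper sub-combination is carried by at least one control (or by
nobody). Minimality is the right reporting unit because every superset of an
exclusive combination is automatically exclusive and carried by a subset of
the same patients.

The search is level-wise. Level 1 classifies single atoms; exclusive atoms
are emitted and removed, atoms carried by at least one patient *and* one
control form the expansion frontier, and control-only or carrier-less atoms
are dropped (carrier sets shrink under superset, so none of their supersets
can be patient-exclusive — a pruning that provably preserves the output).
Level k+1 joins frontier members sharing all but their last atom
(sorted-prefix join; one atom per SNP). Carrier counts for all candidate
pairs of a join group are obtained at once as two integer matrix products
(`M_patients · M_patientsᵀ` and the control analogue of the group's boolean
carrier matrix), which is what makes desk-scale scans (hundreds of SNPs,
hundreds of subjects) run in fractions of a second.

Instead of the classical check that every k-subset of a candidate survived
the previous level, minimality is verified at emission time against the set
of already-emitted exclusives. The two realisations emit the same set: any
exclusive proper subset of a candidate either is minimal (hence emitted) or
contains a minimal exclusive that was. In the guided variant this shortcut
is not available — subsets without a seed atom are never evaluated — so
there exclusivity of subsets is checked directly by memoized mask
intersection.

`guided_scan` implements the low-p pairing heuristic for datasets too wide
to scan exhaustively: from level 2 on, a candidate is evaluated only if it
contains at least one atom whose single-atom association p-value is below
`seed_alpha`. Its output is the subset of the minimal exclusives that
contain a seed atom; with `seed_alpha = 1` it equals the full scan.

`partition_scan` is the exhaustive accounting at one size `r`: every
combination with a carrier is classified shared / patient-only /
control-only and patient-only combinations are tabulated by the number of
carrying patients (the multiplicity distribution, with its `tail(m)`
summary). It refuses, naming the theoretical count, when that count exceeds
a budget (default 10⁸) rather than run away; `iter_partition_combinations`
streams without a budget.

Reported combinations are filtered to `min_patient_support` carrying
patients (default 1, i.e. report everything; the bipolar material used 9).
The full emitted list is retained internally so support filtering never
distorts minimality.

## Clusters and the permutation test

A cluster is a *filter* over the scanned exclusive combinations — anchor
atom contained in every member, member contains a low-p atom, or member
contains an atom annotated (SNP → gene → pathway) to a given pathway. A
patient belongs to a cluster when they carry at least one member; the
per-patient member count (accumulation) is reported alongside. Clusters may
overlap; nothing enforces disjointness.

The permutation test shuffles case/control labels preserving group sizes
and compares the observed number of patients carrying qualifying
combinations with the permutation distribution of the same statistic;
`p = count_ge / B` (so the 50-of-1000 boundary is exactly p = 0.05; the
add-one convention is available as an option, and p = 0 is possible and
should be read as "< 1/B"). Two nulls are implemented and named:

* **rederive** (default): each permutation re-runs the exclusive scan and
  the cluster rule under the pseudo-labels, including the support threshold,
  so the null recreates combinations exclusive to and common among
  pseudo-patients from scratch. Cost is B full scans; the test refuses when
  `B ×` (candidate count) exceeds a budget and suggests the alternative.
* **fixed**: the observed member list is frozen; a member qualifies in a
  permutation when absent from every pseudo-control. A cheap approximation
  for cohort sizes where re-scanning B times is infeasible.

For cohorts of ≤ a few thousand distinct labelings the exact permutation
distribution can be enumerated (`exhaustive=True`); the sampled p converges
to the exact fraction within Monte-Carlo error.

When several clusters are tested in one run their p-values are adjusted by
Benjamini–Hochberg step-up (delegated to statsmodels); the family is the
set of rules tested in that run, not the study history.

## The synthetic generator

The generator emulates the *shape* of a case/control SNP panel, not real
genetics: per-SNP minor-allele frequency uniform on `maf_range` (default
0.1–0.5, common panel variants), genotypes independent across subjects and
SNPs under Hardy–Weinberg proportions, labels independent of genotypes.
Defaults (200 patients, 400 controls, 100 SNPs) keep the 1:2 case/control
ratio of the 607/1354 bipolar material at desk scale. There is no linkage
disequilibrium, no population structure, and planted combinations are 100%
penetrant and fully exclusive — so passing recovery tests demonstrates the
scanner's correctness and power under the planted model, not performance on
real cohorts.

Planting overwrites the genotypes of chosen patients so they carry every
atom of their member combination (members share one anchor atom, mirroring
the published 16-member, 73-patient anchored cluster structure), then
repairs controls that accidentally carry a member by flipping one member
atom to a different code (minimal perturbation, keeping allele frequencies
near target; repaired cells are recorded in the truth). Exclusivity of
every member is re-verified on the emitted matrix as a hard postcondition.
Forced carriers of different members may overlap; conflicting pins (two
members demanding different codes at one SNP of one patient) are resolved
by resampling assignments before any genotype is written. Planting can make
a proper sub-combination of a member exclusive by accident; such *shadowed*
members are flagged in the truth rather than prevented, because a
minimality-respecting scanner reports the sub-combination instead — hiding
that would fake perfect recovery.

## Numerical and design choices

* Carrier sets are boolean subject masks; per-label counts come from
  float32 matrix products (exact for counts below 2²⁴).
* Combinations are canonically ordered by (SNP index, code) and rendered as
  `snp:code+snp:code+…`; scan output order is lexicographic, making runs
  byte-stable.
* Exclusivity is `n_patients ≥ 1 and n_controls = 0`; zero-carrier
  combinations are never emitted and are dropped from every frontier.
* Degenerate association tables (a zero margin) return statistic 0, p 1,
  flagged degenerate rather than raising.
* Budgets guard every enumeration (`partition_scan` theoretical count,
  `ScanConfig.max_candidates` for the level-wise join, the rederive
  permutation budget, the exhaustive-labeling cap); refusals are errors that
  name the offending count, never silent truncation.
* Acceptance-scale problem sizes — 100 random ≤8-SNP datasets for
  brute-force agreement, 50 planted studies of 600 subjects × 100 SNPs,
  200 null calibration studies of 50 subjects × 16 SNPs at B = 200 — were
  chosen as the smallest sizes at which the checked properties are
  statistically meaningful while a full run stays in the minutes range.

## Known limitations

* The published genome-wide example counts for n = 500,000 (≈2.3 × 10¹²
  two-variant, ≈3.4 × 10¹⁸ three-variant combinations) do not follow from
  the `C(n, r) · 3^r` formula (which gives ≈1.12 × 10¹² and ≈5.6 × 10¹⁷);
  they match `(3n)^r` without the `r!` division. The implementation follows
  the stated formula; the discrepancy is documented, not reconciled.
* The level-wise scan materialises the expansion frontier per level; very
  wide datasets (beyond ~10³–10⁴ SNPs) need the guided variant or a higher
  support threshold. Genome-wide scale is out of scope.
* The fixed permutation variant understates the null richness of the
  rederived scan (frozen members can only lose qualification); it is
  labelled an approximation and is not the default.
* The original cohort genotypes were never deposited, so the published
  cohort-level findings (e.g. 209/607 cluster carriers) are replicated
  structurally via simulation only; no claim about real cohorts is tested.
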