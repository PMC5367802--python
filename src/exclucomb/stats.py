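"""Association statistics: single-atom tests, permutation tests, FDR correction.

Single genotype atoms are tested on the 2x2 carrier/non-carrier by
patient/control table (Pearson chi-square without continuity correction, or
the equivalent two-proportion z).  Clusters of patient-exclusive combinations
are assessed with a label-permutation test: patient/control labels are
re-assigned at random (group sizes preserved), the cluster construction is
re-derived under the pseudo-labels, and the observed number of patients
carrying cluster combinations is compared with the permutation distribution
of the same statistic.  Families of cluster p-values are corrected with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    BudgetError,
    GenotypeAtom,
    GenotypeDataset,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .clusters import ClusterRule
    from .scan import ScanConfig

__all__ = [
    "TestResult",
    "PermutationResult",
    "atom_association_test",
    "atom_pvalue_matrix",
    "cluster_permutation_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single-atom association test."""

    statistic: float
    df: int
    p: float
    method: str
    degenerate: bool = False


def _two_by_two(ds: GenotypeDataset, atom: GenotypeAtom) -> tuple[int, int, int, int]:
    mask = ds.atom_mask(atom)
    a = int(np.count_nonzero(mask & ds.is_patient))  # patient carriers
    b = ds.n_patients - a
    c = int(np.count_nonzero(mask)) - a  # control carriers
    d = ds.n_controls - c
    return a, b, c, d


def atom_association_test(
    ds: GenotypeDataset, atom: GenotypeAtom, method: str = "chi-square"
) -> TestResult:
    """Test carrier frequency of one genotype atom between patients and controls.

    The table is carrier/non-carrier x patient/control.  ``chi-square`` is the
    1-df Pearson statistic without continuity correction; ``z`` is the pooled
    two-proportion statistic, signed positive when patients carry more often,
    with z**2 equal to the chi-square statistic.  A degenerate margin (all
    subjects carriers, none, or a missing label group) yields statistic 0 and
    p 1 with the ``degenerate`` flag set.
    """
    if method not in ("chi-square", "z"):
        raise ValidationError(f"unknown test method {method!r}")
    a, b, c, d = _two_by_two(ds, atom)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return TestResult(0.0, 1, 1.0, method, degenerate=True)
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    if method == "chi-square":
        return TestResult(float(chi2), 1, float(sps.chi2.sf(chi2, 1)), method)
    z = math.copysign(math.sqrt(chi2), a / r1 - c / r2)
    return TestResult(float(z), 1, float(2 * sps.norm.sf(abs(z))), method)


def atom_pvalue_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Chi-square p-values for all atoms at once, shape (n_snps, 3).

    Vectorised version of :func:`atom_association_test`; degenerate atoms
    (no carriers, all carriers, or degenerate labels) get p = 1.
    """
    if ds.degenerate_labels:
        return np.ones((ds.n_snps, 3))
    pvals = np.ones((ds.n_snps, 3))
    is_p = ds.is_patient
    n_pat, n_ctrl = ds.n_patients, ds.n_controls
    n = n_pat + n_ctrl
    for code in (0, 1, 2):
        carrier = ds.genotypes == code  # (n_sub, n_snps)
        a = carrier[is_p].sum(axis=0).astype(np.float64)
        c = carrier.sum(axis=0) - a
        c1 = a + c
        ok = (c1 > 0) & (c1 < n)
        b = n_pat - a
        d = n_ctrl - c
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = n * (a * d - b * c) ** 2 / (n_pat * n_ctrl * c1 * (n - c1))
        p = np.ones(ds.n_snps)
        p[ok] = sps.chi2.sf(chi2[ok], 1)
        pvals[:, code] = p
    return pvals


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a cluster label-permutation test.

    ``observed`` is the number of patients carrying at least one qualifying
    combination under the true labels; ``count_ge`` the number of label
    permutations whose statistic reached or exceeded it; ``p = count_ge / B``
    (``(count_ge + 1) / (B + 1)`` when the add-one convention is requested).
    ``exact`` marks exhaustive enumeration of all labelings instead of
    sampling.
    """

    observed: int
    B: int
    count_ge: int
    p: float
    seed: int | None
    variant: str
    exact: bool = False
    null_stats: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.count_ge <= self.B:
            raise ValidationError("count_ge must lie in [0, B]")


def cluster_permutation_test(
    ds: GenotypeDataset,
    rule: "ClusterRule",
    config: "ScanConfig",
    B: int = 1000,
    seed: int | None = None,
    variant: str = "rederive",
    *,
    exhaustive: bool = False,
    plus_one: bool = False,
    keep_null: bool = False,
    rederive_budget: int = 200_000_000,
    max_exhaustive: int = 500_000,
) -> PermutationResult:
    """Permutation test of a cluster construction rule.

    The statistic is the number of (pseudo-)patients carrying at least one
    qualifying combination.  Under ``variant="rederive"`` (default) each
    permutation re-runs the exclusive scan and the cluster rule on the
    pseudo-labels, so the null recreates pseudo-patient-exclusive
    combinations from scratch; under ``variant="fixed"`` the observed member
    list is frozen and a member qualifies in a permutation when it is absent
    from every pseudo-control — a cheap approximation for datasets where
    re-scanning B times is infeasible.  ``exhaustive=True`` enumerates every
    distinct case/control labeling instead of sampling (small cohorts only)
    and ignores ``B`` and ``seed``.
    """
    from .clusters import build_cluster
    from .scan import exclusive_scan

    if B < 1:
        raise ValidationError("B must be >= 1")
    if variant not in ("rederive", "fixed"):
        raise ValidationError(f"unknown permutation variant {variant!r}")
    if ds.degenerate_labels:
        raise ValidationError("permutation test needs both patients and controls")

    scan = exclusive_scan(ds, config)
    cluster = build_cluster(rule, scan, ds)
    member_masks = np.array(
        [ds.combination_mask(c) for c in cluster.members], dtype=bool
    ).reshape(len(cluster.members), ds.n_subjects)
    observed = _n_label_carriers(member_masks, ds.is_patient)

    def statistic(pseudo_is_patient: np.ndarray) -> int:
        if variant == "fixed":
            return _fixed_statistic(member_masks, pseudo_is_patient)
        pds = ds.with_labels(pseudo_is_patient)
        pscan = exclusive_scan(pds, config)
        pcluster = build_cluster(rule, pscan, pds)
        if not pcluster.members:
            return 0
        pm = np.array([pds.combination_mask(c) for c in pcluster.members])
        return _n_label_carriers(pm, pseudo_is_patient)

    n = ds.n_subjects
    if exhaustive:
        n_labelings = math.comb(n, ds.n_patients)
        if n_labelings > max_exhaustive:
            raise BudgetError(
                f"{n_labelings:,} labelings exceed the exhaustive budget "
                f"({max_exhaustive:,}); sample with exhaustive=False"
            )
        count_ge = 0
        null: list[int] = []
        for pat_set in itertools.combinations(range(n), ds.n_patients):
            lab = np.zeros(n, dtype=bool)
            lab[list(pat_set)] = True
            s = statistic(lab)
            null.append(s)
            count_ge += s >= observed
        B_eff = n_labelings
    else:
        if variant == "rederive" and B * scan.n_candidates > rederive_budget:
            raise BudgetError(
                f"rederiving {B} scans of ~{scan.n_candidates:,} candidates "
                "exceeds the permutation budget; lower max_k or B, or use "
                'variant="fixed"'
            )
        rng = np.random.default_rng(seed)
        base = np.zeros(n, dtype=bool)
        base[: ds.n_patients] = True
        count_ge = 0
        null = []
        for _ in range(B):
            lab = rng.permutation(base)
            s = statistic(lab)
            null.append(s)
            count_ge += s >= observed
        B_eff = B
    p = (count_ge + 1) / (B_eff + 1) if plus_one else count_ge / B_eff
    return PermutationResult(
        observed=observed,
        B=B_eff,
        count_ge=count_ge,
        p=float(p),
        seed=None if exhaustive else seed,
        variant=variant,
        exact=exhaustive,
        null_stats=tuple(null) if keep_null else None,
    )


def _n_label_carriers(member_masks: np.ndarray, is_patient: np.ndarray) -> int:
    """Number of patients carrying at least one member."""
    if member_masks.size == 0:
        return 0
    return int(np.count_nonzero(member_masks.any(axis=0) & is_patient))


def _fixed_statistic(member_masks: np.ndarray, pseudo_is_patient: np.ndarray) -> int:
    """Pseudo-patients carrying >=1 member absent from all pseudo-controls."""
    if member_masks.size == 0:
        return 0
    in_control = (member_masks & ~pseudo_is_patient).any(axis=1)
    qualifying = member_masks[~in_control]
    if qualifying.size == 0:
        return 0
    return int(np.count_nonzero(qualifying.any(axis=0) & pseudo_is_patient))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the ascending order
    statistics; adjusted values are never below the raw ones and are monotone
    when sorted by raw p.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(arr, method="fdr_bh")[1]
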