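"""Combination enumeration: analytic counts, partition accounting, exclusive scan.

The central object of study is a *combination* of SNP genotypes (atoms on
distinct SNPs) and its *carrier set*.  With ``n`` SNPs there are
``C(n, r) * 3**r`` possible r-atom combinations, so enumeration is organised
two ways:

* :func:`partition_scan` — exhaustive accounting at a fixed size ``r``: every
  combination with at least one carrier is classified as shared,
  patient-only, or control-only, and patient-only combinations are tabulated
  by how many patients share them.
* :func:`exclusive_scan` — a level-wise (apriori-style) search for the
  *subset-minimal* patient-exclusive combinations: sizes 1, 2, 3, ... are
  scanned successively, exclusive combinations are emitted and removed from
  the expansion frontier (all their supersets would be patient-exclusive
  automatically), and only combinations carried by at least one patient and
  one control are expanded further.  Carrier counts for all candidate pairs
  of a join group are obtained at once from two integer matrix products.

:func:`guided_scan` is the same search restricted to candidates containing at
least one atom whose single-atom association p-value is below a seed cutoff —
the classical low-p pairing heuristic for very wide datasets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np

from .core import (
    BudgetError,
    CarrierSet,
    Combination,
    GenotypeAtom,
    GenotypeDataset,
    ValidationError,
)

__all__ = [
    "ScanConfig",
    "PartitionCounts",
    "MultiplicityDistribution",
    "ExclusiveScanResult",
    "theoretical_combination_count",
    "atom_carriers",
    "combination_carriers",
    "partition_scan",
    "iter_partition_combinations",
    "exclusive_scan",
    "guided_scan",
    "multiplicity_distribution",
]


def theoretical_combination_count(n: int, r: int, genotyped: bool = True) -> int:
    """Number of possible r-variant combinations among n variants.

    ``C(n, r)`` counts the ways to choose ``r`` distinct variants; when the
    variants are SNP genotypes each chosen SNP contributes one of its three
    genotypes, multiplying the count by ``3**r``.  Exact integer arithmetic.
    """
    if n < 0 or r < 0:
        raise ValidationError(f"n and r must be non-negative, got n={n}, r={r}")
    count = math.comb(n, r)
    return count * 3**r if genotyped else count


def atom_carriers(ds: GenotypeDataset, atom: GenotypeAtom) -> CarrierSet:
    """Subjects whose genotype at the atom's SNP equals the atom's code."""
    return CarrierSet.from_mask(ds.atom_mask(atom), ds.is_patient)


def combination_carriers(ds: GenotypeDataset, combo: Combination) -> CarrierSet:
    """Intersection of the atom carrier sets (every atom must match)."""
    return CarrierSet.from_mask(ds.combination_mask(combo), ds.is_patient)


# ---------------------------------------------------------------------------
# Multiplicity accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiplicityDistribution:
    """Histogram of patient-only combinations by number of carrying patients."""

    histogram: Mapping[int, int]

    @property
    def total(self) -> int:
        """Total number of combinations tabulated (sum of histogram rows)."""
        return sum(self.histogram.values())

    def tail(self, m: int) -> int:
        """Number of combinations common among ``>= m`` patients."""
        return sum(v for k, v in self.histogram.items() if k >= m)

    @classmethod
    def from_carriers(
        cls, carriers: Iterable[CarrierSet | tuple[Combination, CarrierSet]]
    ) -> "MultiplicityDistribution":
        hist: dict[int, int] = {}
        for item in carriers:
            cs = item[1] if isinstance(item, tuple) else item
            hist[cs.n_patients] = hist.get(cs.n_patients, 0) + 1
        return cls(hist)


def multiplicity_distribution(
    combos: Iterable[CarrierSet | tuple[Combination, CarrierSet]],
) -> MultiplicityDistribution:
    """Tabulate combinations by the number of patients carrying each."""
    return MultiplicityDistribution.from_carriers(combos)


# ---------------------------------------------------------------------------
# Partition scan (exhaustive accounting at fixed r)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartitionCounts:
    """Full accounting of all r-atom combinations with at least one carrier."""

    r: int
    theoretical: int
    found: int
    shared: int
    patient_only: int
    control_only: int
    patient_multiplicity: Mapping[int, int]

    def __post_init__(self) -> None:
        if self.found != self.shared + self.patient_only + self.control_only:
            raise ValidationError("partition counts do not sum to found")
        if sum(self.patient_multiplicity.values()) != self.patient_only:
            raise ValidationError("multiplicity histogram does not sum to patient_only")
        if self.found > self.theoretical:
            raise ValidationError("found exceeds the theoretical count")

    @property
    def multiplicity(self) -> MultiplicityDistribution:
        return MultiplicityDistribution(self.patient_multiplicity)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "theoretical": self.theoretical,
            "found": self.found,
            "shared": self.shared,
            "patient_only": self.patient_only,
            "control_only": self.control_only,
            "patient_multiplicity": {
                str(k): v for k, v in sorted(self.patient_multiplicity.items())
            },
        }


def partition_scan(
    ds: GenotypeDataset, r: int, *, budget: int | None = 10**8
) -> PartitionCounts:
    """Classify every r-combination with >=1 carrier as shared / patient-only /
    control-only and tabulate patient-only combinations by patient count.

    Runs in ``C(n_snps, r)`` passes of two bincounts over the subjects; when
    the theoretical combination count exceeds *budget* the scan refuses with
    the count in the message rather than run away (pass ``budget=None`` or use
    :func:`iter_partition_combinations` to stream regardless).
    """
    if r < 1:
        raise ValidationError(f"combination size r must be >= 1, got {r}")
    theoretical = theoretical_combination_count(ds.n_snps, r, genotyped=True)
    if budget is not None and theoretical > budget:
        raise BudgetError(
            f"partition scan at r={r} spans {theoretical:,} theoretical "
            f"combinations, above the budget of {budget:,}; raise the budget "
            "or stream with iter_partition_combinations"
        )
    G = ds.genotypes.astype(np.int64)
    is_p = ds.is_patient
    pows = 3 ** np.arange(r, dtype=np.int64)
    n_cells = 3**r
    found = shared = patient_only = control_only = 0
    hist = np.zeros(ds.n_patients + 1, dtype=np.int64)
    for snp_combo in itertools.combinations(range(ds.n_snps), r):
        cols = G[:, list(snp_combo)]
        valid = (cols >= 0).all(axis=1)
        idx = cols @ pows
        pat = np.bincount(idx[valid & is_p], minlength=n_cells)
        ctrl = np.bincount(idx[valid & ~is_p], minlength=n_cells)
        tot = pat + ctrl
        found += int((tot > 0).sum())
        shared += int(((pat > 0) & (ctrl > 0)).sum())
        p_only = (pat > 0) & (ctrl == 0)
        patient_only += int(p_only.sum())
        control_only += int(((pat == 0) & (ctrl > 0)).sum())
        if p_only.any():
            hist += np.bincount(pat[p_only], minlength=hist.size)[: hist.size]
    return PartitionCounts(
        r=r,
        theoretical=theoretical,
        found=found,
        shared=shared,
        patient_only=patient_only,
        control_only=control_only,
        patient_multiplicity={
            int(k): int(v) for k, v in enumerate(hist) if v > 0
        },
    )


def iter_partition_combinations(
    ds: GenotypeDataset, r: int
) -> Iterator[tuple[Combination, CarrierSet, str]]:
    """Stream every r-combination with >=1 carrier and its class.

    Yields ``(combination, carriers, category)`` with category one of
    ``"shared"``, ``"patient_only"``, ``"control_only"``, in lexicographic
    order of (snp_index, code) tuples.  No budget applies: the caller
    controls consumption.
    """
    for snp_combo in itertools.combinations(range(ds.n_snps), r):
        for codes in itertools.product((0, 1, 2), repeat=r):
            combo = Combination(
                tuple(GenotypeAtom(s, c) for s, c in zip(snp_combo, codes))
            )
            cs = combination_carriers(ds, combo)
            if len(cs) == 0:
                continue
            if cs.n_patients > 0 and cs.n_controls > 0:
                category = "shared"
            elif cs.n_patients > 0:
                category = "patient_only"
            else:
                category = "control_only"
            yield combo, cs, category


# ---------------------------------------------------------------------------
# Exclusive scan (level-wise minimal patient-exclusive search)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the level-wise exclusive scan.

    max_k
        Largest combination size scanned.
    min_patient_support
        Minimum number of carrying patients for a combination to be
        *reported* (the full emitted list is retained internally, so
        minimality semantics are unaffected).  The bipolar study used 9;
        the default 1 reports everything.
    mode
        Informational tag used by run configurations
        (``partition | exclusive | guided``).
    max_candidates
        Budget on the total number of candidate combinations evaluated;
        exceeding it raises :class:`BudgetError`.
    """

    max_k: int = 3
    min_patient_support: int = 1
    mode: str = "exclusive"
    max_candidates: int = 20_000_000

    def __post_init__(self) -> None:
        if self.max_k < 1:
            raise ValidationError("max_k must be >= 1")
        if self.min_patient_support < 1:
            raise ValidationError("min_patient_support must be >= 1")


class ExclusiveScanResult:
    """Outcome of :func:`exclusive_scan` / :func:`guided_scan`.

    Attributes
    ----------
    levels : dict[int, list[(Combination, CarrierSet)]]
        Reported minimal patient-exclusive combinations per size, filtered to
        ``n_patients >= min_patient_support``, in lexicographic order.
    frontier_sizes : dict[int, int]
        Number of non-exclusive combinations carried forward from each level.
    n_candidates : int
        Total candidates whose carrier counts were evaluated.
    """

    def __init__(
        self,
        snp_ids: Sequence[str],
        levels: dict[int, list[tuple[Combination, CarrierSet]]],
        frontier_sizes: dict[int, int],
        all_atom_ids: dict[int, list[tuple[tuple[int, ...], int]]],
        min_patient_support: int,
        n_candidates: int,
    ) -> None:
        self.snp_ids = list(snp_ids)
        self.levels = levels
        self.frontier_sizes = frontier_sizes
        self.min_patient_support = min_patient_support
        self.n_candidates = n_candidates
        self._all_atom_ids = all_atom_ids  # full emitted list, (atom-id tuple, n_pat)

    def combinations(self) -> Iterator[tuple[int, Combination, CarrierSet]]:
        """Iterate reported combinations as (level, combination, carriers)."""
        for k in sorted(self.levels):
            for combo, cs in self.levels[k]:
                yield k, combo, cs

    def n_reported(self) -> int:
        return sum(len(v) for v in self.levels.values())

    def all_exclusive(self) -> dict[int, list[Combination]]:
        """Full emitted minimal-exclusive list per level (no support filter)."""
        return {
            k: [_combo_from_ids(ids) for ids, _ in v]
            for k, v in self._all_atom_ids.items()
        }

    def all_exclusive_counts(self) -> dict[int, list[int]]:
        """Patient counts matching :meth:`all_exclusive`."""
        return {k: [n for _, n in v] for k, v in self._all_atom_ids.items()}

    def n_exclusive_total(self) -> int:
        return sum(len(v) for v in self._all_atom_ids.values())


def _combo_from_ids(ids: tuple[int, ...]) -> Combination:
    return Combination(tuple(GenotypeAtom(i // 3, i % 3) for i in ids))


def exclusive_scan(ds: GenotypeDataset, config: ScanConfig) -> ExclusiveScanResult:
    """Find all subset-minimal patient-exclusive combinations up to max_k.

    Level 1 scans single atoms: those carried by at least one patient and no
    control are emitted; atoms carried by both a patient and a control form
    the expansion frontier (control-only and carrier-less atoms are dropped —
    no superset of theirs can be patient-exclusive).  Each further level
    joins frontier members sharing all but their last atom, evaluates the
    joined candidates' per-label carrier counts, emits the patient-exclusive
    ones that contain no previously emitted combination, and carries the
    shared ones forward.  Emitted combinations never re-enter the frontier:
    their supersets would be patient specific automatically.
    """
    return _levelwise_scan(ds, config, seed_atoms=None)


def guided_scan(
    ds: GenotypeDataset, seed_alpha: float, config: ScanConfig
) -> ExclusiveScanResult:
    """Exclusive scan restricted to combinations containing a low-p seed atom.

    Single-atom association p-values (carrier vs non-carrier chi-square) are
    computed first; from level 2 on, a candidate is evaluated only if it
    contains at least one atom with p <= seed_alpha.  The output is always a
    subset of :func:`exclusive_scan`'s output; with ``seed_alpha = 1`` the two
    are identical.
    """
    if not 0 < seed_alpha <= 1:
        raise ValidationError(f"seed_alpha must be in (0, 1], got {seed_alpha}")
    from .stats import atom_pvalue_matrix

    pvals = atom_pvalue_matrix(ds)  # (n_snps, 3)
    seed_atoms = (pvals <= seed_alpha).ravel()  # indexed by atom id = 3*snp + code
    return _levelwise_scan(ds, config, seed_atoms=seed_atoms)


def _levelwise_scan(
    ds: GenotypeDataset,
    config: ScanConfig,
    seed_atoms: np.ndarray | None,
) -> ExclusiveScanResult:
    is_p = ds.is_patient
    n_snps = ds.n_snps
    n_atoms = 3 * n_snps

    # atom id a = 3*snp + code; masks (n_atoms, n_subjects)
    atom_masks = np.zeros((n_atoms, ds.n_subjects), dtype=bool)
    for code in (0, 1, 2):
        atom_masks[code::3] = (ds.genotypes.T == code)[np.arange(n_snps)]
    pat_counts = atom_masks[:, is_p].sum(axis=1)
    tot_counts = atom_masks.sum(axis=1)
    ctrl_counts = tot_counts - pat_counts

    emitted_all: set[tuple[int, ...]] = set()

    # In exclusive mode every exclusive subset of a candidate is necessarily
    # already emitted, so minimality is a membership test in emitted_all.  In
    # guided mode subsets without a seed atom are never evaluated, so
    # exclusivity of subsets is checked directly (memoized mask intersection).
    excl_memo: dict[tuple[int, ...], bool] = {}

    def _subset_is_exclusive(ids: tuple[int, ...]) -> bool:
        cached = excl_memo.get(ids)
        if cached is not None:
            return cached
        mask = atom_masks[ids[0]].copy()
        for a in ids[1:]:
            mask &= atom_masks[a]
        n_pat = int(np.count_nonzero(mask[is_p]))
        result = n_pat >= 1 and int(np.count_nonzero(mask)) == n_pat
        excl_memo[ids] = result
        return result

    def _non_minimal(ids: tuple[int, ...]) -> bool:
        if _contains_emitted(ids, emitted_all):
            return True
        if seed_atoms is None:
            return False
        return any(
            _subset_is_exclusive(sub)
            for j in range(1, len(ids))
            for sub in itertools.combinations(ids, j)
        )

    all_ids: dict[int, list[tuple[tuple[int, ...], int]]] = {}
    levels: dict[int, list[tuple[Combination, CarrierSet]]] = {}
    frontier_sizes: dict[int, int] = {}
    n_candidates = n_atoms

    # ---- level 1 -----------------------------------------------------------
    excl1 = np.flatnonzero((ctrl_counts == 0) & (pat_counts >= 1))
    all_ids[1] = [((int(a),), int(pat_counts[a])) for a in excl1]
    emitted_all.update(ids for ids, _ in all_ids[1])
    levels[1] = [
        (_combo_from_ids(ids), CarrierSet.from_mask(atom_masks[ids[0]], is_p))
        for ids, n in all_ids[1]
        if n >= config.min_patient_support
    ]
    front_idx = np.flatnonzero((ctrl_counts >= 1) & (pat_counts >= 1))
    combos = front_idx[:, None].astype(np.int32)  # (m, 1)
    masks = atom_masks[front_idx]
    frontier_sizes[1] = len(front_idx)

    # ---- levels 2..max_k ---------------------------------------------------
    for k in range(2, config.max_k + 1):
        if combos.shape[0] < 2:
            all_ids[k] = []
            levels[k] = []
            frontier_sizes[k] = 0
            combos = np.empty((0, k), dtype=np.int32)
            masks = np.empty((0, ds.n_subjects), dtype=bool)
            continue
        # frontier is lexicographically sorted by construction; group rows
        # sharing the (k-2)-atom prefix
        if k == 2:
            boundaries = np.array([0, combos.shape[0]])
        else:
            change = np.any(combos[1:, :-1] != combos[:-1, :-1], axis=1)
            starts = np.concatenate(([0], np.flatnonzero(change) + 1))
            boundaries = np.concatenate((starts, [combos.shape[0]]))
        n_pairs = 0
        for gi in range(len(boundaries) - 1):
            g = boundaries[gi + 1] - boundaries[gi]
            n_pairs += g * (g - 1) // 2
        n_candidates += n_pairs
        if n_candidates > config.max_candidates:
            raise BudgetError(
                f"level {k} would evaluate {n_pairs:,} candidates "
                f"(budget {config.max_candidates:,}); lower max_k or raise "
                "max_candidates"
            )
        if seed_atoms is not None:
            row_seed = seed_atoms[combos].any(axis=1)

        new_ids: list[tuple[int, ...]] = []
        new_pat: list[int] = []
        keep_masks: list[np.ndarray] = []
        next_combos: list[np.ndarray] = []
        next_masks: list[np.ndarray] = []
        for gi in range(len(boundaries) - 1):
            lo, hi = int(boundaries[gi]), int(boundaries[gi + 1])
            g = hi - lo
            if g < 2:
                continue
            M = masks[lo:hi]
            Mp = M[:, is_p].astype(np.float32)
            Mc = M[:, ~is_p].astype(np.float32)
            P = Mp @ Mp.T
            C = Mc @ Mc.T
            last = combos[lo:hi, -1]
            snp_last = last // 3
            ii, jj = np.triu_indices(g, 1)
            ok = snp_last[ii] != snp_last[jj]
            if seed_atoms is not None:
                ok &= row_seed[lo:hi][ii] | seed_atoms[last[jj]]
            pc = P[ii, jj].astype(np.int64)
            cc = C[ii, jj].astype(np.int64)
            excl = ok & (cc == 0) & (pc >= 1)
            surv = ok & (cc >= 1) & (pc >= 1)
            if excl.any():
                ei, ej = ii[excl], jj[excl]
                prefix = combos[lo:hi]
                for a, b, np_ in zip(ei, ej, pc[excl]):
                    ids = (*map(int, prefix[a]), int(last[b]))
                    if _non_minimal(ids):
                        continue
                    new_ids.append(ids)
                    new_pat.append(int(np_))
                    keep_masks.append(M[a] & M[b])
            if surv.any() and k < config.max_k:
                si, sj = ii[surv], jj[surv]
                next_combos.append(
                    np.column_stack((combos[lo:hi][si], last[sj]))
                )
                next_masks.append(M[si] & M[sj])

        all_ids[k] = list(zip(new_ids, new_pat))
        emitted_all.update(new_ids)
        levels[k] = [
            (
                _combo_from_ids(ids),
                CarrierSet.from_mask(mask, is_p),
            )
            for (ids, n), mask in zip(all_ids[k], keep_masks)
            if n >= config.min_patient_support
        ]
        if k < config.max_k and next_combos:
            combos = np.concatenate(next_combos)
            masks = np.concatenate(next_masks)
        else:
            combos = np.empty((0, k), dtype=np.int32)
            masks = np.empty((0, ds.n_subjects), dtype=bool)
        frontier_sizes[k] = combos.shape[0]

    return ExclusiveScanResult(
        snp_ids=ds.snp_ids,
        levels=levels,
        frontier_sizes=frontier_sizes,
        all_atom_ids=all_ids,
        min_patient_support=config.min_patient_support,
        n_candidates=n_candidates,
    )


def _contains_emitted(ids: tuple[int, ...], emitted: set[tuple[int, ...]]) -> bool:
    """True when any proper non-empty subset of *ids* was already emitted."""
    for j in range(1, len(ids)):
        for sub in itertools.combinations(ids, j):
            if sub in emitted:
                return True
    return False
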