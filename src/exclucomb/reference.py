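"""Naive reference implementations by exhaustive enumeration.

These walk every combination explicitly and are exponentially slow; they
exist as independent cross-checks for the level-wise scanner on tiny inputs,
not as usable implementations.  They share only the core data types with the
optimised scanner, none of its code paths.
"""

from __future__ import annotations

import itertools
from typing import Iterator

from .core import CarrierSet, Combination, GenotypeAtom, GenotypeDataset


def iter_all_combinations(n_snps: int, r: int) -> Iterator[Combination]:
    """Every r-atom combination on distinct SNPs, lexicographic order."""
    for snps in itertools.combinations(range(n_snps), r):
        for codes in itertools.product((0, 1, 2), repeat=r):
            yield Combination(tuple(GenotypeAtom(s, c) for s, c in zip(snps, codes)))


def brute_force_exclusives(
    ds: GenotypeDataset, max_k: int
) -> dict[int, list[tuple[Combination, CarrierSet]]]:
    """All patient-exclusive combinations up to size max_k, by size."""
    out: dict[int, list[tuple[Combination, CarrierSet]]] = {}
    for r in range(1, max_k + 1):
        found = []
        for combo in iter_all_combinations(ds.n_snps, r):
            cs = ds.carrier_set(combo)
            if cs.is_patient_exclusive:
                found.append((combo, cs))
        out[r] = found
    return out


def brute_force_minimal_exclusives(
    ds: GenotypeDataset, max_k: int
) -> dict[int, list[tuple[Combination, CarrierSet]]]:
    """Subset-minimal patient-exclusive combinations up to size max_k.

    A combination is kept when none of its proper sub-combinations is itself
    patient-exclusive, checked by direct enumeration of all subsets.
    """
    all_excl = brute_force_exclusives(ds, max_k)
    excl_keys = {
        tuple(c.atoms) for combos in all_excl.values() for c, _ in combos
    }
    out: dict[int, list[tuple[Combination, CarrierSet]]] = {}
    for r, combos in all_excl.items():
        minimal = []
        for combo, cs in combos:
            atoms = combo.atoms
            contained = any(
                sub in excl_keys
                for j in range(1, len(atoms))
                for sub in itertools.combinations(atoms, j)
            )
            if not contained:
                minimal.append((combo, cs))
        out[r] = minimal
    return out


def brute_force_partition(ds: GenotypeDataset, r: int) -> dict:
    """Exhaustive shared / patient-only / control-only accounting at size r."""
    found = shared = patient_only = control_only = 0
    hist: dict[int, int] = {}
    for combo in iter_all_combinations(ds.n_snps, r):
        cs = ds.carrier_set(combo)
        if len(cs) == 0:
            continue
        found += 1
        if cs.n_patients > 0 and cs.n_controls > 0:
            shared += 1
        elif cs.n_patients > 0:
            patient_only += 1
            hist[cs.n_patients] = hist.get(cs.n_patients, 0) + 1
        else:
            control_only += 1
    return {
        "found": found,
        "shared": shared,
        "patient_only": patient_only,
        "control_only": control_only,
        "patient_multiplicity": hist,
    }
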