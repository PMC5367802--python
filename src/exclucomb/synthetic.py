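"""Synthetic case/control genotype studies with known ground truth.

The null generator draws each SNP's minor-allele frequency uniformly from a
configurable range and genotypes every subject independently under
Hardy-Weinberg proportions ((1-q)^2, 2q(1-q), q^2); labels are assigned
independently of genotypes, so the data are exchangeable across groups and
any patient-exclusive combination is a finite-sample accident.  SNPs are
independent (no linkage disequilibrium) — the generator emulates the shape
of a case/control SNP panel, not its correlation structure.

On top of the null, :func:`plant_exclusive_cluster` plants an anchored
cluster of patient-exclusive combinations: member combinations share one
anchor genotype (the structure of a reported bipolar-disorder cluster — 16
four-genotype combinations on a common anchor, carried by 73 of 607
patients, absent from all controls); chosen patients are overwritten to
carry every atom of their member, and any control accidentally carrying a
member has one member atom flipped to a different genotype (minimal repair,
recorded in the truth).  Planting can accidentally make a proper
sub-combination of a member patient-exclusive; such *shadowed* members are
flagged in the truth rather than prevented, because a minimality-respecting
scanner will report the sub-combination instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    CarrierSet,
    Combination,
    GenotypeAtom,
    GenotypeDataset,
    ValidationError,
)

__all__ = [
    "SimulationSpec",
    "PlantSpec",
    "PlantedMember",
    "GroundTruth",
    "generate_null_dataset",
    "plant_exclusive_cluster",
    "generate_study",
]


@dataclass(frozen=True)
class PlantSpec:
    """One planted anchored cluster.

    anchor
        Genotype atom contained in every member combination.
    n_members
        Number of member combinations.
    k
        Atoms per member (>= 2; includes the anchor).
    patients_per_member
        Patients forced to carry each member (the realised carrier count can
        be higher through chance carriers).
    overlap
        Whether members may force the same patient (True, the default,
        mirrors observed clusters where carrier sets overlap); False samples
        disjoint forced-carrier sets.
    """

    anchor: GenotypeAtom
    n_members: int = 8
    k: int = 3
    patients_per_member: int = 3
    overlap: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("planted combinations need k >= 2 atoms")
        if self.patients_per_member < 1:
            raise ValidationError("patients_per_member must be >= 1")
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")


@dataclass(frozen=True)
class SimulationSpec:
    """Shape and signal of a simulated case/control study.

    Defaults give a desk-scale study of 200 patients and 400 controls typed
    on 100 SNPs (the same 1:2 case/control ratio as the 607/1354 bipolar
    material, scaled down) with per-SNP minor-allele frequencies uniform on
    [0.1, 0.5] — common variants, as on a genotyping panel.
    """

    n_patients: int = 200
    n_controls: int = 400
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.1, 0.5)
    planted_clusters: tuple[PlantSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if min(self.n_patients, self.n_controls, self.n_snps) < 1:
            raise ValidationError("counts must be >= 1")


@dataclass(frozen=True)
class PlantedMember:
    """One planted combination with its forced patient carriers."""

    combination: Combination
    forced_patients: tuple[int, ...]
    shadowed: bool = False


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, verified against the emitted dataset."""

    members: tuple[PlantedMember, ...]
    repaired_cells: tuple[tuple[int, int], ...]  # (subject, snp) control repairs
    spec: SimulationSpec | None = None

    @property
    def non_shadowed(self) -> tuple[PlantedMember, ...]:
        return tuple(m for m in self.members if not m.shadowed)

    def to_dict(self, snp_ids: Sequence[str] | None = None) -> dict:
        return {
            "members": [
                {
                    "combination": m.combination.render(snp_ids),
                    "forced_patients": list(m.forced_patients),
                    "shadowed": m.shadowed,
                }
                for m in self.members
            ],
            "repaired_cells": [list(c) for c in self.repaired_cells],
            "seed": self.spec.seed if self.spec else None,
        }


def generate_null_dataset(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> GenotypeDataset:
    """Exchangeable case/control data: HWE genotypes, labels independent."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_sub = spec.n_patients + spec.n_controls
    q = rng.uniform(*spec.maf_range, size=spec.n_snps)
    p0 = (1 - q) ** 2
    p1 = 2 * q * (1 - q)
    u = rng.random((n_sub, spec.n_snps))
    geno = ((u > p0).astype(np.int8) + (u > p0 + p1).astype(np.int8))
    subject_ids = [f"P{i + 1:04d}" for i in range(spec.n_patients)] + [
        f"C{i + 1:04d}" for i in range(spec.n_controls)
    ]
    labels = np.zeros(n_sub, dtype=bool)
    labels[: spec.n_patients] = True
    snp_ids = [f"snp{j + 1:04d}" for j in range(spec.n_snps)]
    return GenotypeDataset(subject_ids, labels, snp_ids, geno)


def _sample_members(
    ds: GenotypeDataset, plant: PlantSpec, rng: np.random.Generator
) -> list[Combination]:
    """Distinct member combinations: anchor + k-1 partner atoms on other SNPs."""
    other_snps = [s for s in range(ds.n_snps) if s != plant.anchor.snp_index]
    if len(other_snps) < plant.k - 1:
        raise ValidationError(
            f"need {plant.k - 1} partner SNPs, dataset has {len(other_snps)}"
        )
    members: list[Combination] = []
    seen: set[tuple] = set()
    for _ in range(10_000):
        if len(members) == plant.n_members:
            break
        snps = rng.choice(other_snps, size=plant.k - 1, replace=False)
        codes = rng.integers(0, 3, size=plant.k - 1)
        atoms = (plant.anchor, *(GenotypeAtom(int(s), int(c)) for s, c in zip(snps, codes)))
        combo = Combination(atoms)
        key = tuple(combo.atoms)
        if key not in seen:
            seen.add(key)
            members.append(combo)
    if len(members) < plant.n_members:
        raise ValidationError(
            f"could not sample {plant.n_members} distinct members with "
            f"k={plant.k} over {ds.n_snps} SNPs"
        )
    return members


def _assign_carriers(
    ds: GenotypeDataset,
    members: list[Combination],
    plant: PlantSpec,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Forced patient carriers per member, conflict-free.

    Two members conflict on a patient when they pin different codes on the
    same SNP; a conflicting assignment is resampled (bounded retries) before
    any genotype is written.
    """
    patients = [int(p) for p in ds.patient_indices]
    need = plant.patients_per_member
    if plant.overlap:
        assigned: list[list[int]] = []
        pinned: dict[int, dict[int, int]] = {}  # patient -> snp -> code
        for member in members:
            atoms = {a.snp_index: a.code for a in member.atoms}
            chosen: list[int] = []
            pool = patients.copy()
            rng.shuffle(pool)
            for p in pool:
                if len(chosen) == need:
                    break
                pins = pinned.get(p, {})
                if any(pins.get(s, c) != c for s, c in atoms.items()):
                    continue  # conflicting pin on a shared SNP
                chosen.append(p)
            if len(chosen) < need:
                raise ValidationError(
                    "cannot assign forced carriers without genotype conflicts; "
                    "fewer members or more patients needed"
                )
            for p in chosen:
                pinned.setdefault(p, {}).update(atoms)
            assigned.append(chosen)
        return assigned
    total = need * len(members)
    if total > len(patients):
        raise ValidationError(
            f"disjoint planting needs {total} patients, dataset has {len(patients)}"
        )
    picks = rng.choice(patients, size=total, replace=False)
    return [list(map(int, picks[i * need : (i + 1) * need])) for i in range(len(members))]


def plant_exclusive_cluster(
    ds: GenotypeDataset,
    plant: PlantSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeDataset, GroundTruth]:
    """Plant an anchored cluster of patient-exclusive combinations.

    Returns a new dataset (the input is not mutated) and the ground truth.
    Member combinations and their forced carriers are chosen first and
    validated; genotypes of forced carriers are overwritten to carry every
    member atom; controls accidentally carrying a member are repaired by
    flipping one member atom to a different code (re-checked to a fixed
    point).  Exclusivity of every member is re-verified on the emitted
    matrix — a hard postcondition, not a sampling hope.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if plant.anchor.snp_index >= ds.n_snps:
        raise ValidationError("anchor SNP outside the dataset")
    if ds.n_patients < plant.patients_per_member:
        raise ValidationError("not enough patients for the requested plant")
    # a sampled member set can be unassignable (members pinning different codes
    # on a shared SNP with too few patients to separate them): resample a few
    # times before declaring the plant unsatisfiable
    last_err: ValidationError | None = None
    for _ in range(20):
        members = _sample_members(ds, plant, rng)
        try:
            assigned = _assign_carriers(ds, members, plant, rng)
            break
        except ValidationError as e:
            last_err = e
    else:
        raise ValidationError(
            f"plant unsatisfiable after 20 member resamplings: {last_err}"
        )

    geno = ds.genotypes.copy()
    for member, carriers in zip(members, assigned):
        for p in carriers:
            for atom in member.atoms:
                geno[p, atom.snp_index] = atom.code

    # control repair to a fixed point: flipping one atom for one member can
    # by chance complete another member, so sweep until no control carries any
    repaired: list[tuple[int, int]] = []
    control_idx = np.flatnonzero(~ds.is_patient)
    for _ in range(100):
        dirty = False
        for member in members:
            mask = np.ones(ds.n_subjects, dtype=bool)
            for atom in member.atoms:
                mask &= geno[:, atom.snp_index] == atom.code
            bad = [c for c in control_idx if mask[c]]
            for c in bad:
                atom = member.atoms[rng.integers(len(member.atoms))]
                new_code = int((atom.code + 1 + rng.integers(2)) % 3)
                geno[c, atom.snp_index] = new_code
                repaired.append((int(c), int(atom.snp_index)))
                dirty = True
        if not dirty:
            break
    else:  # pragma: no cover - practically unreachable
        raise ValidationError("control repair did not converge")

    out = GenotypeDataset(ds.subject_ids, ds.is_patient, ds.snp_ids, geno)

    truth_members = []
    for member, carriers in zip(members, assigned):
        cs = out.carrier_set(member)
        if not cs.is_patient_exclusive or cs.n_patients < plant.patients_per_member:
            raise ValidationError("planting postcondition failed")  # pragma: no cover
        truth_members.append(
            PlantedMember(
                combination=member,
                forced_patients=tuple(sorted(carriers)),
                shadowed=_is_shadowed(out, member),
            )
        )
    return out, GroundTruth(tuple(truth_members), tuple(repaired))


def _is_shadowed(ds: GenotypeDataset, member: Combination) -> bool:
    """True when a proper sub-combination of the member is patient-exclusive."""
    import itertools

    atoms = member.atoms
    for j in range(1, len(atoms)):
        for sub in itertools.combinations(atoms, j):
            cs = ds.carrier_set(Combination(sub))
            if cs.is_patient_exclusive:
                return True
    return False


def generate_study(spec: SimulationSpec) -> tuple[GenotypeDataset, GroundTruth]:
    """Null generation followed by all plants; one seed drives the pipeline."""
    rng = np.random.default_rng(spec.seed)
    ds = generate_null_dataset(spec, rng)
    members: tuple[PlantedMember, ...] = ()
    repaired: tuple[tuple[int, int], ...] = ()
    for plant in spec.planted_clusters:
        ds, truth = plant_exclusive_cluster(ds, plant, rng)
        members += truth.members
        repaired += truth.repaired_cells
    # re-flag shadowing on the final matrix (a later plant can shadow an earlier one)
    members = tuple(
        replace(m, shadowed=_is_shadowed(ds, m.combination)) for m in members
    )
    return ds, GroundTruth(members, repaired, spec=spec)
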