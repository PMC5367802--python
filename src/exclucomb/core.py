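"""Core domain types: genotype datasets, genotype atoms, combinations, carrier sets.

A biallelic SNP has three diploid genotypes, encoded 0 (reference homozygote),
1 (heterozygote), 2 (alternate homozygote); :data:`MISSING` (-1) marks an
unobserved genotype.  A *genotype atom* is one genotype at one SNP; a
*combination* is a set of atoms on distinct SNPs; a subject *carries* a
combination when their genotype matches every atom.  Subjects with a missing
genotype at a SNP carry no atom at that SNP.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Genotype code for an unobserved genotype.
MISSING: int = -1

#: Valid observed genotype codes.
GENOTYPE_CODES: tuple[int, int, int] = (0, 1, 2)

#: Marker returned by annotation lookups for SNPs/genes without annotation.
UNANNOTATED: str = "unannotated"


class ExclucombError(Exception):
    """Base class for package errors."""


class ValidationError(ExclucombError, ValueError):
    """Malformed input data or invalid parameters."""


class BudgetError(ExclucombError, RuntimeError):
    """An enumeration whose size exceeds the configured budget was refused."""


@dataclass(frozen=True, order=True)
class GenotypeAtom:
    """One genotype at one SNP — the unit the 3^r factor counts.

    Parameters
    ----------
    snp_index : int
        Column index into the dataset's ``snp_ids``.
    code : int
        Genotype code in {0, 1, 2}; never MISSING.
    """

    snp_index: int
    code: int

    def __post_init__(self) -> None:
        if self.code not in GENOTYPE_CODES:
            raise ValidationError(
                f"atom code must be one of {GENOTYPE_CODES}, got {self.code!r}"
            )
        if self.snp_index < 0:
            raise ValidationError(f"negative snp_index {self.snp_index}")


@dataclass(frozen=True)
class Combination:
    """An ordered set of genotype atoms on distinct SNPs.

    Atoms are stored sorted by ``snp_index`` so equality and the textual
    rendering are canonical.
    """

    atoms: tuple[GenotypeAtom, ...]

    def __post_init__(self) -> None:
        atoms = tuple(sorted(self.atoms))
        snps = [a.snp_index for a in atoms]
        if len(set(snps)) != len(snps):
            raise ValidationError(f"combination has repeated SNP indices: {snps}")
        object.__setattr__(self, "atoms", atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __contains__(self, atom: GenotypeAtom) -> bool:
        return atom in self.atoms

    def contains(self, other: "Combination") -> bool:
        """True when every atom of *other* is an atom of this combination."""
        return set(other.atoms) <= set(self.atoms)

    def render(self, snp_ids: Sequence[str] | None = None) -> str:
        """Canonical text form ``snp:code+snp:code+...``."""
        parts = []
        for a in self.atoms:
            name = snp_ids[a.snp_index] if snp_ids is not None else str(a.snp_index)
            parts.append(f"{name}:{a.code}")
        return "+".join(parts)

    @classmethod
    def from_atoms(cls, atoms: Iterable[GenotypeAtom]) -> "Combination":
        return cls(tuple(atoms))

    @classmethod
    def parse(cls, text: str, snp_ids: Sequence[str] | None = None) -> "Combination":
        """Inverse of :meth:`render`."""
        index = {s: i for i, s in enumerate(snp_ids)} if snp_ids is not None else None
        atoms = []
        for part in text.split("+"):
            m = re.fullmatch(r"(.+):([012])", part)
            if m is None:
                raise ValidationError(f"cannot parse combination part {part!r}")
            name, code = m.group(1), int(m.group(2))
            snp = index[name] if index is not None else int(name)
            atoms.append(GenotypeAtom(snp, code))
        return cls(tuple(atoms))


@dataclass(frozen=True)
class CarrierSet:
    """The subjects carrying an atom or combination, with per-label counts."""

    members: frozenset[int]
    n_patients: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_patients + self.n_controls != len(self.members):
            raise ValidationError("carrier counts do not sum to the member count")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def is_patient_exclusive(self) -> bool:
        """Carried by at least one patient and no control."""
        return self.n_patients >= 1 and self.n_controls == 0

    @classmethod
    def from_mask(cls, mask: np.ndarray, is_patient: np.ndarray) -> "CarrierSet":
        idx = np.flatnonzero(mask)
        n_pat = int(np.count_nonzero(mask & is_patient))
        return cls(frozenset(int(i) for i in idx), n_pat, len(idx) - n_pat)


class GenotypeDataset:
    """A subjects × SNPs genotype matrix with case/control labels.

    Parameters
    ----------
    subject_ids : sequence of str
        Unique subject identifiers, one per row.
    is_patient : boolean array
        True for patients (cases), False for controls.
    snp_ids : sequence of str
        Unique SNP identifiers, one per column.
    genotypes : int array, shape (n_subjects, n_snps)
        Codes in {0, 1, 2, MISSING}.

    A dataset with zero patients or zero controls is allowed (it can arise
    under label permutation) but carries ``degenerate_labels = True``; scans
    on such data are meaningless and statistical tests refuse it.
    """

    def __init__(
        self,
        subject_ids: Sequence[str],
        is_patient: np.ndarray | Sequence[bool],
        snp_ids: Sequence[str],
        genotypes: np.ndarray,
        *,
        validate: bool = True,
    ) -> None:
        self.subject_ids = list(subject_ids)
        self.is_patient = np.asarray(is_patient, dtype=bool)
        self.snp_ids = list(snp_ids)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        if validate:
            self._validate()
        self.degenerate_labels = (
            self.n_patients == 0 or self.n_controls == 0
        )

    def _validate(self) -> None:
        n_sub, n_snp = self.genotypes.shape if self.genotypes.ndim == 2 else (0, 0)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        if len(self.subject_ids) != n_sub:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {n_sub} genotype rows"
            )
        if len(self.snp_ids) != n_snp:
            raise ValidationError(
                f"{len(self.snp_ids)} SNP ids for {n_snp} genotype columns"
            )
        if self.is_patient.shape != (n_sub,):
            raise ValidationError("one label per subject required")
        if len(set(self.subject_ids)) != n_sub:
            dup = _first_duplicate(self.subject_ids)
            raise ValidationError(f"duplicate subject id {dup!r}")
        if len(set(self.snp_ids)) != n_snp:
            dup = _first_duplicate(self.snp_ids)
            raise ValidationError(f"duplicate SNP id {dup!r}")
        bad = ~np.isin(self.genotypes, (*GENOTYPE_CODES, MISSING))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype code {int(self.genotypes[r, c])} at subject "
                f"{self.subject_ids[r]!r}, SNP {self.snp_ids[c]!r}"
            )

    # -- shape and label helpers -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_patients(self) -> int:
        return int(np.count_nonzero(self.is_patient))

    @property
    def n_controls(self) -> int:
        return self.n_subjects - self.n_patients

    @property
    def patient_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_patient)

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_patient)

    def atom_mask(self, atom: GenotypeAtom) -> np.ndarray:
        """Boolean carrier mask of a single atom (MISSING never matches)."""
        if not 0 <= atom.snp_index < self.n_snps:
            raise ValidationError(
                f"snp_index {atom.snp_index} out of range for {self.n_snps} SNPs"
            )
        return self.genotypes[:, atom.snp_index] == atom.code

    def combination_mask(self, combo: Combination) -> np.ndarray:
        """Boolean carrier mask of a combination (all atoms must match)."""
        mask = np.ones(self.n_subjects, dtype=bool)
        for atom in combo:
            mask &= self.atom_mask(atom)
        return mask

    def with_labels(self, is_patient: np.ndarray) -> "GenotypeDataset":
        """Cheap relabelled view sharing the genotype matrix (for permutation)."""
        ds = GenotypeDataset.__new__(GenotypeDataset)
        ds.subject_ids = self.subject_ids
        ds.snp_ids = self.snp_ids
        ds.genotypes = self.genotypes
        ds.is_patient = np.asarray(is_patient, dtype=bool)
        ds.degenerate_labels = ds.n_patients == 0 or ds.n_controls == 0
        return ds

    def carrier_set(self, combo: Combination) -> CarrierSet:
        return CarrierSet.from_mask(self.combination_mask(combo), self.is_patient)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.is_patient, other.is_patient)
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeDataset({self.n_subjects} subjects "
            f"[{self.n_patients} patients/{self.n_controls} controls], "
            f"{self.n_snps} SNPs)"
        )


@dataclass
class AnnotationMap:
    """SNP → gene and gene → pathway annotations.

    Lookups for unannotated SNPs or genes return :data:`UNANNOTATED` /
    an empty set, never raise.
    """

    snp_to_gene: dict[str, str] = field(default_factory=dict)
    gene_to_pathway: dict[str, frozenset[str]] = field(default_factory=dict)

    def gene_of(self, snp_id: str) -> str:
        return self.snp_to_gene.get(snp_id, UNANNOTATED)

    def pathways_of_gene(self, gene: str) -> frozenset[str]:
        return self.gene_to_pathway.get(gene, frozenset())

    def pathways_of_snp(self, snp_id: str) -> frozenset[str]:
        return self.pathways_of_gene(self.gene_of(snp_id))

    @property
    def pathways(self) -> frozenset[str]:
        out: set[str] = set()
        for ps in self.gene_to_pathway.values():
            out |= ps
        return frozenset(out)


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
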