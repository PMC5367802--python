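"""Grouping patient-exclusive combinations into clusters.

A single exclusive combination is usually carried by too few patients to
reach significance on its own; clusters pool combinations that share a
defining feature so the pooled carrier group can be tested.  Three rules are
supported: a common *anchor* genotype contained in every member, a low-p
seed atom (single-atom association p below a cutoff), and a shared pathway
annotation.  A patient belongs to a cluster when they carry at least one of
its member combinations; on the source dataset no control ever does, because
members are patient-exclusive by construction.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .core import (
    AnnotationMap,
    CarrierSet,
    Combination,
    GenotypeAtom,
    GenotypeDataset,
    ValidationError,
)
from .scan import ExclusiveScanResult

__all__ = [
    "Cluster",
    "ClusterCarriers",
    "AnchorRule",
    "LowPRule",
    "PathwayRule",
    "ClusterRule",
    "build_cluster",
    "cluster_by_anchor",
    "cluster_by_low_p",
    "cluster_by_pathway",
    "cluster_patient_carriers",
]


@dataclass(frozen=True)
class AnchorRule:
    """Members must contain this genotype atom."""

    anchor: GenotypeAtom

    def describe(self, snp_ids: Sequence[str] | None = None) -> str:
        name = snp_ids[self.anchor.snp_index] if snp_ids else self.anchor.snp_index
        return f"anchor={name}:{self.anchor.code}"


@dataclass(frozen=True)
class LowPRule:
    """Members must contain >=1 atom with single-atom association p <= alpha."""

    alpha: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha must be in (0, 1], got {self.alpha}")

    def describe(self, snp_ids: Sequence[str] | None = None) -> str:
        return f"low_p<={self.alpha}"


@dataclass(frozen=True)
class PathwayRule:
    """Members must contain >=1 atom whose SNP maps (via its gene) to the pathway."""

    pathway: str
    annotations: AnnotationMap = field(compare=False)

    def describe(self, snp_ids: Sequence[str] | None = None) -> str:
        return f"pathway={self.pathway}"


ClusterRule = Union[AnchorRule, LowPRule, PathwayRule]


@dataclass(frozen=True)
class Cluster:
    """A rule-defined set of patient-exclusive combinations.

    ``patient_carriers`` is the union of the member carrier sets on the
    source dataset; its ``n_controls`` is 0 there by member exclusivity.
    """

    rule_description: str
    members: tuple[Combination, ...]
    patient_carriers: CarrierSet

    def __len__(self) -> int:
        return len(self.members)

    @property
    def identity(self) -> str:
        """Stable digest of rule + sorted member list, for cross-run comparison."""
        text = self.rule_description + "|" + ";".join(
            sorted(m.render() for m in self.members)
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def to_report(
        self, ds: GenotypeDataset, member_counts: Mapping[str, int] | None = None
    ) -> dict:
        return {
            "rule": self.rule_description,
            "identity": self.identity,
            "n_members": len(self.members),
            "members": [m.render(ds.snp_ids) for m in self.members],
            "n_patient_carriers": self.patient_carriers.n_patients,
            "n_control_carriers": self.patient_carriers.n_controls,
            "patient_carriers": sorted(
                ds.subject_ids[i] for i in self.patient_carriers.members
            ),
            **(
                {"per_patient_member_counts": dict(member_counts)}
                if member_counts is not None
                else {}
            ),
        }


@dataclass(frozen=True)
class ClusterCarriers:
    """Cluster membership of patients with per-patient accumulation counts."""

    carriers: CarrierSet
    member_counts: Mapping[int, int]  # subject index -> number of members carried


def _scan_members(scan: ExclusiveScanResult) -> list[Combination]:
    return [combo for _, combo, _ in scan.combinations()]


def _make_cluster(
    description: str, members: Sequence[Combination], ds: GenotypeDataset
) -> Cluster:
    mask = np.zeros(ds.n_subjects, dtype=bool)
    for m in members:
        mask |= ds.combination_mask(m)
    return Cluster(
        rule_description=description,
        members=tuple(members),
        patient_carriers=CarrierSet.from_mask(mask, ds.is_patient),
    )


def build_cluster(
    rule: ClusterRule,
    scan: ExclusiveScanResult,
    ds: GenotypeDataset,
) -> Cluster:
    """Apply a cluster rule to scanned exclusive combinations.

    Clustering is a pure filter over the scan's reported combinations —
    it never creates a combination.
    """
    if isinstance(rule, AnchorRule):
        return cluster_by_anchor(scan, ds, rule.anchor)
    if isinstance(rule, LowPRule):
        from .stats import atom_pvalue_matrix

        pvals = atom_pvalue_matrix(ds)
        members = [
            m
            for m in _scan_members(scan)
            if any(pvals[a.snp_index, a.code] <= rule.alpha for a in m)
        ]
        return _make_cluster(rule.describe(ds.snp_ids), members, ds)
    if isinstance(rule, PathwayRule):
        return cluster_by_pathway(scan, ds, rule.annotations, rule.pathway)
    raise ValidationError(f"unknown cluster rule {rule!r}")


def cluster_by_anchor(
    scan: ExclusiveScanResult, ds: GenotypeDataset, anchor: GenotypeAtom
) -> Cluster:
    """All scanned exclusive combinations containing the anchor atom.

    An anchor contained in no combination yields an empty cluster, not an
    error.
    """
    members = [m for m in _scan_members(scan) if anchor in m]
    return _make_cluster(AnchorRule(anchor).describe(ds.snp_ids), members, ds)


def cluster_by_low_p(
    scan: ExclusiveScanResult, ds: GenotypeDataset, alpha: float
) -> list[Cluster]:
    """One cluster per low-p atom (p <= alpha), empty clusters omitted.

    The test is per genotype atom (carrier vs non-carrier, 2x2) rather than
    per SNP: clusters are defined by a genotype, not a SNP.  For a single
    re-derivable construction pooling all low-p members, use
    :class:`LowPRule` with :func:`build_cluster`.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    from .stats import atom_pvalue_matrix

    pvals = atom_pvalue_matrix(ds)
    members = _scan_members(scan)
    atoms = sorted({a for m in members for a in m})
    clusters = []
    for atom in atoms:
        if pvals[atom.snp_index, atom.code] > alpha:
            continue
        mem = [m for m in members if atom in m]
        if mem:
            clusters.append(
                _make_cluster(
                    f"low_p_atom={atom.snp_index}:{atom.code} (alpha={alpha})",
                    mem,
                    ds,
                )
            )
    return clusters


def cluster_by_pathway(
    scan: ExclusiveScanResult,
    ds: GenotypeDataset,
    annotations: AnnotationMap,
    pathway: str,
) -> Cluster:
    """Exclusive combinations containing >=1 atom annotated to the pathway."""
    if pathway not in annotations.pathways:
        warnings.warn(f"pathway {pathway!r} not present in the annotation map")
    members = [
        m
        for m in _scan_members(scan)
        if any(pathway in annotations.pathways_of_snp(ds.snp_ids[a.snp_index]) for a in m)
    ]
    return _make_cluster(f"pathway={pathway}", members, ds)


def cluster_patient_carriers(ds: GenotypeDataset, cluster: Cluster) -> ClusterCarriers:
    """Patients carrying >=1 cluster member, with per-patient accumulation.

    The accumulation count (how many members each patient carries) is the
    personal-risk quantity layered on top of cluster membership.
    """
    counts = np.zeros(ds.n_subjects, dtype=int)
    union = np.zeros(ds.n_subjects, dtype=bool)
    for m in cluster.members:
        mask = ds.combination_mask(m)
        counts += mask
        union |= mask
    union &= ds.is_patient
    member_counts = {
        int(i): int(counts[i]) for i in np.flatnonzero(union)
    }
    return ClusterCarriers(
        carriers=CarrierSet.from_mask(union, ds.is_patient),
        member_counts=member_counts,
    )
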