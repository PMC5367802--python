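"""Reading and writing genotype tables, VCFs and annotation files.

The native table format is a TSV with one row per subject::

    subject_id<TAB>status<TAB>rs1<TAB>rs2<TAB>...
    P1<TAB>case<TAB>0<TAB>1<TAB>...

``status`` accepts case/patient/1 for patients and control/0 for controls
(configurable).  Genotype cells hold 0/1/2 or the missing token (default
``NA``).  VCF input carries no phenotype, so sample status comes from a
sidecar TSV of ``sample<TAB>status``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    AnnotationMap,
    GenotypeDataset,
    ValidationError,
)

logger = logging.getLogger(__name__)

_CASE_TOKENS = frozenset({"case", "patient", "affected", "1"})
_CONTROL_TOKENS = frozenset({"control", "unaffected", "0"})


@dataclass(frozen=True)
class TableDialect:
    """Separator/token options for the genotype table format."""

    sep: str = "\t"
    missing: str = "NA"
    subject_column: str = "subject_id"
    status_column: str = "status"
    case_tokens: frozenset[str] = _CASE_TOKENS
    control_tokens: frozenset[str] = _CONTROL_TOKENS


def read_genotype_table(
    path: str | Path, dialect: TableDialect = TableDialect()
) -> GenotypeDataset:
    """Read a subjects × SNPs genotype table.

    Row order of the file is preserved as subject order.  A malformed
    genotype code raises :class:`ValidationError` naming the offending
    subject and SNP; zero patients or zero controls only sets the dataset's
    ``degenerate_labels`` flag (with a warning).
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in (dialect.subject_column, dialect.status_column):
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r} in {path}")
    subject_ids = df[dialect.subject_column].tolist()
    labels = []
    for sid, raw in zip(subject_ids, df[dialect.status_column]):
        token = raw.strip().lower()
        if token in dialect.case_tokens:
            labels.append(True)
        elif token in dialect.control_tokens:
            labels.append(False)
        else:
            raise ValidationError(f"unrecognised status {raw!r} for subject {sid!r}")
    snp_ids = [
        c for c in df.columns if c not in (dialect.subject_column, dialect.status_column)
    ]
    geno = np.full((len(subject_ids), len(snp_ids)), MISSING, dtype=np.int8)
    for j, snp in enumerate(snp_ids):
        col = df[snp].str.strip()
        for i, cell in enumerate(col):
            if cell == dialect.missing:
                continue
            if cell in ("0", "1", "2"):
                geno[i, j] = int(cell)
            else:
                raise ValidationError(
                    f"invalid genotype code {cell!r} at subject "
                    f"{subject_ids[i]!r}, SNP {snp!r}"
                )
    ds = GenotypeDataset(subject_ids, labels, snp_ids, geno)
    if ds.degenerate_labels:
        warnings.warn(
            f"dataset from {path} has zero patients or zero controls", stacklevel=2
        )
    return ds


def write_genotype_table(
    ds: GenotypeDataset, path: str | Path, dialect: TableDialect = TableDialect()
) -> None:
    """Write *ds* in the TSV dialect; exact inverse of :func:`read_genotype_table`."""
    codes = ds.genotypes.astype(object)
    codes[ds.genotypes == MISSING] = dialect.missing
    df = pd.DataFrame(codes, columns=ds.snp_ids)
    df.insert(0, dialect.status_column, np.where(ds.is_patient, "case", "control"))
    df.insert(0, dialect.subject_column, ds.subject_ids)
    df.to_csv(path, sep=dialect.sep, index=False)


def read_status_sidecar(path: str | Path, dialect: TableDialect = TableDialect()) -> dict[str, bool]:
    """Read a ``sample<TAB>status`` sidecar into {sample: is_patient}."""
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"sidecar {path} needs sample and status columns")
    out: dict[str, bool] = {}
    for sid, raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        token = raw.strip().lower()
        if token in dialect.case_tokens:
            out[sid] = True
        elif token in dialect.control_tokens:
            out[sid] = False
        else:
            raise ValidationError(f"unrecognised status {raw!r} for sample {sid!r}")
    return out


@dataclass
class VcfReadReport:
    """Side information from a VCF load."""

    n_records: int = 0
    n_multiallelic_skipped: int = 0
    skipped_ids: list[str] = field(default_factory=list)


def read_vcf(
    vcf_path: str | Path,
    status_path: str | Path,
    *,
    report: VcfReadReport | None = None,
) -> GenotypeDataset:
    """Load genotypes from a VCF (GT fields) plus a status sidecar TSV.

    GT mapping: 0/0→0, 0/1 or 1/0→1, 1/1→2, ./. (or any missing allele)→MISSING.
    Multiallelic records are skipped with a logged count — the three-genotype
    combinatorics assume biallelic sites.  A sample present in the VCF but
    absent from the sidecar is an error.
    """
    import pysam

    status = read_status_sidecar(status_path)
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        missing_samples = [s for s in samples if s not in status]
        if missing_samples:
            raise ValidationError(
                f"samples absent from status sidecar: {missing_samples}"
            )
        snp_ids: list[str] = []
        rows: list[np.ndarray] = []
        rep = report if report is not None else VcfReadReport()
        for rec in vf:
            rep.n_records += 1
            if len(rec.alts or ()) != 1:
                rep.n_multiallelic_skipped += 1
                rid = rec.id or f"{rec.chrom}:{rec.pos}"
                rep.skipped_ids.append(rid)
                logger.warning("skipping multiallelic record %s", rid)
                continue
            snp_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    continue
                col[i] = int(gt[0]) + int(gt[1])
            rows.append(col)
    geno = (
        np.column_stack(rows)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    ds = GenotypeDataset(samples, [status[s] for s in samples], snp_ids, geno)
    if ds.degenerate_labels:
        warnings.warn(
            f"dataset from {vcf_path} has zero patients or zero controls",
            stacklevel=2,
        )
    return ds


def read_annotations(path: str | Path, sep: str = "\t") -> AnnotationMap:
    """Read a ``snp_id<TAB>gene<TAB>pathway`` annotation table.

    A gene may appear on several rows with different pathways (multi-pathway
    genes); the pathway field may be empty.  Duplicate SNP rows assigning
    conflicting genes are an error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    needed = {"snp_id", "gene"}
    if not needed <= set(df.columns):
        raise ValidationError(f"annotation file {path} must have columns snp_id, gene")
    snp_to_gene: dict[str, str] = {}
    gene_to_pathway: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        snp = row["snp_id"].strip()
        gene = row["gene"].strip()
        if snp in snp_to_gene and snp_to_gene[snp] != gene:
            raise ValidationError(
                f"SNP {snp!r} annotated to both {snp_to_gene[snp]!r} and {gene!r}"
            )
        snp_to_gene[snp] = gene
        pathway = row.get("pathway", "").strip() if "pathway" in df.columns else ""
        if pathway:
            gene_to_pathway.setdefault(gene, set()).add(pathway)
    return AnnotationMap(
        snp_to_gene,
        {g: frozenset(ps) for g, ps in gene_to_pathway.items()},
    )
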