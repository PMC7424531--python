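"""Readers and writers for mutation tables, annotations, metadata and expression.

All tables are tab-separated text.  Mutation tables are accepted in two
dialects: the TCGA MC3 MAF column set (``Hugo_Symbol``,
``Variant_Classification``, ``Variant_Type``, ``Tumor_Sample_Barcode``) and a
minimal canonical 4+ column set (``gene``, ``variant_classification``,
``variant_type``, ``sample_id``).  In memory a mutation table is a
:class:`pandas.DataFrame` with the canonical columns; :class:`MutationRecord`
is the record-level view.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .vocab import (
    CLASS_SYNONYMS,
    DEL_CLASSES,
    INS_CLASSES,
    TYPE_SYNONYMS,
    MsiStatus,
    PoleStatus,
    VariantClass,
    VariantType,
)

log = logging.getLogger(__name__)

#: Canonical mutation-table columns, in write order.
MUTATION_COLUMNS = [
    "sample_id",
    "gene",
    "variant_classification",
    "variant_type",
    "chrom",
    "pos",
    "protein_change",
]

#: Column aliases recognised when reading a mutation table.
_COLUMN_ALIASES: dict[str, str] = {
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
    "Variant_Type": "variant_type",
    "Tumor_Sample_Barcode": "sample_id",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "HGVSp_Short": "protein_change",
}

_MANDATORY = ["sample_id", "gene", "variant_classification", "variant_type"]


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation event.

    ``variant_classification`` and ``variant_type`` must be mutually
    consistent: frameshift/in-frame insertion classes imply INS, the deletion
    classes imply DEL, and neither may carry type SNV.
    """

    sample_id: str
    gene: str
    variant_classification: VariantClass
    variant_type: VariantType
    chrom: str | None = None
    pos: int | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        cls, typ = self.variant_classification, self.variant_type
        if cls in INS_CLASSES and typ is not VariantType.INS:
            raise ValueError(f"{cls.value} requires variant_type INS, got {typ.value}")
        if cls in DEL_CLASSES and typ is not VariantType.DEL:
            raise ValueError(f"{cls.value} requires variant_type DEL, got {typ.value}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: CDS length (bp), GC fraction, replication time.

    Lower replication time means earlier replication in S-phase.
    """

    gene: str
    cds_length: int
    gc_fraction: float
    replication_time: float | None = None
    is_flags: bool = False

    def __post_init__(self) -> None:
        if self.cds_length <= 0:
            raise ValueError(f"cds_length must be positive, got {self.cds_length}")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError(f"gc_fraction must lie in (0,1), got {self.gc_fraction}")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    tumor_type: str = "NA"
    msi_status: MsiStatus = MsiStatus.UNKNOWN
    pole_status: PoleStatus = PoleStatus.UNKNOWN


def normalize_classification(value: str, synonyms: Mapping[str, VariantClass] | None = None) -> VariantClass:
    """Map a raw classification string onto the controlled vocabulary.

    Unknown values map to ``Other`` with a logged warning.
    """
    table = CLASS_SYNONYMS if synonyms is None else synonyms
    try:
        return table[value]
    except KeyError:
        log.warning("unknown variant classification %r mapped to Other", value)
        return VariantClass.OTHER


def normalize_type(value: str) -> VariantType:
    try:
        return TYPE_SYNONYMS[value]
    except KeyError:
        log.warning("unknown variant type %r mapped to SNV", value)
        return VariantType.SNV


def read_mutation_table(
    path,
    dialect_config: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Read a MAF-dialect mutation table into a canonical DataFrame.

    Parameters
    ----------
    path
        Tab-separated file.  Lines starting with ``#`` are skipped.
    dialect_config
        Optional mapping with keys ``columns`` (raw column -> canonical
        column) and ``classes`` (raw class -> canonical class name), merged
        on top of the built-in TCGA dialect.

    Returns
    -------
    DataFrame with columns :data:`MUTATION_COLUMNS`; classification and type
    are canonical vocabulary strings.
    """
    col_map = dict(_COLUMN_ALIASES)
    class_map = dict(CLASS_SYNONYMS)
    if dialect_config:
        col_map.update(dialect_config.get("columns", {}))
        for raw, canon in dialect_config.get("classes", {}).items():
            class_map[raw] = VariantClass(canon)

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.rename(columns=col_map)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"mutation table {path} missing mandatory column(s): {', '.join(missing)}")

    out = pd.DataFrame(index=df.index)
    out["sample_id"] = df["sample_id"].astype(str)
    out["gene"] = df["gene"].astype(str)
    out["variant_classification"] = [
        normalize_classification(v, class_map).value for v in df["variant_classification"]
    ]
    out["variant_type"] = [normalize_type(v).value for v in df["variant_type"]]
    out["chrom"] = df["chrom"] if "chrom" in df.columns else pd.NA
    out["pos"] = pd.to_numeric(df["pos"], errors="coerce") if "pos" in df.columns else pd.NA
    out["protein_change"] = df["protein_change"] if "protein_change" in df.columns else pd.NA
    return out.reset_index(drop=True)


def write_mutation_table(mutations: pd.DataFrame, path) -> None:
    """Write a canonical mutation table as TSV (round-trips with the reader)."""
    mutations.reindex(columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [
        (r.sample_id, r.gene, r.variant_classification.value, r.variant_type.value, r.chrom, r.pos, r.protein_change)
        for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def frame_to_records(mutations: pd.DataFrame) -> list[MutationRecord]:
    return [
        MutationRecord(
            sample_id=row.sample_id,
            gene=row.gene,
            variant_classification=VariantClass(row.variant_classification),
            variant_type=VariantType(row.variant_type),
            chrom=None if pd.isna(row.chrom) else str(row.chrom),
            pos=None if pd.isna(row.pos) else int(row.pos),
            protein_change=None if pd.isna(row.protein_change) else str(row.protein_change),
        )
        for row in mutations.itertuples(index=False)
    ]


def summarize_classes(mutations: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts and percentages over non-intronic mutations.

    Percentages are 100*count/total over records whose classification is not
    ``Intron``, rounded to two decimals; the table is sorted by descending
    count.  An all-intronic (or empty) input yields an empty table with a
    warning.
    """
    if len(mutations) == 0:
        raise ValueError("summarize_classes requires a non-empty mutation table")
    coding = mutations[mutations["variant_classification"] != VariantClass.INTRON.value]
    if len(coding) == 0:
        warnings.warn("all mutations are intronic; class summary is empty")
        return pd.DataFrame(columns=["classification", "count", "percent"])
    counts = coding["variant_classification"].value_counts()
    out = pd.DataFrame(
        {
            "classification": counts.index,
            "count": counts.to_numpy(),
            "percent": (100.0 * counts / counts.sum()).round(2).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def read_gene_annotations(path) -> pd.DataFrame:
    """Read a per-gene annotation TSV.

    Expects columns ``gene``, ``cds_length``, ``gc_fraction``; optional
    ``replication_time`` and ``is_flags``.  Duplicate gene symbols keep the
    longest CDS; non-positive CDS rows are dropped.  Both events are logged.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "cds_length", "gc_fraction") if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table {path} missing column(s): {', '.join(missing)}")
    bad = df["cds_length"] <= 0
    if bad.any():
        log.warning("dropping %d annotation row(s) with non-positive CDS length", int(bad.sum()))
        df = df[~bad]
    dup = df.duplicated("gene", keep=False)
    if dup.any():
        log.warning("collapsing %d duplicate gene annotation row(s); keeping longest CDS", int(dup.sum()))
        df = df.sort_values("cds_length").drop_duplicates("gene", keep="last")
    if "replication_time" not in df.columns:
        df = df.assign(replication_time=pd.NA)
    if "is_flags" not in df.columns:
        df = df.assign(is_flags=False)
    df["is_flags"] = df["is_flags"].astype(bool)
    return df.sort_values("gene").reset_index(drop=True)[
        ["gene", "cds_length", "gc_fraction", "replication_time", "is_flags"]
    ]


def write_gene_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, tumor_type, msi_status, pole_status)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"metadata table {path} missing column sample_id")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample_id(s) in metadata: {dups}")
    for col, default in (("tumor_type", "NA"), ("msi_status", MsiStatus.UNKNOWN.value), ("pole_status", PoleStatus.UNKNOWN.value)):
        if col not in df.columns:
            df[col] = default
    return df.reset_index(drop=True)


def write_sample_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (raw, non-negative values).

    The first column holds gene symbols and becomes the index.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"expression matrix {path} contains negative values; raw counts/abundances expected")
    return df


def write_expression_matrix(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")
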