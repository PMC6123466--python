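"""Domain records and readers/writers for every on-disk format.

Variant tables travel as a minimal TCGA-dialect MAF (tab-separated); target
regions as BED (0-based half-open on disk, 1-based inclusive in memory);
clinical and survival data as TSVs with headers. All outputs are UTF-8 with
LF line endings and tab separators so regression comparisons are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

VARIANT_TYPES = ("SNV", "INS", "DEL", "DNP")

CONSEQUENCE_CLASSES = (
    "missense", "nonsense", "frameshift", "inframe_indel", "splice_site",
    "splice_region", "silent", "rna", "utr", "intron",
)

#: MAF ``Variant_Classification`` vocabulary -> internal consequence class.
#: Shipped as data so users can extend it for other annotation dialects.
CONSEQUENCE_MAP: dict[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "In_Frame_Del": "inframe_indel",
    "In_Frame_Ins": "inframe_indel",
    "Splice_Site": "splice_site",
    "Splice_Region": "splice_region",
    "Silent": "silent",
    "RNA": "rna",
    "3'UTR": "utr",
    "5'UTR": "utr",
    "Intron": "intron",
}

# Canonical spelling used when writing a MAF back out.
_CLASS_TO_MAF: dict[tuple[str, str], str] = {
    ("missense", "SNV"): "Missense_Mutation",
    ("missense", "DNP"): "Missense_Mutation",
    ("nonsense", "SNV"): "Nonsense_Mutation",
    ("nonsense", "DNP"): "Nonsense_Mutation",
    ("frameshift", "DEL"): "Frame_Shift_Del",
    ("frameshift", "INS"): "Frame_Shift_Ins",
    ("inframe_indel", "DEL"): "In_Frame_Del",
    ("inframe_indel", "INS"): "In_Frame_Ins",
}

_TYPE_TO_MAF = {"SNV": "SNP", "INS": "INS", "DEL": "DEL", "DNP": "DNP"}
_MAF_TO_TYPE = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL",
                "DNP": "DNP"}

MAF_COLUMNS = (
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "Variant_Type",
    "Tumor_Sample_Barcode", "t_ref_count", "t_alt_count", "Protein_Change",
)


@dataclass
class VariantRecord:
    """One called variant in one sample, with read support and annotation.

    Coordinates are 1-based; ref/alt follow VCF conventions with indels
    left-aligned. The VAF is always recomputed from read counts, never read
    from a file.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    consequence_class: str
    var_reads: int
    depth: int
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(f"unknown variant type {self.variant_type!r}")
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"unknown consequence class {self.consequence_class!r}")
        if not 0 <= self.var_reads <= self.depth:
            raise ValidationError(
                f"require 0 <= var_reads <= depth, got "
                f"var_reads={self.var_reads}, depth={self.depth}")

    @property
    def vaf(self) -> float:
        return self.var_reads / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Site key (chrom, pos, ref, alt) used by all panel lookups."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.variant_type in ("INS", "DEL")


@dataclass
class TargetRegion:
    """A targeted interval, 1-based inclusive in memory."""

    chrom: str
    start: int
    end: int
    gene: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


GRADES = (1, 2, 3)
SIZE_CATEGORIES = (1, 2, 3, 4)
SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "Normal", "unknown")
ENDPOINTS = ("BCSS", "RFS", "OS")


@dataclass
class ClinicalRecord:
    """Clinical covariates for one patient."""

    sample_id: str
    age: float
    grade: int
    nodes_positive: int
    tumor_size_category: int
    er_status: bool = True
    pr_status: bool = True
    her2_status: bool = False
    her2_amplified: bool = False
    subtype: str = "unknown"
    cnv_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.grade not in GRADES:
            raise ValidationError(f"grade must be one of {GRADES}, got {self.grade}")
        if self.tumor_size_category not in SIZE_CATEGORIES:
            raise ValidationError(
                f"tumor size category must be one of {SIZE_CATEGORIES}, "
                f"got {self.tumor_size_category}")
        if self.nodes_positive < 0:
            raise ValidationError("nodes_positive must be >= 0")
        if self.subtype not in SUBTYPES:
            raise ValidationError(f"unknown subtype {self.subtype!r}")


@dataclass
class SurvivalRecord:
    """One survival observation for one patient and endpoint."""

    sample_id: str
    endpoint: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if not (self.time > 0 and self.time < float("inf")):
            raise ValidationError(
                f"time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def read_maf(path: str | Path) -> list[VariantRecord]:
    """Parse a TCGA-dialect MAF into validated variant records.

    Every row is parsed or rejected with its (1-based, header-exclusive) row
    number; read counts are coerced to integers and the VAF is computed from
    them, never trusted from the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in MAF_COLUMNS if c not in df.columns
               and c != "Protein_Change"]
    if missing:
        raise FormatError(f"{path}: missing mandatory MAF column(s): "
                          + ", ".join(missing))
    has_pc = "Protein_Change" in df.columns
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            vtype = _MAF_TO_TYPE.get(str(row["Variant_Type"]))
            if vtype is None:
                raise ValidationError(
                    f"unknown Variant_Type {row['Variant_Type']!r}")
            cls = CONSEQUENCE_MAP.get(str(row["Variant_Classification"]))
            if cls is None:
                raise ValidationError(
                    f"unknown Variant_Classification "
                    f"{row['Variant_Classification']!r}")
            ref_count = int(row["t_ref_count"])
            alt_count = int(row["t_alt_count"])
            pc = row["Protein_Change"] if has_pc else None
            if pc is not None and (pd.isna(pc) or pc == ""):
                pc = None
            records.append(VariantRecord(
                sample_id=str(row["Tumor_Sample_Barcode"]),
                gene=str(row["Hugo_Symbol"]),
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=str(row["Reference_Allele"]),
                alt=str(row["Tumor_Seq_Allele2"]),
                variant_type=vtype,
                consequence_class=cls,
                var_reads=alt_count,
                depth=ref_count + alt_count,
                protein_change=pc,
            ))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def _classification_for(rec: VariantRecord) -> str:
    special = _CLASS_TO_MAF.get((rec.consequence_class, rec.variant_type))
    if special:
        return special
    return {
        "splice_site": "Splice_Site", "splice_region": "Splice_Region",
        "silent": "Silent", "rna": "RNA", "utr": "3'UTR", "intron": "Intron",
    }.get(rec.consequence_class, "Missense_Mutation")


def write_maf(records: list[VariantRecord], path: str | Path) -> None:
    """Write variant records as a TCGA-dialect MAF (bit-stable output)."""
    rows = [{
        "Hugo_Symbol": r.gene,
        "Chromosome": r.chrom,
        "Start_Position": r.pos,
        "Reference_Allele": r.ref,
        "Tumor_Seq_Allele2": r.alt,
        "Variant_Classification": _classification_for(r),
        "Variant_Type": _TYPE_TO_MAF[r.variant_type],
        "Tumor_Sample_Barcode": r.sample_id,
        "t_ref_count": r.depth - r.var_reads,
        "t_alt_count": r.var_reads,
        "Protein_Change": r.protein_change or "",
    } for r in records]
    df = pd.DataFrame(rows, columns=list(MAF_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[TargetRegion]:
    """Read BED target regions, converting to 1-based inclusive coordinates."""
    regions: list[TargetRegion] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i}: expected >= 3 BED columns")
        chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
        gene = parts[3] if len(parts) > 3 else ""
        regions.append(TargetRegion(chrom=chrom, start=start0 + 1,
                                    end=end0, gene=gene))
    return regions


def write_bed(regions: list[TargetRegion], path: str | Path) -> None:
    lines = [f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}" for r in regions]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Clinical / survival TSVs
# ---------------------------------------------------------------------------

_BOOL = {"True": True, "False": False, "1": True, "0": False,
         "true": True, "false": False}


def _as_bool(value, column: str, row: int) -> bool:
    v = _BOOL.get(str(value))
    if v is None:
        raise ValidationError(f"row {row}: column {column}: "
                              f"cannot parse boolean from {value!r}")
    return v


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical covariate TSV; subtype 'unknown' is allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["sample_id", "age", "grade", "nodes_positive",
              "tumor_size_category"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical column(s): "
                          + ", ".join(missing))
    cnv_cols = [c for c in df.columns if c.startswith("cnv_")]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            kwargs = dict(
                sample_id=str(row["sample_id"]),
                age=float(row["age"]),
                grade=int(row["grade"]),
                nodes_positive=int(row["nodes_positive"]),
                tumor_size_category=int(row["tumor_size_category"]),
            )
            for col in ("er_status", "pr_status", "her2_status",
                        "her2_amplified"):
                if col in row and not pd.isna(row[col]):
                    kwargs[col] = _as_bool(row[col], col, i)
            if "subtype" in row and not pd.isna(row["subtype"]):
                kwargs["subtype"] = str(row["subtype"])
            kwargs["cnv_flags"] = {
                c[len("cnv_"):]: _as_bool(row[c], c, i)
                for c in cnv_cols if not pd.isna(row[c])}
            records.append(ClinicalRecord(**kwargs))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    cnv_genes = sorted({g for r in records for g in r.cnv_flags})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id, "age": r.age, "grade": r.grade,
            "nodes_positive": r.nodes_positive,
            "tumor_size_category": r.tumor_size_category,
            "er_status": r.er_status, "pr_status": r.pr_status,
            "her2_status": r.her2_status, "her2_amplified": r.her2_amplified,
            "subtype": r.subtype,
        }
        for g in cnv_genes:
            row[f"cnv_{g}"] = r.cnv_flags.get(g, False)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read the survival TSV; duplicate (sample, endpoint) pairs are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["sample_id", "endpoint", "time", "event"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing survival column(s): "
                          + ", ".join(missing))
    records, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            rec = SurvivalRecord(
                sample_id=str(row["sample_id"]),
                endpoint=str(row["endpoint"]),
                time=float(row["time"]),
                event=int(row["event"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        key = (rec.sample_id, rec.endpoint)
        if key in seen:
            raise ValidationError(
                f"{path}: row {i}: duplicate (sample_id, endpoint) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    rows = [{"sample_id": r.sample_id, "endpoint": r.endpoint,
             "time": r.time, "event": r.event} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
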