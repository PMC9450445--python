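"""Domain types, packaged reference tables, and cohort file I/O.

The pipeline operates on three in-memory containers: a list of
:class:`VariantRecord` (annotated biallelic SNVs), a :class:`GenotypeMatrix`
(samples x variants allele dosages), and a list of :class:`PhenotypeRecord`
(per-patient cohort label and quantitative phenotypes).  Variants arrive
either as an annotated VCF (INFO keys ``GENE``, ``FUNC``, ``AF_1KG``,
``AF_1KG_EAS``, ``SIFT``, ``PPH2``, ``HGVSC``, ``HGVSP``) or as an
equivalent tab-separated table; both carry per-sample genotypes.

Published summary tables from the source study (per-sample SNP counts,
the 40 recurrent candidate variants, per-gene carrier counts in the
validation and control cohorts, and phenotype summary statistics) are
packaged as plain-text fixtures and exposed through :func:`fixtures`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FUNC_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "COHORT_LABELS",
    "MISSING_DOSAGE",
    "ParseError",
    "AnnotationError",
    "ValidationError",
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeRecord",
    "SummaryStat",
    "CandidateRow",
    "CascadeReport",
    "PipelineConfig",
    "chrom_sort_key",
    "read_variants",
    "read_phenotypes",
    "read_candidate_table",
    "cohort_from_candidates",
    "write_candidates",
    "write_variants_tsv",
    "write_vcf",
    "write_phenotypes",
    "fixtures",
]

# ---------------------------------------------------------------------------
# Constants and errors

FUNC_CLASSES = frozenset(
    {
        "missense",
        "stopgain",
        "stoploss",
        "splicing",
        "synonymous",
        "intronic",
        "intergenic",
        "other",
    }
)

#: Functional classes counted as nonsynonymous (protein-altering or
#: splice-disrupting) by the discovery-stage filter.
NONSYNONYMOUS_CLASSES = frozenset({"missense", "stopgain", "stoploss", "splicing"})

COHORT_LABELS = frozenset({"wes", "validation", "control"})

#: Sentinel for an uncalled genotype in the dosage matrix.
MISSING_DOSAGE = -1

_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """A file does not conform to its declared format."""


class AnnotationError(ValueError):
    """A variant record lacks a required annotation."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Order chromosomes 1..22, X, Y, MT, then others lexicographically."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name.upper() in special:
        return (special[name.upper()], "")
    return (26, name)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class VariantRecord:
    """One annotated biallelic SNV.

    Missing population MAFs are resolved to 0.0 at read time (absence from
    the reference panel is read as rarity); missing in-silico scores stay
    ``None`` and are treated as non-implicated downstream.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    func_class: str
    dbsnp_id: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    maf_1kg: float = 0.0
    maf_1kg_eas: float = 0.0
    sift: float | None = None
    polyphen: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValidationError(
                f"SNVs only: alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValidationError(f"unknown functional class {self.func_class!r}")
        for name in ("maf_1kg", "maf_1kg_eas", "sift", "polyphen"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name}={val} outside [0, 1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def sort_key(self) -> tuple[tuple[int, str], int]:
        return (chrom_sort_key(self.chrom), self.pos)


class GenotypeMatrix:
    """Samples x variants allele-dosage matrix (0/1/2, -1 for uncalled).

    Optionally carries the gene symbol of each variant column so gene-level
    carrier queries need no side table.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        variant_keys: Sequence[str],
        dosage: np.ndarray,
        variant_genes: Sequence[str] | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.variant_keys = list(variant_keys)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        self.variant_genes = list(variant_genes) if variant_genes is not None else None
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.variant_keys)) != len(self.variant_keys):
            raise ValidationError("duplicate variant keys")
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        bad = ~np.isin(self.dosage, (MISSING_DOSAGE, 0, 1, 2))
        if bad.any():
            raise ValidationError("dosage values must be 0, 1, 2 or missing (-1)")
        if self.variant_genes is not None and len(self.variant_genes) != len(self.variant_keys):
            raise ValidationError("variant_genes length mismatch")
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(self.variant_keys)}

    @classmethod
    def empty(cls) -> "GenotypeMatrix":
        return cls([], [], np.zeros((0, 0), dtype=np.int8), [])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def sample_row(self, sample_id: str) -> np.ndarray:
        try:
            return self.dosage[self._sample_index[sample_id]]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def dosages(self, variant_key: str) -> np.ndarray:
        """Dosage column for one variant, ordered as ``sample_ids``."""
        try:
            return self.dosage[:, self._variant_index[variant_key]]
        except KeyError:
            raise KeyError(f"unknown variant key {variant_key!r}") from None

    def keys_for_gene(self, gene: str) -> list[str]:
        if self.variant_genes is None:
            raise ValidationError("matrix carries no gene assignment for its variants")
        return [k for k, g in zip(self.variant_keys, self.variant_genes) if g == gene]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variant_keys == other.variant_keys
            and self.variant_genes == other.variant_genes
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-patient cohort label, demographics and quantitative phenotypes."""

    sample_id: str
    cohort: str
    sex: str | None = None
    age: float | None = None
    lvef: float | None = None
    calc_volume: float | None = None
    hypertension: bool | None = None
    diabetes: bool | None = None
    hyperlipemia: bool | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_LABELS:
            raise ValidationError(f"unknown cohort label {self.cohort!r}")
        if self.sex is not None and self.sex not in {"male", "female"}:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.lvef is not None and not 0.0 < self.lvef <= 100.0:
            raise ValidationError(f"LVEF {self.lvef} outside (0, 100]")
        if self.calc_volume is not None and self.calc_volume < 0:
            raise ValidationError(f"negative calcification volume {self.calc_volume}")


@dataclass(frozen=True)
class SummaryStat:
    """Group size, mean and standard deviation (the mean +/- SD convention)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError(f"negative SD {self.sd}")


@dataclass(frozen=True)
class CandidateRow:
    """A prioritized variant with its discovery-cohort carrier count."""

    variant: VariantRecord
    case_count: int

    def __post_init__(self) -> None:
        if self.case_count < 0:
            raise ValidationError("negative case count")


@dataclass(frozen=True)
class CascadeReport:
    """Ordered filter-stage names with surviving-variant counts."""

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.stages]
        if any(c < 0 for c in counts):
            raise ValidationError("negative stage count")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValidationError("stage counts must be non-increasing")

    def to_dict(self) -> dict:
        return {"stages": [{"name": n, "count": c} for n, c in self.stages]}

    def count(self, stage_name: str) -> int:
        for name, c in self.stages:
            if name == stage_name:
                return c
        raise KeyError(stage_name)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and policies of the prioritization and association stages.

    Defaults reproduce the zero-configuration analysis: both population MAFs
    strictly below 0.05, SIFT strictly below 0.05, PolyPhen class D
    (probably damaging, score >= 0.957) or P (possibly damaging,
    0.453-0.956) counted as implicated, recurrence at >= 2 carrier
    patients, and automatic chi-square/Fisher selection with the minimum
    expected count rule at 5.
    """

    maf_max: float = 0.05
    sift_max: float = 0.05
    polyphen_benign_max: float = 0.452
    polyphen_possible_max: float = 0.956
    polyphen_damaging_classes: frozenset[str] = frozenset({"D", "P"})
    min_case_count: int = 2
    gene_allowlist: frozenset[str] | None = None
    test_policy: str = "auto"
    expected_count_min: float = 5.0
    alpha: float = 0.05
    adjust_bh: bool = False
    continuity_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_max <= 1.0:
            raise ValidationError(f"maf_max {self.maf_max} outside (0, 1]")
        if not 0.0 < self.sift_max <= 1.0:
            raise ValidationError(f"sift_max {self.sift_max} outside (0, 1]")
        if not 0.0 <= self.polyphen_benign_max < self.polyphen_possible_max <= 1.0:
            raise ValidationError("PolyPhen bin boundaries must be ordered within [0, 1]")
        if self.min_case_count < 1:
            raise ValidationError("min_case_count must be >= 1")
        if not self.polyphen_damaging_classes <= {"D", "P"}:
            raise ValidationError("damaging classes must be a subset of {D, P}")
        if self.test_policy not in {"auto", "chi2", "fisher"}:
            raise ValidationError(f"unknown test policy {self.test_policy!r}")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Variant I/O

_VARIANT_COLUMNS = {
    "chrom": str,
    "pos": int,
    "ref": str,
    "alt": str,
    "gene": str,
    "dbsnp_id": str,
    "cdna_change": str,
    "protein_change": str,
    "func_class": str,
    "maf_1kg": float,
    "maf_1kg_eas": float,
    "sift": float,
    "polyphen": float,
}

#: Metadata columns that may appear in a variant table without being
#: interpreted as per-sample genotype columns.
_NON_SAMPLE_EXTRAS = {"cases"}

_REQUIRED_TSV = {"chrom", "pos", "ref", "alt", "gene", "func_class"}


def read_variants(
    path: str | Path, format: str = "tsv"
) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read annotated SNVs plus per-sample dosages from VCF or TSV.

    Multiallelic VCF records are split into one entry per alternate allele;
    the dosage of each entry counts copies of that alternate only.  A
    candidate table written by :func:`write_candidates` (which has no sample
    columns) reads back as records plus an empty matrix.
    """
    path = Path(path)
    if format == "tsv":
        return _read_variants_tsv(path)
    if format == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant format {format!r}")


def _parse_cell(raw: str, kind, column: str, line_no: int):
    raw = raw.strip()
    if raw in ("", "."):
        return None
    try:
        return kind(raw)
    except ValueError:
        raise ParseError(f"line {line_no}: cannot parse {column}={raw!r}") from None


def _read_variants_tsv(path: Path) -> tuple[list[VariantRecord], GenotypeMatrix]:
    with open(path, newline="", encoding="utf-8") as fh:
        header: list[str] | None = None
        header_line = 0
        rows: list[tuple[int, list[str]]] = []
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = [h.strip() for h in parts]
                header_line = line_no
                continue
            if len(parts) != len(header):
                raise ParseError(
                    f"line {line_no}: expected {len(header)} fields, got {len(parts)}"
                )
            rows.append((line_no, parts))
    if header is None:
        raise ParseError("line 1: empty file, no header row")

    lower = [h.lower() for h in header]
    missing = _REQUIRED_TSV - set(lower)
    if missing:
        raise AnnotationError(
            f"line {header_line}: missing required column(s) {sorted(missing)}"
        )
    col_of = {name: lower.index(name) for name in _VARIANT_COLUMNS if name in lower}
    sample_cols = [
        (header[i], i)
        for i, name in enumerate(lower)
        if name not in _VARIANT_COLUMNS and name not in _NON_SAMPLE_EXTRAS
    ]

    records: list[VariantRecord] = []
    genes: list[str] = []
    dosage_rows: list[list[int]] = []
    for line_no, parts in rows:
        kwargs: dict = {}
        for name, kind in _VARIANT_COLUMNS.items():
            if name not in col_of:
                continue
            val = _parse_cell(parts[col_of[name]], kind, name, line_no)
            if val is None:
                if name in _REQUIRED_TSV:
                    raise AnnotationError(f"line {line_no}: missing {name}")
                val = _MISSING_DEFAULTS.get(name)
            kwargs[name] = val
        for text_field in ("dbsnp_id", "cdna_change", "protein_change"):
            if kwargs.get(text_field) is None:
                kwargs[text_field] = ""
        try:
            rec = VariantRecord(**kwargs)
        except ValidationError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        records.append(rec)
        genes.append(rec.gene)
        row = []
        for col_name, i in sample_cols:
            cell = parts[i].strip()
            if cell in ("", "."):
                row.append(MISSING_DOSAGE)
            elif cell in ("0", "1", "2"):
                row.append(int(cell))
            else:
                raise ParseError(f"line {line_no}: bad dosage {cell!r} for sample {col_name}")
        dosage_rows.append(row)

    sample_ids = [name for name, _ in sample_cols]
    if dosage_rows and sample_ids:
        dosage = np.array(dosage_rows, dtype=np.int8).T  # rows were per-variant
    else:
        dosage = np.zeros((len(sample_ids), len(records)), dtype=np.int8)
    matrix = GenotypeMatrix(sample_ids, [r.key for r in records], dosage, genes)
    return records, matrix


#: Defaults applied when an optional annotation cell is missing.
_MISSING_DEFAULTS = {"maf_1kg": 0.0, "maf_1kg_eas": 0.0, "sift": None, "polyphen": None}


def _info_scalar(info_val, alt_index: int):
    """Pick the per-alternate entry from a possibly tuple-valued INFO field."""
    if isinstance(info_val, (tuple, list)):
        info_val = info_val[alt_index] if alt_index < len(info_val) else None
    if isinstance(info_val, bytes):
        info_val = info_val.decode()
    if isinstance(info_val, str) and "," in info_val:
        # Number=A string fields come back comma-joined
        parts = info_val.split(",")
        info_val = parts[alt_index] if alt_index < len(parts) else None
    return info_val


def _read_variants_vcf(path: Path) -> tuple[list[VariantRecord], GenotypeMatrix]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception on malformed input
        raise ParseError(f"cannot open VCF {path}: {exc}") from None

    sample_ids = list(vcf.samples)
    records: list[VariantRecord] = []
    genes: list[str] = []
    dosage_cols: list[np.ndarray] = []
    for rec in vcf:
        where = f"{rec.CHROM}:{rec.POS}"
        genotypes = rec.genotypes if sample_ids else []
        for alt_index, alt in enumerate(rec.ALT):
            if len(rec.REF) != 1 or len(alt) != 1:
                raise ParseError(f"{where}: not an SNV ({rec.REF}>{alt})")
            info = {}
            for key, kind in (
                ("GENE", str),
                ("FUNC", str),
                ("AF_1KG", float),
                ("AF_1KG_EAS", float),
                ("SIFT", float),
                ("PPH2", float),
                ("HGVSC", str),
                ("HGVSP", str),
            ):
                raw = _info_scalar(rec.INFO.get(key), alt_index)
                if raw is None:
                    info[key] = None
                elif kind is float:
                    # INFO floats come back as float32; renormalize to the
                    # 6-significant-digit precision the writers emit
                    info[key] = float(f"{float(raw):.6g}")
                else:
                    info[key] = kind(raw)
            for required in ("GENE", "FUNC"):
                if info[required] is None:
                    raise AnnotationError(f"{where}: missing INFO key {required}")
            records.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=info["GENE"],
                    func_class=info["FUNC"],
                    dbsnp_id=rec.ID or "",
                    cdna_change=info["HGVSC"] or "",
                    protein_change=info["HGVSP"] or "",
                    maf_1kg=info["AF_1KG"] if info["AF_1KG"] is not None else 0.0,
                    maf_1kg_eas=info["AF_1KG_EAS"] if info["AF_1KG_EAS"] is not None else 0.0,
                    sift=info["SIFT"],
                    polyphen=info["PPH2"],
                )
            )
            genes.append(info["GENE"])
            allele = alt_index + 1
            col = np.empty(len(sample_ids), dtype=np.int8)
            for s, gt in enumerate(genotypes):
                alleles = [a for a in gt[:-1]]  # last element is phasing flag
                if any(a < 0 for a in alleles):
                    col[s] = MISSING_DOSAGE
                else:
                    col[s] = sum(1 for a in alleles if a == allele)
            dosage_cols.append(col)

    if dosage_cols:
        dosage = np.stack(dosage_cols, axis=1)
    else:
        dosage = np.zeros((len(sample_ids), 0), dtype=np.int8)
    matrix = GenotypeMatrix(sample_ids, [r.key for r in records], dosage, genes)
    return records, matrix


def _fmt(value, digits: int = 6) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        if math.isnan(value):
            return "."
        return f"{value:.{digits}g}"
    return str(value)


CANDIDATE_HEADER = [
    "Chrom",
    "Pos",
    "Ref",
    "Alt",
    "Gene",
    "dbSNP_ID",
    "cDNA_change",
    "Protein_change",
    "Func_class",
    "Cases",
    "MAF_1KG",
    "MAF_1KG_EAS",
    "SIFT",
    "PolyPhen",
]


def write_candidates(rows: Iterable[CandidateRow], path: str | Path) -> None:
    """Write a candidate table sorted by chromosomal sequence (chrom, pos)."""
    ordered = sorted(rows, key=lambda r: r.variant.sort_key)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(CANDIDATE_HEADER) + "\n")
        for row in ordered:
            v = row.variant
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene,
                        v.dbsnp_id or ".",
                        v.cdna_change or ".",
                        v.protein_change or ".",
                        v.func_class,
                        str(row.case_count),
                        _fmt(v.maf_1kg),
                        _fmt(v.maf_1kg_eas),
                        _fmt(v.sift),
                        _fmt(v.polyphen),
                    ]
                )
                + "\n"
            )


def write_variants_tsv(
    variants: Sequence[VariantRecord], g: GenotypeMatrix, path: str | Path
) -> None:
    """Write variants plus per-sample dosage columns as a TSV cohort file."""
    cols = list(_VARIANT_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(cols + list(g.sample_ids)) + "\n")
        for v in variants:
            dosages = g.dosages(v.key)
            cells = [
                v.chrom,
                str(v.pos),
                v.ref,
                v.alt,
                v.gene,
                v.dbsnp_id or ".",
                v.cdna_change or ".",
                v.protein_change or ".",
                v.func_class,
                _fmt(v.maf_1kg),
                _fmt(v.maf_1kg_eas),
                _fmt(v.sift),
                _fmt(v.polyphen),
            ]
            cells += ["." if d == MISSING_DOSAGE else str(int(d)) for d in dosages]
            fh.write("\t".join(cells) + "\n")


def read_candidate_table(path: str | Path) -> list[CandidateRow]:
    """Read a candidate table written by :func:`write_candidates`."""
    records, _ = read_variants(path, format="tsv")
    cases: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        header = None
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = [h.strip().lower() for h in parts]
                if "cases" not in header:
                    raise AnnotationError(f"line {line_no}: missing Cases column")
                idx = header.index("cases")
                continue
            cases.append(int(parts[idx]))
    return [CandidateRow(variant=r, case_count=c) for r, c in zip(records, cases)]


def cohort_from_candidates(
    rows: Sequence[CandidateRow], n_samples: int | None = None
) -> tuple[list[VariantRecord], "GenotypeMatrix"]:
    """Synthesize a cohort whose carrier counts equal the candidate counts.

    Each variant gets heterozygous carriers in the first ``case_count``
    samples — a deterministic arrangement sufficient for re-running the
    cascade on a published candidate table, which records carrier counts
    but not carrier identities.
    """
    if n_samples is None:
        n_samples = max((r.case_count for r in rows), default=1)
    records = [r.variant for r in rows]
    dosage = np.zeros((n_samples, len(records)), dtype=np.int8)
    for j, row in enumerate(rows):
        if row.case_count > n_samples:
            raise ValidationError(
                f"{row.variant.key}: case_count {row.case_count} exceeds cohort size {n_samples}"
            )
        dosage[: row.case_count, j] = 1
    matrix = GenotypeMatrix(
        [f"S{i + 1:03d}" for i in range(n_samples)],
        [v.key for v in records],
        dosage,
        [v.gene for v in records],
    )
    return records, matrix


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">
##INFO=<ID=FUNC,Number=A,Type=String,Description="Functional class">
##INFO=<ID=AF_1KG,Number=A,Type=Float,Description="1000 Genomes global MAF">
##INFO=<ID=AF_1KG_EAS,Number=A,Type=Float,Description="1000 Genomes East Asian MAF">
##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT tolerance score">
##INFO=<ID=PPH2,Number=A,Type=Float,Description="PolyPhen-2 probability">
##INFO=<ID=HGVSC,Number=A,Type=String,Description="HGVS cDNA change">
##INFO=<ID=HGVSP,Number=A,Type=String,Description="HGVS protein change">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    variants: Sequence[VariantRecord], g: GenotypeMatrix, path: str | Path
) -> None:
    """Write the cohort as an uncompressed VCF v4.2 with GT genotypes."""
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_VCF_HEADER)
        for c in sorted(chroms, key=chrom_sort_key):
            fh.write(f"##contig=<ID={c}>\n")
        columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if g.sample_ids:
            columns += ["FORMAT"] + list(g.sample_ids)
        fh.write("\t".join(columns) + "\n")
        for v in sorted(variants, key=lambda v: v.sort_key):
            info_parts = [f"GENE={v.gene}", f"FUNC={v.func_class}"]
            info_parts.append(f"AF_1KG={_fmt(v.maf_1kg)}")
            info_parts.append(f"AF_1KG_EAS={_fmt(v.maf_1kg_eas)}")
            if v.sift is not None:
                info_parts.append(f"SIFT={_fmt(v.sift)}")
            if v.polyphen is not None:
                info_parts.append(f"PPH2={_fmt(v.polyphen)}")
            if v.cdna_change:
                info_parts.append(f"HGVSC={v.cdna_change}")
            if v.protein_change:
                info_parts.append(f"HGVSP={v.protein_change}")
            row = [
                v.chrom,
                str(v.pos),
                v.dbsnp_id or ".",
                v.ref,
                v.alt,
                ".",
                "PASS",
                ";".join(info_parts),
            ]
            if g.sample_ids:
                gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}
                row += ["GT"] + [gt_map[int(d)] for d in g.dosages(v.key)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Phenotype I/O

_PHENO_FIELDS = [f.name for f in fields(PhenotypeRecord)]
_PHENO_BOOLS = {"hypertension", "diabetes", "hyperlipemia"}
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read the per-patient phenotype table ("." marks a missing value)."""
    records: list[PhenotypeRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError("line 1: empty phenotype file")
        unknown = set(reader.fieldnames) - set(_PHENO_FIELDS)
        if unknown:
            raise ParseError(f"line 1: unknown phenotype column(s) {sorted(unknown)}")
        if "sample_id" not in reader.fieldnames or "cohort" not in reader.fieldnames:
            raise ParseError("line 1: phenotype table needs sample_id and cohort columns")
        for line_no, row in enumerate(reader, start=2):
            kwargs: dict = {}
            for name in _PHENO_FIELDS:
                raw = (row.get(name) or "").strip()
                if raw in ("", "."):
                    kwargs[name] = None
                    continue
                if name in ("sample_id", "cohort", "sex"):
                    kwargs[name] = raw
                elif name in _PHENO_BOOLS:
                    low = raw.lower()
                    if low in _TRUE:
                        kwargs[name] = True
                    elif low in _FALSE:
                        kwargs[name] = False
                    else:
                        raise ParseError(f"line {line_no}: bad boolean {name}={raw!r}")
                else:
                    try:
                        kwargs[name] = float(raw)
                    except ValueError:
                        kwargs[name] = None  # unparseable numeric cell -> missing
            if kwargs["sample_id"] is None:
                raise ParseError(f"line {line_no}: missing sample_id")
            if kwargs["sample_id"] in seen:
                raise ValidationError(f"line {line_no}: duplicate sample_id {kwargs['sample_id']!r}")
            seen.add(kwargs["sample_id"])
            try:
                records.append(PhenotypeRecord(**kwargs))
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from None
    return records


def write_phenotypes(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_PHENO_FIELDS) + "\n")
        for r in records:
            cells = []
            for name in _PHENO_FIELDS:
                val = getattr(r, name)
                if val is None:
                    cells.append(".")
                elif isinstance(val, bool):
                    cells.append("1" if val else "0")
                elif isinstance(val, float):
                    cells.append(_fmt(val, digits=10))
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Packaged reference tables


@dataclass(frozen=True)
class Table4Row:
    gene: str
    validation_carriers: int
    control_carriers: int


@dataclass(frozen=True)
class Fixtures:
    """Packaged copies of the study's printed summary tables.

    ``table2``: per-sample SNP counts by functional category for the 20
    discovery-cohort exomes.  ``table3``: the 40 recurrent candidate
    variants across 36 genes with discovery carrier counts and two
    population MAFs (genomic positions and in-silico scores are synthetic
    placeholders consistent with the published filters — the printed table
    omits them).  ``table4``: per-gene carrier counts in the validation
    (n=137) and control (n=130) cohorts.  ``table5``: phenotype summary
    statistics (mean +/- SD) stratified by mutation-carrier status.
    """

    table2: pd.DataFrame
    table3: tuple[CandidateRow, ...]
    table4: tuple[Table4Row, ...]
    table5: dict[tuple[str, str], SummaryStat]
    n_validation: int = 137
    n_control: int = 130
    n_discovery: int = 20

    def table4_counts(self, gene: str) -> tuple[int, int]:
        for row in self.table4:
            if row.gene == gene:
                return (row.validation_carriers, row.control_carriers)
        raise KeyError(gene)


_FIXTURES_CACHE: Fixtures | None = None


def _data_path(name: str):
    return resources.files("bavscreen.data").joinpath(name)


def fixtures() -> Fixtures:
    """Load the packaged summary tables (cached)."""
    global _FIXTURES_CACHE
    if _FIXTURES_CACHE is not None:
        return _FIXTURES_CACHE

    with resources.as_file(_data_path("table2_per_sample_counts.tsv")) as p:
        table2 = pd.read_csv(p, sep="\t").set_index("sample_id")

    with resources.as_file(_data_path("table3_recurrent_variants.tsv")) as p:
        records, _ = read_variants(p, format="tsv")
        cases = pd.read_csv(p, sep="\t", comment="#")["cases"].tolist()
    table3 = tuple(
        CandidateRow(variant=rec, case_count=int(c)) for rec, c in zip(records, cases)
    )

    with resources.as_file(_data_path("table4_carrier_counts.tsv")) as p:
        t4 = pd.read_csv(p, sep="\t")
    table4 = tuple(
        Table4Row(r.gene, int(r.validation_carriers), int(r.control_carriers))
        for r in t4.itertuples()
    )

    with resources.as_file(_data_path("table5_phenotype_summary.tsv")) as p:
        t5 = pd.read_csv(p, sep="\t")
    table5 = {
        (r.variable, r.group): SummaryStat(n=int(r.n), mean=float(r.mean), sd=float(r.sd))
        for r in t5.itertuples()
    }

    _FIXTURES_CACHE = Fixtures(table2=table2, table3=table3, table4=table4, table5=table5)
    return _FIXTURES_CACHE
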