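"""High-confidence missense SNV selection from MAF-dialect somatic variant tables.

The filters retain, per tumor sample, single-nucleotide missense variants
with a valid transcript and protein annotation, adequate read support
(alternate reads and VAF), and no appreciable population allele frequency —
the standard precautions against sequencing artifacts and mislabelled
germline polymorphisms before any cross-patient recurrence analysis.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES = frozenset("ACGT")

#: Exact column names of the GDC MAF dialect consumed here.
REQUIRED_MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Transcript_ID",
    "HGVSp_Short",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Type",
    "Variant_Classification",
    "Mutation_Status",
    "t_depth",
    "t_ref_count",
    "t_alt_count",
)
OPTIONAL_MAF_COLUMNS = ("max_pop_af",)

_HGVSP_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class ProteinChange:
    """A single amino-acid exchange, e.g. PIK3CA:H1047R."""

    gene_symbol: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"amino-acid position must be >= 1, got {self.position}")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{aa!r} is not a standard amino acid")
        if self.ref_aa == self.alt_aa:
            raise ValueError("reference and alternate residues must differ")

    @property
    def token(self) -> str:
        """Compact gene:refPOSalt token, e.g. ``GLRA3:S274L``."""
        return f"{self.gene_symbol}:{self.ref_aa}{self.position}{self.alt_aa}"

    @classmethod
    def from_token(cls, token: str) -> "ProteinChange":
        gene, _, rest = token.partition(":")
        m = re.fullmatch(r"([A-Z])(\d+)([A-Z])", rest)
        if not gene or m is None:
            raise ValueError(f"malformed protein-change token: {token!r}")
        return cls(gene, int(m.group(2)), m.group(1), m.group(3))

    def hgvsp_short(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class SomaticVariantRecord:
    """One MAF row: a somatic variant call in one tumor sample."""

    sample_id: str
    study_id: str
    gene_symbol: str
    transcript_id: str
    hgvsp_short: str
    chromosome: str
    position: int
    ref_base: str
    alt_base: str
    variant_type: str
    variant_classification: str
    mutation_status: str
    t_depth: int
    t_ref_count: int
    t_alt_count: int
    max_population_af: Optional[float] = None

    @property
    def vaf(self) -> float:
        if self.t_depth == 0:
            raise ZeroDivisionError("VAF undefined at zero depth")
        return self.t_alt_count / self.t_depth


@dataclass
class FilterConfig:
    """Thresholds for the high-confidence missense SNV selection."""

    min_alt_reads: int = 5
    min_vaf: float = 0.10
    max_pop_af: float = 0.01
    required_classification: str = "Missense_Mutation"
    required_type: str = "SNP"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af must lie in [0, 1]")


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_out: int
    n_rejected: int
    reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_in == self.n_out + self.n_rejected, self.name


@dataclass
class FilterReport:
    """Ordered per-stage bookkeeping: in = out + rejected at every stage."""

    stages: list[FilterStage] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int, reasons: Counter | dict | None = None) -> None:
        reasons = dict(reasons or {})
        self.stages.append(FilterStage(name, n_in, n_out, n_in - n_out, reasons))

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps([asdict(s) for s in self.stages], indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def parse_hgvsp(text: str) -> Optional[ProteinChange]:
    """Parse a short-form protein annotation like ``p.H1047R``.

    Only single-residue missense exchanges parse; frameshifts, stop gains,
    synonymous changes, and anything else return ``None`` (a rejection,
    not an error). The gene symbol is left empty — callers attach it.
    """
    if not isinstance(text, str):
        return None
    m = _HGVSP_RE.match(text.strip())
    if m is None:
        return None
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS or ref == alt or pos < 1:
        return None
    return ProteinChange("", pos, ref, alt)


def _row_rejection_reason(row: pd.Series) -> Optional[str]:
    """Reason a raw MAF row cannot become a record, or None if it can."""
    if _is_blank(row["Transcript_ID"]):
        return "no valid ENSEMBL transcript ID"
    for col in ("Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome",
                "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Type",
                "Variant_Classification", "Mutation_Status"):
        if _is_blank(row[col]):
            return f"missing {col}"
    for col in ("Start_Position", "t_depth", "t_ref_count", "t_alt_count"):
        val = row[col]
        if _is_blank(val):
            return f"missing {col}"
        try:
            iv = int(float(val))
        except (TypeError, ValueError):
            return f"non-numeric {col}"
        if iv < 0:
            return f"negative {col}"
    if int(float(row["Start_Position"])) < 1:
        return "position < 1"
    return None


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def read_maf(path: str | Path, study_id: str,
             report: FilterReport | None = None) -> tuple[list[SomaticVariantRecord], FilterReport]:
    """Read a tab-delimited MAF file into records.

    Rows with a missing required field are rejected (with a counted
    reason); a missing required *column* is a hard error; an empty file
    yields an empty list. ``#`` lines are comments. Column order is
    irrelevant.
    """
    report = report if report is not None else FilterReport()
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        report.add(f"read_maf[{study_id}]", 0, 0)
        return [], report
    df = df.replace("", None)
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file {path} lacks required column(s): {', '.join(missing)}")
    has_af = "max_pop_af" in df.columns

    records: list[SomaticVariantRecord] = []
    reasons: Counter[str] = Counter()
    for _, row in df.iterrows():
        reason = _row_rejection_reason(row)
        if reason is not None:
            reasons[reason] += 1
            continue
        af = None
        if has_af and not _is_blank(row["max_pop_af"]):
            af = float(row["max_pop_af"])
        records.append(SomaticVariantRecord(
            sample_id=str(row["Tumor_Sample_Barcode"]),
            study_id=study_id,
            gene_symbol=str(row["Hugo_Symbol"]),
            transcript_id=str(row["Transcript_ID"]),
            hgvsp_short="" if _is_blank(row["HGVSp_Short"]) else str(row["HGVSp_Short"]),
            chromosome=str(row["Chromosome"]),
            position=int(float(row["Start_Position"])),
            ref_base=str(row["Reference_Allele"]),
            alt_base=str(row["Tumor_Seq_Allele2"]),
            variant_type=str(row["Variant_Type"]),
            variant_classification=str(row["Variant_Classification"]),
            mutation_status=str(row["Mutation_Status"]),
            t_depth=int(float(row["t_depth"])),
            t_ref_count=int(float(row["t_ref_count"])),
            t_alt_count=int(float(row["t_alt_count"])),
            max_population_af=af,
        ))
    report.add(f"read_maf[{study_id}]", len(df), len(records), reasons)
    return records, report


def validate_consistency(record: SomaticVariantRecord) -> tuple[bool, Optional[str]]:
    """Internal-consistency check of one record.

    Accepts iff mutation status is "Somatic" up to capitalisation, the
    total depth equals ref + alt read counts, and ref/alt alleles are
    each one nucleotide.
    """
    if record.mutation_status.lower() != "somatic":
        return False, "mutation status not somatic"
    if record.t_depth != record.t_ref_count + record.t_alt_count:
        return False, "depth mismatch"
    if len(record.ref_base) != 1 or record.ref_base not in NUCLEOTIDES:
        return False, "not single nucleotide"
    if len(record.alt_base) != 1 or record.alt_base not in NUCLEOTIDES:
        return False, "not single nucleotide"
    return True, None


def apply_consistency_filter(records: Iterable[SomaticVariantRecord],
                             report: FilterReport | None = None) -> list[SomaticVariantRecord]:
    records = list(records)
    reasons: Counter[str] = Counter()
    kept = []
    for r in records:
        ok, reason = validate_consistency(r)
        if ok:
            kept.append(r)
        else:
            reasons[reason] += 1
    if report is not None:
        report.add("consistency", len(records), len(kept), reasons)
    return kept


def select_missense_snv(records: Iterable[SomaticVariantRecord], config: FilterConfig,
                        report: FilterReport | None = None) -> list[SomaticVariantRecord]:
    """Keep single-nucleotide missense variants with a parsable protein change."""
    records = list(records)
    reasons: Counter[str] = Counter()
    kept = []
    for r in records:
        if r.variant_type != config.required_type:
            reasons["not " + config.required_type] += 1
        elif r.variant_classification != config.required_classification:
            reasons["not " + config.required_classification] += 1
        elif not r.transcript_id.strip():
            reasons["no valid ENSEMBL transcript ID"] += 1
        elif parse_hgvsp(r.hgvsp_short) is None:
            reasons["no single-residue missense HGVSp"] += 1
        else:
            kept.append(r)
    if report is not None:
        report.add("missense_snv", len(records), len(kept), reasons)
    return kept


def apply_support_filter(records: Iterable[SomaticVariantRecord], config: FilterConfig,
                         report: FilterReport | None = None) -> list[SomaticVariantRecord]:
    """Require >= min_alt_reads alternate reads and VAF >= min_vaf (both inclusive)."""
    records = list(records)
    reasons: Counter[str] = Counter()
    kept = []
    for r in records:
        if r.t_depth == 0:
            raise ValueError(
                f"zero-depth record reached the support filter ({r.sample_id} "
                f"{r.gene_symbol}): consistency filtering must run first")
        if r.t_alt_count < config.min_alt_reads:
            reasons["insufficient alt reads"] += 1
        elif r.vaf < config.min_vaf:
            reasons["VAF below threshold"] += 1
        else:
            kept.append(r)
    if report is not None:
        report.add("read_support", len(records), len(kept), reasons)
    return kept


def apply_population_filter(records: Iterable[SomaticVariantRecord], config: FilterConfig,
                            report: FilterReport | None = None) -> list[SomaticVariantRecord]:
    """Drop likely germline polymorphisms: population AF strictly above the cutoff.

    Records without an annotation are kept — absence of evidence of a
    common polymorphism is not treated as evidence.
    """
    records = list(records)
    reasons: Counter[str] = Counter()
    kept = []
    for r in records:
        if r.max_population_af is not None and r.max_population_af > config.max_pop_af:
            reasons["common population variant"] += 1
        else:
            kept.append(r)
    if report is not None:
        report.add("population_af", len(records), len(kept), reasons)
    return kept


def apply_filters(records: Iterable[SomaticVariantRecord], config: FilterConfig | None = None,
                  report: FilterReport | None = None) -> tuple[list[SomaticVariantRecord], FilterReport]:
    """Run the full filter cascade in its canonical order."""
    config = config or FilterConfig()
    report = report if report is not None else FilterReport()
    out = apply_consistency_filter(records, report)
    out = select_missense_snv(out, config, report)
    out = apply_support_filter(out, config, report)
    out = apply_population_filter(out, config, report)
    return out, report


def record_protein_change(record: SomaticVariantRecord) -> ProteinChange:
    """The gene-qualified protein change of a filtered record."""
    change = parse_hgvsp(record.hgvsp_short)
    if change is None:
        raise ValueError(f"record has no parsable missense HGVSp: {record.hgvsp_short!r}")
    return ProteinChange(record.gene_symbol, change.position, change.ref_aa, change.alt_aa)


def patient_protein_changes(records: Iterable[SomaticVariantRecord]) -> set[tuple[str, ProteinChange]]:
    """Collapse filtered records to the (patient, protein change) carrier relation.

    Distinct genomic SNVs producing the same amino-acid exchange in one
    patient (codon redundancy) collapse to a single pair.
    """
    return {(r.sample_id, record_protein_change(r)) for r in records}


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read the patient <-> study membership table (TSV: patient_id, study_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "study_id"):
        if col not in df.columns:
            raise ValueError(f"clinical table lacks required column {col}")
    return df[["patient_id", "study_id"]]


def records_to_frame(records: Iterable[SomaticVariantRecord]) -> pd.DataFrame:
    """Records back to a MAF-dialect DataFrame (for persisting filtered TSVs)."""
    rows = []
    for r in records:
        rows.append({
            "Tumor_Sample_Barcode": r.sample_id,
            "Hugo_Symbol": r.gene_symbol,
            "Transcript_ID": r.transcript_id,
            "HGVSp_Short": r.hgvsp_short,
            "Chromosome": r.chromosome,
            "Start_Position": r.position,
            "Reference_Allele": r.ref_base,
            "Tumor_Seq_Allele2": r.alt_base,
            "Variant_Type": r.variant_type,
            "Variant_Classification": r.variant_classification,
            "Mutation_Status": r.mutation_status,
            "t_depth": r.t_depth,
            "t_ref_count": r.t_ref_count,
            "t_alt_count": r.t_alt_count,
            "max_pop_af": "" if r.max_population_af is None else r.max_population_af,
            "study_id": r.study_id,
        })
    return pd.DataFrame(rows)
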