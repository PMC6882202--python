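"""Per-cohort recurrence calling of protein changes.

A protein change is recurrent within one study cohort when it is carried
by at least a threshold fraction (default 1%) of all patients with
clinical information in that study — including patients contributing no
surviving variant, which keeps the denominator conservative. Cohorts
below a minimum size (default 101 patients, i.e. strictly more than 100)
are excluded; together with the 1% threshold this guarantees every
recurrent call rests on at least two carriers.

Frequencies are carried as exact rationals so the threshold comparison
is never subject to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .variant_filtering import ProteinChange

CohortTable = dict[str, set[str]]


@dataclass(frozen=True)
class RecurrenceRecord:
    """One recurrent protein change in one study cohort."""

    change: ProteinChange
    study_id: str
    n_carriers: int
    cohort_size: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_carriers <= self.cohort_size:
            raise ValueError("carrier count must lie in [1, cohort size]")

    @property
    def frequency(self) -> Fraction:
        """Observed carrier fraction r_d, exact."""
        return Fraction(self.n_carriers, self.cohort_size)


@dataclass
class CodonGroup:
    """All recurrent changes sharing one (gene, codon) position."""

    gene_symbol: str
    position: int
    alt_residues: set[str] = field(default_factory=set)
    member_records: list[RecurrenceRecord] = field(default_factory=list)

    @property
    def total_carriers(self) -> int:
        return sum(r.n_carriers for r in self.member_records)


def build_cohorts(clinical: pd.DataFrame) -> CohortTable:
    """Study -> clinical patient set, from a (patient_id, study_id) table."""
    cohorts: CohortTable = {}
    for study, group in clinical.groupby("study_id"):
        cohorts[str(study)] = set(group["patient_id"].astype(str))
    seen: set[str] = set()
    for study, patients in cohorts.items():
        dup = seen & patients
        if dup:
            raise ValueError(f"patients in multiple studies: {sorted(dup)[:5]}")
        seen |= patients
    return cohorts


def eligible_cohorts(cohorts: CohortTable, min_patients: int = 101) -> CohortTable:
    """Retain studies with at least `min_patients` clinical patients."""
    return {s: p for s, p in cohorts.items() if len(p) >= min_patients}


def call_recurrent(carriers: Iterable[tuple[str, ProteinChange]],
                   cohorts: CohortTable,
                   threshold: Fraction | float = Fraction(1, 100)) -> list[RecurrenceRecord]:
    """Call per-study recurrent changes at the (inclusive) frequency threshold.

    The denominator is the full clinical patient count of the study.
    Carrier patients absent from every cohort are a hard error (they
    indicate a clinical-table / variant-table mismatch upstream).
    """
    if not isinstance(threshold, Fraction):
        threshold = Fraction(threshold).limit_denominator(10**9)
    patient_to_study = {p: s for s, ps in cohorts.items() for p in ps}
    counts: dict[tuple[str, ProteinChange], set[str]] = {}
    for patient, change in carriers:
        study = patient_to_study.get(patient)
        if study is None:
            raise ValueError(f"carrier patient {patient!r} not in any cohort")
        counts.setdefault((study, change), set()).add(patient)

    records = [
        RecurrenceRecord(change=change, study_id=study,
                         n_carriers=len(patients), cohort_size=len(cohorts[study]))
        for (study, change), patients in counts.items()
        if Fraction(len(patients), len(cohorts[study])) >= threshold
    ]
    records.sort(key=lambda r: (r.study_id, -r.frequency,
                                r.change.gene_symbol, r.change.position, r.change.alt_aa))
    return records


def unique_changes(records: Iterable[RecurrenceRecord]) -> set[ProteinChange]:
    """Deduplicate recurrent changes across studies."""
    return {r.change for r in records}


def group_by_codon(records: Iterable[RecurrenceRecord]) -> list[CodonGroup]:
    """Merge recurrent changes at the same (gene, codon), e.g. IDH1 R132H/C/G/S.

    Groups are sorted by total carrier count descending (ties by gene,
    position) for stable hotspot-style output.
    """
    groups: dict[tuple[str, int], CodonGroup] = {}
    for rec in records:
        key = (rec.change.gene_symbol, rec.change.position)
        grp = groups.setdefault(key, CodonGroup(*key))
        grp.alt_residues.add(rec.change.alt_aa)
        grp.member_records.append(rec)
    out = list(groups.values())
    out.sort(key=lambda g: (-g.total_carriers, g.gene_symbol, g.position))
    return out


def hotspot_overlap(groups: Iterable[CodonGroup],
                    hotspots: Mapping[tuple[str, int], bool] | set[tuple[str, int]],
                    ) -> tuple[int, list[CodonGroup], list[CodonGroup]]:
    """Codon-level overlap with an external hotspot list.

    `hotspots` maps (gene, position) -> flagged-as-presumptive-false-positive,
    or is a plain set (nothing flagged). Returns the overlap count, the
    overlapping groups, and those matching flagged entries.
    """
    if not isinstance(hotspots, Mapping):
        hotspots = {key: False for key in hotspots}
    overlap = [g for g in groups if (g.gene_symbol, g.position) in hotspots]
    flagged = [g for g in overlap if hotspots[(g.gene_symbol, g.position)]]
    return len(overlap), overlap, flagged


def load_hotspots(path: str | Path) -> dict[tuple[str, int], bool]:
    """Hotspot TSV with columns gene, position[, flagged]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "position": int})
    flagged = df["flagged"].astype(int).astype(bool) if "flagged" in df.columns \
        else pd.Series(False, index=df.index)
    return {(str(g), int(p)): bool(f)
            for g, p, f in zip(df["gene"], df["position"], flagged)}


def records_to_frame(records: Iterable[RecurrenceRecord]) -> pd.DataFrame:
    """Recurrence records as the canonical output TSV layout."""
    return pd.DataFrame([{
        "study_id": r.study_id,
        "gene": r.change.gene_symbol,
        "position": r.change.position,
        "ref_aa": r.change.ref_aa,
        "alt_aa": r.change.alt_aa,
        "n_carriers": r.n_carriers,
        "cohort_size": r.cohort_size,
        "frequency": float(r.frequency),
    } for r in records])


def frame_to_records(df: pd.DataFrame) -> list[RecurrenceRecord]:
    return [
        RecurrenceRecord(
            change=ProteinChange(str(row.gene), int(row.position), str(row.ref_aa), str(row.alt_aa)),
            study_id=str(row.study_id),
            n_carriers=int(row.n_carriers),
            cohort_size=int(row.cohort_size),
        )
        for row in df.itertuples()
    ]


def observed_frequencies(carriers: Iterable[tuple[str, ProteinChange]],
                         cohorts: CohortTable) -> dict[tuple[ProteinChange, str], Fraction]:
    """Observed carrier fraction of every change in every study, sub-threshold included.

    This is the r_d table the downstream expected-patient ranking sums
    over: a change that is recurrent anywhere still accrues patients from
    cohorts where its frequency sits below the recurrence threshold.
    """
    patient_to_study = {p: s for s, ps in cohorts.items() for p in ps}
    counts: dict[tuple[ProteinChange, str], set[str]] = {}
    for patient, change in carriers:
        study = patient_to_study.get(patient)
        if study is None:
            raise ValueError(f"carrier patient {patient!r} not in any cohort")
        counts.setdefault((change, study), set()).add(patient)
    return {key: Fraction(len(ps), len(cohorts[key[1]])) for key, ps in counts.items()}
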