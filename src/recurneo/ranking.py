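"""Expected-patient ranking and population coverage of neo-epitope candidates.

The ranking statistic for a candidate (protein change v, HLA allele h) is
the expected number of newly diagnosed patients per year who both carry
the mutation and the allele:

    n_h = f_h * sum_d r_{v,d} * N_d

where f_h is the population frequency of allele h, N_d the annual number
of newly diagnosed patients with disease d, and r_{v,d} the observed
carrier fraction of the change in the disease-d study cohort. The sum
runs over diseases present in both the incidence table and the variant
frequency table; sub-threshold observed frequencies still contribute.

Coverage cells aggregate candidates under an independence model: the
expected number of patients of disease d and allele h carrying at least
one candidate mutation is N_d * f_h * (1 - prod_v (1 - r_{v,d})).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .peptides import NeoEpitopeCandidate
from .variant_filtering import ProteinChange

HlaFrequencyTable = dict[str, float]
IncidenceTable = dict[str, float]
VariantFrequencyTable = dict[tuple[ProteinChange, str], float]


@dataclass
class ExpectedPatientCount:
    """n_h for one candidate, with its per-disease decomposition."""

    change: ProteinChange
    allele: str
    n_h: float
    per_disease: dict[str, float] = field(default_factory=dict)


def carrier_frequency(f_h: float, diploid: bool = False) -> float:
    """Allele frequency, or the diploid carrier frequency 1-(1-f)^2 on request."""
    return 1.0 - (1.0 - f_h) ** 2 if diploid else f_h


def expected_patients(candidate: NeoEpitopeCandidate,
                      f: Mapping[str, float],
                      N: Mapping[str, float],
                      r: VariantFrequencyTable,
                      diploid: bool = False) -> ExpectedPatientCount:
    """Expected annual patients carrying the candidate's mutation and allele."""
    if candidate.allele not in f:
        raise KeyError(f"allele {candidate.allele!r} absent from frequency table")
    f_h = carrier_frequency(f[candidate.allele], diploid)
    per_disease: dict[str, float] = {}
    for (change, disease), freq in r.items():
        if change != candidate.change or disease not in N:
            continue
        if not 0.0 <= freq <= 1.0:
            raise ValueError(f"variant frequency out of [0,1]: {freq}")
        per_disease[disease] = f_h * float(freq) * float(N[disease])
    return ExpectedPatientCount(candidate.change, candidate.allele,
                                sum(per_disease.values()), per_disease)


def rank_candidates(counts: Iterable[ExpectedPatientCount]) -> list[ExpectedPatientCount]:
    """Descending n_h; deterministic lexicographic tie-break."""
    return sorted(counts, key=lambda c: (
        -c.n_h, c.change.gene_symbol, c.change.position, c.change.alt_aa, c.allele))


def prob_at_least_one(freqs: Sequence[float]) -> float:
    """P(at least one event) for independent events with the given probabilities."""
    prod = 1.0
    for p in freqs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of [0,1]: {p}")
        prod *= 1.0 - p
    return 1.0 - prod if freqs else 0.0


def coverage_table(candidates: Sequence[NeoEpitopeCandidate],
                   f: Mapping[str, float],
                   N: Mapping[str, float],
                   r: VariantFrequencyTable,
                   diploid: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disease x allele expected-patient matrix plus per-allele candidate counts.

    Cell (d, h) = N_d * f_h * P(>= 1 candidate mutation of an h-binder),
    under independence of variant occurrences. Returns the matrix with a
    "Total" row of column sums, and a one-row per-allele candidate-count
    table (distinct protein changes with a candidate for that allele).
    """
    alleles = sorted({c.allele for c in candidates})
    diseases = sorted(N.keys())
    changes_by_allele: dict[str, set[ProteinChange]] = {a: set() for a in alleles}
    for c in candidates:
        changes_by_allele[c.allele].add(c.change)

    matrix = pd.DataFrame(0.0, index=diseases, columns=alleles)
    for d in diseases:
        for h in alleles:
            freqs = [float(r[(v, d)]) for v in changes_by_allele[h] if (v, d) in r]
            matrix.loc[d, h] = (float(N[d]) * carrier_frequency(f[h], diploid)
                                * prob_at_least_one(freqs))
    matrix.loc["Total"] = matrix.sum(axis=0)
    counts = pd.DataFrame(
        {h: [len(changes_by_allele[h])] for h in alleles}, index=["n_candidates"])
    return matrix, counts


# ---------------------------------------------------------------------------
# table IO

def load_hla_frequencies(path: str | Path) -> HlaFrequencyTable:
    """TSV with columns allele, frequency (fractions in [0,1])."""
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "frequency": float})
    table = dict(zip(df["allele"], df["frequency"]))
    bad = {a: v for a, v in table.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"allele frequencies outside [0,1]: {bad}")
    return table


def load_incidence(path: str | Path) -> IncidenceTable:
    """TSV with columns disease, annual_cases."""
    df = pd.read_csv(path, sep="\t")
    table = {str(d): float(n) for d, n in zip(df["disease"], df["annual_cases"])}
    if any(v < 0 for v in table.values()):
        raise ValueError("negative annual case counts")
    return table


def load_variant_frequencies(path: str | Path) -> VariantFrequencyTable:
    """TSV with columns gene, position, ref_aa, alt_aa, disease, frequency."""
    df = pd.read_csv(path, sep="\t")
    return {
        (ProteinChange(str(row.gene), int(row.position), str(row.ref_aa), str(row.alt_aa)),
         str(row.disease)): float(row.frequency)
        for row in df.itertuples()
    }


def variant_frequencies_to_frame(r: VariantFrequencyTable) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": change.gene_symbol, "position": change.position,
        "ref_aa": change.ref_aa, "alt_aa": change.alt_aa,
        "disease": disease, "frequency": float(freq),
    } for (change, disease), freq in sorted(
        r.items(), key=lambda kv: (kv[0][0].token, kv[0][1]))])


def _data_path(name: str):
    return resources.files("recurneo.data").joinpath(name)


def us_reference_tables() -> tuple[HlaFrequencyTable, IncidenceTable]:
    """The bundled U.S. reference tables: 11 HLA-1 allele frequencies
    (AFND North-American averages) and 18 annual cancer incidence counts
    (GLOBOCAN 2012)."""
    with resources.as_file(_data_path("us_hla_frequencies.tsv")) as p:
        f = load_hla_frequencies(p)
    with resources.as_file(_data_path("us_cancer_incidence.tsv")) as p:
        N = load_incidence(p)
    return f, N


def ranking_to_frame(counts: Iterable[ExpectedPatientCount]) -> pd.DataFrame:
    """Ranked-candidate TSV: per-disease expected patients plus the total."""
    counts = list(counts)
    diseases = sorted({d for c in counts for d in c.per_disease})
    rows = []
    for c in counts:
        row = {
            "gene": c.change.gene_symbol, "position": c.change.position,
            "ref_aa": c.change.ref_aa, "alt_aa": c.change.alt_aa,
            "allele": c.allele, "expected_patients": c.n_h,
            "expected_patients_rounded": round(c.n_h),
        }
        for d in diseases:
            row[f"expected_{d}"] = c.per_disease.get(d, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
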