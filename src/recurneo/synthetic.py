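"""Synthetic cohorts with ground truth for end-to-end pipeline testing.

Everything the pipeline consumes can be generated here with known truth:
a random proteome, MAF-dialect somatic variant tables with planted
recurrent protein changes at exact carrier counts (or binomially drawn
frequencies), contaminant rows that each violate exactly one labelled
filter, per-patient HLA genotypes drawn under Hardy-Weinberg
independence, homopolymer-context tables, and random or reference
population tables. All generators are pure functions of (config, seed).

The emulated data shape follows tumor/normal whole-exome cohorts: read
depths are negative-binomial (mean 80, dispersion 10), VAFs are
Beta(8, 12) — mean 0.4, as in moderately impure tumors — truncated so
intended pass/fail labels stay correct, and background (non-recurrent)
changes are unique per patient so that no accidental recurrence can
blur the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .predictors import DEFAULT_ALLELE_PANEL, ToyBindingPredictor
from .qc import in_homopolymer
from .ranking import us_reference_tables
from .variant_filtering import ProteinChange

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

#: contaminant label -> filter stage expected to reject it
CONTAMINANT_STAGES = {
    "no_transcript": "read_maf",
    "not_somatic": "consistency",
    "depth_mismatch": "consistency",
    "multi_nt_allele": "consistency",
    "non_snp_type": "missense_snv",
    "silent_classification": "missense_snv",
    "bad_hgvsp": "missense_snv",
    "low_support": "read_support",
    "low_vaf": "read_support",
    "common_population": "population_af",
}


@dataclass(frozen=True)
class PlantedChange:
    """A protein change planted in one study at a known prevalence."""

    change: ProteinChange
    study_id: str
    n_carriers: Optional[int] = None     # exact mode
    frequency: Optional[float] = None    # stochastic (binomial) mode

    def __post_init__(self) -> None:
        if (self.n_carriers is None) == (self.frequency is None):
            raise ValueError("specify exactly one of n_carriers / frequency")


@dataclass
class SimulationConfig:
    studies: list[tuple[str, int]] = field(
        default_factory=lambda: [("TCGA-SIM1", 400), ("TCGA-SIM2", 250)])
    planted_changes: list[PlantedChange] = field(default_factory=list)
    background_changes_per_patient: float = 3.0
    depth_mean: float = 80.0
    depth_dispersion: float = 10.0
    vaf_alpha: float = 8.0
    vaf_beta: float = 12.0
    contaminants: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.contaminants) - set(CONTAMINANT_STAGES)
        if unknown:
            raise ValueError(f"unknown contaminant labels: {sorted(unknown)}")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated cohort."""

    planted: list[tuple[ProteinChange, str, int]] = field(default_factory=list)
    contaminant_rows: dict[str, list[int]] = field(default_factory=dict)  # label -> MAF row idx
    hla_genotypes: dict[str, set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# proteome

def simulate_proteome(n_genes: int, length_range: tuple[int, int] = (80, 300),
                      seed: int = 0) -> tuple[str, dict[str, str]]:
    """Uniform-random protein sequences; returns (FASTA text, id -> sequence).

    Minimum length 23 so that interior positions admit the full set of
    11-mer windows on both sides.
    """
    lo, hi = length_range
    if lo < 23:
        raise ValueError("minimum protein length is 23")
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA), size=length))
        sequences[f"GENE{i + 1:04d}"] = seq
    fasta = "".join(f">{name}\n{seq}\n" for name, seq in sequences.items())
    return fasta, sequences


def change_from_proteome(proteome: Mapping[str, str], gene: str, position: int,
                         alt_aa: str) -> ProteinChange:
    """A planted change consistent with the proteome's reference residue."""
    seq = proteome[gene]
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} outside {gene}")
    ref = seq[position - 1]
    if ref == alt_aa:
        raise ValueError(f"{gene} position {position} already is {alt_aa}")
    return ProteinChange(gene, position, ref, alt_aa)


def random_change(proteome: Mapping[str, str], rng: np.random.Generator,
                  exclude: set[ProteinChange] | None = None) -> ProteinChange:
    """A random proteome-consistent change, avoiding an exclusion set."""
    genes = sorted(proteome)
    exclude = exclude or set()
    for _ in range(10000):
        gene = genes[int(rng.integers(len(genes)))]
        pos = int(rng.integers(1, len(proteome[gene]) + 1))
        ref = proteome[gene][pos - 1]
        alt = AA[int(rng.integers(len(AA)))]
        if alt == ref:
            continue
        change = ProteinChange(gene, pos, ref, alt)
        if change not in exclude:
            return change
    raise RuntimeError("could not draw a fresh change; proteome too small")


# ---------------------------------------------------------------------------
# cohort

def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    n = cfg.depth_dispersion
    p = n / (n + cfg.depth_mean)
    return int(max(rng.negative_binomial(n, p), 30))


def _draw_passing_vaf(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    while True:
        v = float(rng.beta(cfg.vaf_alpha, cfg.vaf_beta))
        if v >= 0.10:
            return v


def _codon_coordinates(change: ProteinChange) -> tuple[str, int]:
    # one gene <-> one contig; the codon's first base at 3 * (aa position) - 2
    return f"chr_{change.gene_symbol}", 3 * change.position - 2


def _base_row(sample: str, change: ProteinChange, rng: np.random.Generator,
              cfg: SimulationConfig) -> dict:
    """A MAF row that passes every filter."""
    chrom, npos = _codon_coordinates(change)
    depth = _draw_depth(rng, cfg)
    vaf = _draw_passing_vaf(rng, cfg)
    alt = max(5, round(vaf * depth))
    ref_nt = NT[int(rng.integers(4))]
    alt_nt = NT[(NT.index(ref_nt) + 1 + int(rng.integers(3))) % 4]
    return {
        "Tumor_Sample_Barcode": sample,
        "Hugo_Symbol": change.gene_symbol,
        "Transcript_ID": f"ENST_{change.gene_symbol}",
        "HGVSp_Short": change.hgvsp_short(),
        "Chromosome": chrom,
        "Start_Position": npos,
        "Reference_Allele": ref_nt,
        "Tumor_Seq_Allele2": alt_nt,
        "Variant_Type": "SNP",
        "Variant_Classification": "Missense_Mutation",
        "Mutation_Status": "Somatic",
        "t_depth": depth,
        "t_ref_count": depth - alt,
        "t_alt_count": alt,
        "max_pop_af": "",
    }


def _contaminate(row: dict, label: str, rng: np.random.Generator) -> dict:
    """Break a passing row so it violates exactly the labelled filter."""
    row = dict(row)
    if label == "no_transcript":
        row["Transcript_ID"] = ""
    elif label == "not_somatic":
        row["Mutation_Status"] = "Germline"
    elif label == "depth_mismatch":
        row["t_depth"] = int(row["t_depth"]) + 1
    elif label == "multi_nt_allele":
        row["Reference_Allele"] = str(row["Reference_Allele"]) + "C"
    elif label == "non_snp_type":
        row["Variant_Type"] = "DEL"
    elif label == "silent_classification":
        row["Variant_Classification"] = "Silent"
    elif label == "bad_hgvsp":
        row["HGVSp_Short"] = f"p.R{int(rng.integers(1, 500))}*"
    elif label == "low_support":
        # 4 alt reads but VAF comfortably above threshold
        row["t_alt_count"], row["t_depth"] = 4, 20
        row["t_ref_count"] = 16
    elif label == "low_vaf":
        # plenty of alt reads but VAF 5%
        row["t_alt_count"], row["t_depth"] = 6, 120
        row["t_ref_count"] = 114
    elif label == "common_population":
        row["max_pop_af"] = 0.02
    else:
        raise ValueError(f"unknown contaminant label {label!r}")
    return row


def simulate_cohort(config: SimulationConfig, proteome: Mapping[str, str],
                    ) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate MAF + clinical tables with known planted truth.

    Planted changes get exactly their specified carrier count (exact
    mode) or Binomial(n_patients, frequency) carriers (stochastic mode).
    Background changes are drawn fresh per patient and never repeat
    across patients, so only planted changes can be recurrent.
    Contaminant rows are appended per label, each violating exactly its
    labelled filter stage.
    """
    rng = np.random.default_rng(config.seed)
    patients = {study: [f"{study}-P{i:04d}" for i in range(n)]
                for study, n in config.studies}
    clinical = pd.DataFrame([
        {"patient_id": p, "study_id": s}
        for s, ps in patients.items() for p in ps])

    truth = TruthRecord()
    rows: list[dict] = []
    used_changes = {pc.change for pc in config.planted_changes}

    for planted in config.planted_changes:
        if planted.study_id not in patients:
            raise ValueError(f"planted change references unknown study {planted.study_id}")
        pool = patients[planted.study_id]
        # verify the proteome agrees with the planted reference residue
        change_from_proteome(proteome, planted.change.gene_symbol,
                             planted.change.position, planted.change.alt_aa)
        if planted.n_carriers is not None:
            if planted.n_carriers > len(pool):
                raise ValueError(
                    f"{planted.change.token}: {planted.n_carriers} carriers "
                    f"> {len(pool)} patients in {planted.study_id}")
            carriers = list(rng.choice(pool, size=planted.n_carriers, replace=False))
        else:
            mask = rng.random(len(pool)) < planted.frequency
            carriers = [p for p, m in zip(pool, mask) if m]
        for carrier in carriers:
            rows.append(_base_row(carrier, planted.change, rng, config))
        truth.planted.append((planted.change, planted.study_id, len(carriers)))

    # unique-per-patient background changes
    for study, pool in patients.items():
        n_bg = rng.poisson(config.background_changes_per_patient, size=len(pool))
        for patient, k in zip(pool, n_bg):
            for _ in range(int(k)):
                change = random_change(proteome, rng, exclude=used_changes)
                used_changes.add(change)
                rows.append(_base_row(patient, change, rng, config))

    # contaminants, appended with per-label row bookkeeping
    all_patients = [p for ps in patients.values() for p in ps]
    for label in sorted(config.contaminants):
        idxs = []
        for _ in range(config.contaminants[label]):
            patient = all_patients[int(rng.integers(len(all_patients)))]
            change = random_change(proteome, rng, exclude=used_changes)
            used_changes.add(change)
            idxs.append(len(rows))
            rows.append(_contaminate(_base_row(patient, change, rng, config), label, rng))
        truth.contaminant_rows[label] = idxs

    maf = pd.DataFrame(rows)
    return maf, clinical, truth


# ---------------------------------------------------------------------------
# HLA genotypes

def default_locus_frequencies() -> dict[str, dict[str, float]]:
    """Panel allele frequencies grouped by locus (remainder = untyped 'other')."""
    f, _ = us_reference_tables()
    loci: dict[str, dict[str, float]] = {}
    for allele, freq in f.items():
        locus = allele.split("*")[0]  # e.g. HLA-A
        loci.setdefault(locus, {})[allele] = freq
    return loci


def simulate_hla_genotypes(patients: Sequence[str],
                           locus_freqs: Mapping[str, Mapping[str, float]] | None = None,
                           seed: int = 0) -> dict[str, set[str]]:
    """Two independent draws per locus (Hardy-Weinberg); allele set per patient.

    Per-locus frequencies must sum to <= 1; the remainder is an
    anonymous non-panel allele that never enters the profile.
    """
    locus_freqs = locus_freqs or default_locus_frequencies()
    rng = np.random.default_rng(seed)
    for locus, freqs in locus_freqs.items():
        total = sum(freqs.values())
        if total > 1 + 1e-9:
            raise ValueError(f"frequencies at locus {locus} sum to {total} > 1")
    genotypes: dict[str, set[str]] = {}
    for patient in patients:
        alleles: set[str] = set()
        for locus, freqs in locus_freqs.items():
            names = sorted(freqs)
            probs = [freqs[n] for n in names]
            other = 1.0 - sum(probs)
            for _ in range(2):  # two chromosomes
                draw = rng.choice(len(names) + 1, p=probs + [other])
                if draw < len(names):
                    alleles.add(names[draw])
        genotypes[patient] = alleles
    return genotypes


# ---------------------------------------------------------------------------
# contexts & population tables

def _random_context(rng: np.random.Generator, window: int) -> str:
    return "".join(np.asarray(list(NT))[rng.integers(4, size=window)])


def _repeat_context(rng: np.random.Generator, window: int, min_run: int) -> str:
    """A context whose center run length is >= min_run."""
    while True:
        base = NT[int(rng.integers(4))]
        center = window // 2
        run = int(rng.integers(min_run, window + 1))
        start = int(rng.integers(max(0, center - run + 1), min(center, window - run) + 1))
        ctx = list(_random_context(rng, window))
        ctx[start:start + run] = base * run
        ctx = "".join(ctx)
        if in_homopolymer(ctx, min_run):
            return ctx


def _nonrepeat_context(rng: np.random.Generator, window: int, min_run: int) -> str:
    while True:
        ctx = _random_context(rng, window)
        if not in_homopolymer(ctx, min_run):
            return ctx


def simulate_context_table(studies: Sequence[tuple[str, int, int]],
                           repeat_fraction_singleton: float,
                           repeat_fraction_recurrent: float = 0.0,
                           window: int = 11, min_run: int = 6,
                           seed: int = 0) -> pd.DataFrame:
    """Per-study variant context table with planted repeat fractions.

    `studies` lists (study_id, n_singletons, n_recurrent). Each variant
    row carries its 11-base reference context and its cohort occurrence
    count (1 for singletons, 2 for the recurrent branch).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for study, n_single, n_recur in studies:
        for branch, n, frac in (("s", n_single, repeat_fraction_singleton),
                                ("r", n_recur, repeat_fraction_recurrent)):
            n_rep = round(n * frac)
            for i in range(n):
                ctx = (_repeat_context(rng, window, min_run) if i < n_rep
                       else _nonrepeat_context(rng, window, min_run))
                rows.append({"study_id": study, "variant": f"{study}-{branch}{i}",
                             "context": ctx,
                             "n_occurrences": 1 if branch == "s" else 2})
    return pd.DataFrame(rows)


def simulate_population_tables(n_diseases: int = 18, seed: int = 0,
                               incidence_range: tuple[int, int] = (3000, 260000),
                               alleles: Sequence[str] = DEFAULT_ALLELE_PANEL,
                               freq_range: tuple[float, float] = (0.02, 0.25),
                               ) -> tuple[dict[str, float], dict[str, float]]:
    """Random HLA-frequency and incidence tables (or use `us_reference_tables`)."""
    rng = np.random.default_rng(seed)
    f = {a: float(rng.uniform(*freq_range)) for a in alleles}
    N = {f"DIS{i + 1:02d}": float(rng.integers(*incidence_range))
         for i in range(n_diseases)}
    return f, N


def toy_binding_predictor(seed: int = 0, **kwargs) -> ToyBindingPredictor:
    """The deterministic synthetic binding predictor (see `predictors`)."""
    return ToyBindingPredictor(seed=seed, **kwargs)


def _alt_residue(ref: str, shift: int = 1) -> str:
    return AA[(AA.index(ref) + shift) % len(AA)]


def example_scenario(seed: int = 0, n_genes: int = 30,
                     ) -> tuple[SimulationConfig, str, dict[str, str]]:
    """A ready-made two-study scenario exercising every pipeline stage.

    Two cohorts (400 and 250 patients) carry four planted changes: a
    clearly recurrent one (5%), a moderately recurrent one present in
    both studies (1.5% / 1.2%), a sub-threshold one (0.5%), and one
    recurrent only in the second study (4%). Four contaminant rows per
    violation label are mixed in. Returns (config, FASTA text, proteome).
    """
    fasta, proteome = simulate_proteome(n_genes, (60, 200), seed=seed)
    genes = sorted(proteome)

    def planted(gene_idx, pos, study, **kw):
        gene = genes[gene_idx]
        alt = _alt_residue(proteome[gene][pos - 1])
        return PlantedChange(change_from_proteome(proteome, gene, pos, alt),
                             study, **kw)

    config = SimulationConfig(
        studies=[("TCGA-SIM1", 400), ("TCGA-SIM2", 250)],
        planted_changes=[
            planted(0, 30, "TCGA-SIM1", n_carriers=20),   # 5.0%
            planted(1, 25, "TCGA-SIM1", n_carriers=6),    # 1.5%
            planted(1, 25, "TCGA-SIM2", n_carriers=3),    # 1.2%, same change
            planted(2, 40, "TCGA-SIM1", n_carriers=2),    # 0.5%, sub-threshold
            planted(3, 18, "TCGA-SIM2", n_carriers=10),   # 4.0%
        ],
        background_changes_per_patient=3.0,
        contaminants={label: 4 for label in CONTAMINANT_STAGES},
        seed=seed,
    )
    return config, fasta, proteome
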