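"""End-to-end orchestration: filter -> recurrence -> epitopes -> ranking.

Every stage persists its output as a TSV in the run directory, so any
stage can be re-run independently from the previous stage's file, and a
JSON manifest records configuration, seeds and per-stage record counts.
Identical configuration and seed produce byte-identical TSV outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import peptides, predictors, qc, ranking, recurrence, robustness
from . import variant_filtering as vf


@dataclass
class PipelineConfig:
    """All inputs and stage parameters; defaults encode the standard analysis."""

    maf: str | dict[str, str] = ""
    clinical: str = ""
    proteome: str = ""
    out_dir: str = "recurneo_run"
    # filter stage
    min_alt_reads: int = 5
    min_vaf: float = 0.10
    max_pop_af: float = 0.01
    # recurrence stage
    recurrence_threshold: float = 0.01
    min_cohort: int = 101
    hotspots: Optional[str] = None
    # epitope stage
    window_lengths: tuple[int, ...] = (9, 10, 11)
    alleles: Optional[str] = None        # panel file; None = default 11-allele panel
    predictor: str = "toy"               # "toy" or "netmhccons-table:<path>"
    keep_classes: tuple[str, ...] = ("strong",)
    # ranking stage
    hla_freq: Optional[str] = None       # None = bundled U.S. reference
    incidence: Optional[str] = None
    study_disease_map: Optional[dict[str, str]] = None  # default: identity
    diploid: bool = False
    # optional stages
    profiles: Optional[str] = None       # enables robustness
    fp_fractions: tuple[float, ...] = (0.5, 0.8, 0.9, 0.95)
    n_iterations: int = 1000
    contexts: Optional[str] = None       # enables homopolymer QC
    min_run: int = 6
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("window_lengths", "keep_classes", "fp_fractions"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _build_predictor(config: PipelineConfig):
    if config.predictor == "toy":
        return predictors.ToyBindingPredictor(seed=config.seed)
    if config.predictor.startswith("netmhccons-table:"):
        return predictors.TablePredictor.from_file(
            config.predictor.split(":", 1)[1])
    raise ValueError(f"unknown predictor spec {config.predictor!r}")


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_all(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "recurneo",
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    # ---- filtering -------------------------------------------------------
    fcfg = vf.FilterConfig(min_alt_reads=config.min_alt_reads,
                           min_vaf=config.min_vaf, max_pop_af=config.max_pop_af)
    clinical = vf.load_clinical(config.clinical)
    patient_study = dict(zip(clinical["patient_id"], clinical["study_id"]))
    report = vf.FilterReport()
    records = []
    maf_inputs = config.maf if isinstance(config.maf, dict) else {"": config.maf}
    for study, path in sorted(maf_inputs.items()):
        recs, _ = vf.read_maf(path, study, report)
        records.extend(recs)
    for rec in records:  # study membership comes from the clinical table
        rec.study_id = patient_study.get(rec.sample_id, rec.study_id)
    filtered, report = vf.apply_filters(records, fcfg, report)
    _write_tsv(vf.records_to_frame(filtered), out / "filtered_variants.tsv")
    report.to_json(out / "filter_report.json")
    manifest["stages"]["filter"] = {
        "n_input_rows": report.stages[0].n_in if report.stages else 0,
        "n_filtered": len(filtered),
        "report": [asdict(s) for s in report.stages],
    }

    # ---- recurrence ------------------------------------------------------
    carriers = vf.patient_protein_changes(filtered)
    cohorts = recurrence.build_cohorts(clinical)
    eligible = recurrence.eligible_cohorts(cohorts, config.min_cohort)
    eligible_patients = {p for ps in eligible.values() for p in ps}
    dropped = {(p, c) for p, c in carriers if p not in eligible_patients}
    carriers -= dropped
    recurrent = recurrence.call_recurrent(carriers, eligible,
                                          config.recurrence_threshold)
    uniques = recurrence.unique_changes(recurrent)
    groups = recurrence.group_by_codon(recurrent)
    _write_tsv(recurrence.records_to_frame(recurrent), out / "recurrent_variants.tsv")
    manifest["stages"]["recurrence"] = {
        "n_cohorts": len(cohorts), "n_eligible_cohorts": len(eligible),
        "n_carriers_dropped_ineligible": len(dropped),
        "n_recurrent": len(recurrent), "n_unique_changes": len(uniques),
        "n_codon_groups": len(groups),
    }
    if config.hotspots:
        hotspots = recurrence.load_hotspots(config.hotspots)
        n_overlap, _, flagged = recurrence.hotspot_overlap(groups, hotspots)
        manifest["stages"]["recurrence"]["hotspot_overlap"] = n_overlap
        manifest["stages"]["recurrence"]["hotspot_flagged"] = len(flagged)

    # r_d over ALL eligible cohorts, sub-threshold frequencies included
    dmap = config.study_disease_map or {}
    freqs = recurrence.observed_frequencies(carriers, eligible)
    r_table = {(change, dmap.get(study, study)): float(frac)
               for (change, study), frac in freqs.items() if change in uniques}
    _write_tsv(ranking.variant_frequencies_to_frame(r_table),
               out / "variant_frequencies.tsv")

    # ---- epitopes --------------------------------------------------------
    proteome = peptides.load_proteome(config.proteome)
    predictor = _build_predictor(config)
    panel = predictors.load_allele_panel(config.alleles)
    candidates: list[peptides.NeoEpitopeCandidate] = []
    skipped_genes: set[str] = set()
    for change in sorted(uniques):
        if change.gene_symbol not in proteome:
            skipped_genes.add(change.gene_symbol)
            continue
        candidates.extend(peptides.candidates_for_change(
            change, proteome, predictor, panel, config.window_lengths))
    kept = peptides.filter_binders(candidates, config.keep_classes)
    _write_tsv(peptides.candidates_to_frame(kept), out / "candidates.tsv")
    manifest["stages"]["epitopes"] = {
        "n_alleles": len(panel), "n_collapsed": len(candidates),
        "n_kept": len(kept), "kept_classes": list(config.keep_classes),
        "n_genes_without_sequence": len(skipped_genes),
    }

    # ---- ranking & coverage ---------------------------------------------
    f = ranking.load_hla_frequencies(config.hla_freq) if config.hla_freq \
        else ranking.us_reference_tables()[0]
    N = ranking.load_incidence(config.incidence) if config.incidence \
        else ranking.us_reference_tables()[1]
    counts = [ranking.expected_patients(c, f, N, r_table, config.diploid)
              for c in kept if c.allele in f]
    ranked = ranking.rank_candidates(counts)
    _write_tsv(ranking.ranking_to_frame(ranked), out / "ranked_candidates.tsv")
    matrix, per_allele = ranking.coverage_table(
        [c for c in kept if c.allele in f], f, N, r_table, config.diploid)
    matrix.to_csv(out / "coverage_matrix.tsv", sep="\t")
    per_allele.to_csv(out / "coverage_candidate_counts.tsv", sep="\t")
    manifest["stages"]["ranking"] = {
        "n_ranked": len(ranked),
        "total_expected_patients": float(sum(c.n_h for c in ranked)),
    }

    # ---- robustness (optional) ------------------------------------------
    if config.profiles:
        profiles = robustness.load_profiles(config.profiles)
        keys = {robustness.CandidateKey(c.change, c.allele) for c in kept}
        rcfg = robustness.ResamplingConfig(
            fp_fractions=tuple(config.fp_fractions),
            n_iterations=config.n_iterations, seed=config.seed)
        summaries = robustness.resample(profiles, keys, rcfg)
        per_study = robustness.per_study_summaries(profiles, keys, rcfg)
        _write_tsv(robustness.summaries_to_frame(summaries),
                   out / "robustness_summary.tsv")
        _write_tsv(robustness.summaries_to_frame(per_study, per_study=True),
                   out / "robustness_per_study.tsv")
        manifest["stages"]["robustness"] = {
            "n_profiles": len(profiles), "n_candidates": len(keys),
            "fp_fractions": list(config.fp_fractions),
            "n_iterations": config.n_iterations,
        }

    # ---- homopolymer QC (optional) --------------------------------------
    if config.contexts:
        ctx = pd.read_csv(config.contexts, sep="\t")
        for branch, flag in (("singleton", True), ("recurrent", False)):
            results, n_excluded = qc.run_repeat_qc(
                ctx, unique_only=flag, min_run=config.min_run, alpha=config.alpha)
            _write_tsv(qc.qc_results_to_frame(results), out / f"qc_{branch}.tsv")
            manifest["stages"][f"qc_{branch}"] = {
                "n_studies": len(results), "n_excluded": n_excluded,
                "n_significant": sum(r.significant for r in results),
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
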