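"""Neo-epitope enumeration around recurrent amino-acid exchanges.

For each recurrent protein change the mutant protein is built, every
9/10/11-mer window containing the exchanged residue is enumerated, each
window is scored against an allele panel through a pluggable binding
predictor, and the redundancy across overlapping windows is collapsed to
a single best epitope per (variant, allele) — the window with the lowest
predicted mutant IC50. The wild-type peptide at the same coordinates is
scored alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .predictors import (BindingPrediction, BindingPredictor, BinderClass,
                         DEFAULT_ALLELE_PANEL, PredictorError)
from .variant_filtering import AMINO_ACIDS, ProteinChange

DEFAULT_WINDOW_LENGTHS = (9, 10, 11)


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id} is empty")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.id} contains non-standard residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MutantContext:
    """Wild-type and mutant protein differing at exactly one residue."""

    wild: ProteinSequence
    mutant: ProteinSequence
    mutated_index: int  # 1-based

    def __post_init__(self) -> None:
        if len(self.wild) != len(self.mutant):
            raise ValueError("wild and mutant lengths differ")
        diffs = [i + 1 for i, (a, b) in
                 enumerate(zip(self.wild.residues, self.mutant.residues)) if a != b]
        if diffs != [self.mutated_index]:
            raise ValueError(
                f"sequences differ at positions {diffs}, expected only {self.mutated_index}")


@dataclass(frozen=True)
class PeptideWindow:
    sequence: str
    start: int            # 1-based in the protein
    length: int
    variant_offset: int   # 1-based within the peptide

    def __post_init__(self) -> None:
        if self.start < 1 or not 1 <= self.variant_offset <= self.length:
            raise ValueError("window coordinates out of range")
        if len(self.sequence) != self.length:
            raise ValueError("window sequence length mismatch")


@dataclass(frozen=True)
class NeoEpitopeCandidate:
    """Best predicted epitope for one (protein change, HLA allele) pair."""

    change: ProteinChange
    allele: str
    window: PeptideWindow
    mut_ic50_nm: float
    binder_class: BinderClass
    wt_ic50_nm: float | None = None


def load_proteome(path: str | Path) -> dict[str, ProteinSequence]:
    """Read a protein FASTA; record ids are gene symbols (or transcript ids)."""
    proteome: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise ValueError(f"duplicate FASTA id {rec.id}")
        proteome[rec.id] = ProteinSequence(rec.id, str(rec.seq).upper())
    return proteome


def apply_variant_to_protein(seq: ProteinSequence, change: ProteinChange) -> MutantContext:
    """Substitute the exchanged residue, checking the reference residue matches."""
    pos = change.position
    if pos > len(seq):
        raise ValueError(
            f"position {pos} outside protein {seq.id} (length {len(seq)})")
    found = seq.residues[pos - 1]
    if found != change.ref_aa:
        raise ValueError(
            f"reference mismatch in {seq.id} at {pos}: expected "
            f"{change.ref_aa}, found {found}")
    mutant = seq.residues[:pos - 1] + change.alt_aa + seq.residues[pos:]
    return MutantContext(wild=seq, mutant=ProteinSequence(seq.id, mutant),
                         mutated_index=pos)


def enumerate_windows(context: MutantContext,
                      lengths: Iterable[int] = DEFAULT_WINDOW_LENGTHS) -> list[PeptideWindow]:
    """All peptide windows of the given lengths that contain the mutated residue.

    A window of length k starting at s (1-based) covers positions
    [s, s+k-1]; it qualifies when it lies fully inside the protein and
    covers the mutated index. Windows are ordered by (length, start).
    """
    L = len(context.mutant)
    pos = context.mutated_index
    windows: list[PeptideWindow] = []
    for k in sorted(set(lengths)):
        lo = max(1, pos - k + 1)
        hi = min(pos, L - k + 1)
        for s in range(lo, hi + 1):
            windows.append(PeptideWindow(
                sequence=context.mutant.residues[s - 1:s - 1 + k],
                start=s, length=k, variant_offset=pos - s + 1))
    return windows


def predict_bindings(windows: Sequence[PeptideWindow], alleles: Sequence[str],
                     predictor: BindingPredictor) -> list[BindingPrediction]:
    """One prediction per (window, allele); predictor failures propagate."""
    out: list[BindingPrediction] = []
    for window in windows:
        for allele in alleles:
            try:
                out.append(predictor.predict(window.sequence, allele))
            except PredictorError:
                raise
            except Exception as exc:  # re-brand with the offending pair
                raise PredictorError(
                    f"predictor failed on ({window.sequence!r}, {allele!r}): {exc}"
                ) from exc
    return out


def collapse_redundancy(windows: Sequence[PeptideWindow],
                        predictions: Iterable[BindingPrediction],
                        change: ProteinChange) -> dict[str, NeoEpitopeCandidate]:
    """Per allele, keep only the window with the lowest mutant IC50.

    Ties break toward the shorter peptide, then the smaller start, then
    lexicographically — the result depends only on the prediction
    multiset, not its order. Alleles without predictions are absent.
    """
    by_sequence: dict[str, list[PeptideWindow]] = {}
    for w in windows:
        by_sequence.setdefault(w.sequence, []).append(w)

    best: dict[str, tuple[tuple, PeptideWindow, BindingPrediction]] = {}
    for pred in predictions:
        if pred.peptide not in by_sequence:
            raise ValueError(f"prediction for unknown window {pred.peptide!r}")
        for window in by_sequence[pred.peptide]:
            key = (pred.ic50_nm, window.length, window.start, window.sequence)
            if pred.allele not in best or key < best[pred.allele][0]:
                best[pred.allele] = (key, window, pred)

    return {
        allele: NeoEpitopeCandidate(
            change=change, allele=allele, window=window,
            mut_ic50_nm=pred.ic50_nm, binder_class=pred.binder_class)
        for allele, (_, window, pred) in sorted(best.items())
    }


def attach_wild_type(candidate: NeoEpitopeCandidate, context: MutantContext,
                     predictor: BindingPredictor) -> NeoEpitopeCandidate:
    """Score the wild-type peptide at the candidate's coordinates."""
    w = candidate.window
    wt_peptide = context.wild.residues[w.start - 1:w.start - 1 + w.length]
    wt = predictor.predict(wt_peptide, candidate.allele)
    return replace(candidate, wt_ic50_nm=wt.ic50_nm)


def filter_binders(candidates: Iterable[NeoEpitopeCandidate],
                   keep: Iterable[BinderClass] = ("strong",)) -> list[NeoEpitopeCandidate]:
    """Retain candidates whose mutant peptide falls in the kept binder classes."""
    keep = set(keep)
    return [c for c in candidates if c.binder_class in keep]


def candidates_for_change(change: ProteinChange,
                          proteome: Mapping[str, ProteinSequence],
                          predictor: BindingPredictor,
                          alleles: Sequence[str] = DEFAULT_ALLELE_PANEL,
                          lengths: Iterable[int] = DEFAULT_WINDOW_LENGTHS,
                          ) -> list[NeoEpitopeCandidate]:
    """Full per-variant epitope workflow: mutate, enumerate, predict, collapse."""
    if change.gene_symbol not in proteome:
        raise KeyError(f"no protein sequence for gene {change.gene_symbol!r}")
    context = apply_variant_to_protein(proteome[change.gene_symbol], change)
    windows = enumerate_windows(context, lengths)
    predictions = predict_bindings(windows, alleles, predictor)
    collapsed = collapse_redundancy(windows, predictions, change)
    return [attach_wild_type(c, context, predictor) for c in collapsed.values()]


def candidates_to_frame(candidates: Iterable[NeoEpitopeCandidate]) -> pd.DataFrame:
    """Candidate table in the canonical TSV layout."""
    return pd.DataFrame([{
        "gene": c.change.gene_symbol,
        "position": c.change.position,
        "ref_aa": c.change.ref_aa,
        "alt_aa": c.change.alt_aa,
        "allele": c.allele,
        "peptide": c.window.sequence,
        "start": c.window.start,
        "length": c.window.length,
        "variant_offset": c.window.variant_offset,
        "mut_ic50_nm": c.mut_ic50_nm,
        "wt_ic50_nm": c.wt_ic50_nm,
        "binder_class": c.binder_class,
    } for c in candidates])


def frame_to_candidates(df: pd.DataFrame) -> list[NeoEpitopeCandidate]:
    out = []
    for row in df.itertuples():
        change = ProteinChange(str(row.gene), int(row.position),
                               str(row.ref_aa), str(row.alt_aa))
        window = PeptideWindow(str(row.peptide), int(row.start),
                               int(row.length), int(row.variant_offset))
        out.append(NeoEpitopeCandidate(
            change=change, allele=str(row.allele), window=window,
            mut_ic50_nm=float(row.mut_ic50_nm),
            wt_ic50_nm=None if pd.isna(row.wt_ic50_nm) else float(row.wt_ic50_nm),
            binder_class=str(row.binder_class)))
    return out
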