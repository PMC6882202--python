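"""MHC class I binding predictors behind one minimal interface.

The pipeline treats binding prediction as a black box returning, for a
(peptide, allele) pair, a predicted IC50 in nanomolar and a rank-based
binder class (strong / weak / non). Two implementations ship here:

* :class:`TablePredictor` — an adapter for pre-computed tabular output in
  the NetMHCcons style (one row per peptide-allele pair).
* :class:`ToyBindingPredictor` — a fully deterministic, seeded synthetic
  predictor for testing and simulation. Its IC50s are log-uniform hashes
  of the (peptide, allele) pair with an allele-specific anchor-motif
  bonus, and its classes are assigned by fixed per-allele quantiles of
  its own score distribution, mirroring the rank-based class conventions
  of the NetMHC family.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Protocol

import pandas as pd

BinderClass = Literal["non", "weak", "strong"]

#: The 11 frequent class I alleles of the default analysis panel.
DEFAULT_ALLELE_PANEL = (
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01",
    "HLA-C*04:01", "HLA-C*06:02", "HLA-C*07:01", "HLA-C*07:02",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: str
    ic50_nm: float
    binder_class: BinderClass

    def __post_init__(self) -> None:
        if self.ic50_nm <= 0:
            raise ValueError("IC50 must be positive")


class BindingPredictor(Protocol):
    """Anything that deterministically scores a peptide against an allele."""

    def predict(self, peptide: str, allele: str) -> BindingPrediction: ...


class PredictorError(RuntimeError):
    """A predictor could not produce a prediction for a (peptide, allele) pair."""


def _unit_hash(*parts: object) -> float:
    """Deterministic uniform variate in [0, 1) from a string tuple."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


class ToyBindingPredictor:
    """Seeded synthetic predictor with NetMHC-style rank classes.

    IC50 is log-uniform on [ic50_min, ic50_max] nM as a pure hash of
    (seed, allele, peptide). Each allele carries a deterministic anchor
    motif — a (position-2 residue, C-terminal residue) pair — and
    peptides matching both anchors have their IC50 divided by
    ``motif_bonus``, so motif-bearing peptides are systematically
    stronger binders, loosely imitating real anchor preferences.

    Strong / weak classes are assigned at fixed per-allele quantiles
    (default 0.5% and 2%) of the predictor's own score distribution,
    estimated once per allele on a seeded reference sample of random
    9-mers and cached.
    """

    def __init__(self, seed: int = 0, strong_quantile: float = 0.005,
                 weak_quantile: float = 0.02, motif_bonus: float = 200.0,
                 ic50_min: float = 1.0, ic50_max: float = 50000.0,
                 n_reference: int = 50000) -> None:
        if not 0 < strong_quantile < weak_quantile < 1:
            raise ValueError("need 0 < strong_quantile < weak_quantile < 1")
        self.seed = seed
        self.strong_quantile = strong_quantile
        self.weak_quantile = weak_quantile
        self.motif_bonus = motif_bonus
        self.ic50_min = ic50_min
        self.ic50_max = ic50_max
        self.n_reference = n_reference
        self._thresholds: dict[str, tuple[float, float]] = {}

    # -- scoring ---------------------------------------------------------
    def anchor_motif(self, allele: str) -> tuple[str, str]:
        """The allele's (position-2, C-terminal) anchor residues."""
        i = int(_unit_hash("motif2", self.seed, allele) * len(_AA))
        j = int(_unit_hash("motifC", self.seed, allele) * len(_AA))
        return _AA[i], _AA[j]

    def ic50(self, peptide: str, allele: str) -> float:
        u = _unit_hash("ic50", self.seed, allele, peptide)
        span = math.log(self.ic50_max / self.ic50_min)
        value = self.ic50_min * math.exp(u * span)
        p2, cterm = self.anchor_motif(allele)
        if len(peptide) >= 2 and peptide[1] == p2 and peptide[-1] == cterm:
            value /= self.motif_bonus
        return max(value, 1e-6)

    def _reference_peptide(self, index: int) -> str:
        u = _unit_hash("refpep", self.seed, index)
        # expand one uniform into 9 residues via re-hashing per position
        return "".join(_AA[int(_unit_hash("refres", self.seed, index, k) * len(_AA))]
                       for k in range(9))

    def class_thresholds(self, allele: str) -> tuple[float, float]:
        """(strong, weak) IC50 cutoffs for one allele, cached."""
        if allele not in self._thresholds:
            scores = sorted(self.ic50(self._reference_peptide(i), allele)
                            for i in range(self.n_reference))
            s_idx = max(int(self.strong_quantile * self.n_reference) - 1, 0)
            w_idx = max(int(self.weak_quantile * self.n_reference) - 1, 0)
            self._thresholds[allele] = (scores[s_idx], scores[w_idx])
        return self._thresholds[allele]

    def predict(self, peptide: str, allele: str) -> BindingPrediction:
        value = self.ic50(peptide, allele)
        strong_cut, weak_cut = self.class_thresholds(allele)
        if value <= strong_cut:
            cls: BinderClass = "strong"
        elif value <= weak_cut:
            cls = "weak"
        else:
            cls = "non"
        return BindingPrediction(peptide, allele, value, cls)


class TablePredictor:
    """Adapter over NetMHCcons-style tabular predictions.

    Expects a whitespace- or tab-delimited table with one row per
    (peptide, allele) pair; the column names are configurable. Binder
    levels "SB"/"WB" (or "strong"/"weak", case-insensitive) map to the
    strong/weak classes, anything else to non-binder.
    """

    _LEVELS = {"sb": "strong", "strong": "strong",
               "wb": "weak", "weak": "weak"}

    def __init__(self, table: pd.DataFrame, peptide_col: str = "peptide",
                 allele_col: str = "allele", ic50_col: str = "ic50_nm",
                 level_col: str = "binder_level") -> None:
        for col in (peptide_col, allele_col, ic50_col, level_col):
            if col not in table.columns:
                raise ValueError(f"prediction table lacks column {col!r}")
        self._table: dict[tuple[str, str], BindingPrediction] = {}
        for row in table.itertuples():
            peptide = str(getattr(row, peptide_col))
            allele = str(getattr(row, allele_col))
            level = str(getattr(row, level_col)).strip().lower()
            self._table[(peptide, allele)] = BindingPrediction(
                peptide=peptide, allele=allele,
                ic50_nm=float(getattr(row, ic50_col)),
                binder_class=self._LEVELS.get(level, "non"),
            )

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None, **columns) -> "TablePredictor":
        df = pd.read_csv(path, sep=sep if sep is not None else r"\s+",
                         engine="python", comment="#")
        return cls(df, **columns)

    def predict(self, peptide: str, allele: str) -> BindingPrediction:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise PredictorError(
                f"no prediction available for peptide {peptide!r} / allele {allele!r}"
            ) from None


def load_allele_panel(path: str | Path | None = None) -> list[str]:
    """Allele panel from a one-allele-per-line file, or the default 11-allele panel."""
    if path is None:
        return list(DEFAULT_ALLELE_PANEL)
    lines = Path(path).read_text().splitlines()
    panel = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    if not panel:
        raise ValueError(f"allele panel file {path} is empty")
    return panel


def predictions_to_frame(predictions: Iterable[BindingPrediction]) -> pd.DataFrame:
    return pd.DataFrame([{
        "peptide": p.peptide, "allele": p.allele,
        "ic50_nm": p.ic50_nm, "binder_level": p.binder_class,
    } for p in predictions])
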