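"""False-positive robustness of the accessible patient population.

Not every predicted candidate will be immunogenic. To quantify how the
reachable patient fraction degrades if a share of candidates turns out
ineffective, a fixed number of candidates (half-up rounding of the
false-positive fraction times the candidate count) is flagged uniformly
at random, many times over; at each iteration the fraction of patients
matched by the retained candidates — carrying at least one retained
candidate's mutation while their HLA set contains its allele — is
recorded, and the iteration distribution is summarised by its mean,
median and empirical 2.5/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_filtering import ProteinChange

DEFAULT_FP_FRACTIONS = (0.5, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class CandidateKey:
    """A (protein change, HLA allele) candidate pair."""

    change: ProteinChange
    allele: str


@dataclass
class PatientProfile:
    patient_id: str
    study_id: str
    hla_alleles: set[str] = field(default_factory=set)
    changes: set[ProteinChange] = field(default_factory=set)


@dataclass
class ResamplingConfig:
    fp_fractions: tuple[float, ...] = DEFAULT_FP_FRACTIONS
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fp_fractions):
            raise ValueError("false-positive fractions must lie in [0,1]")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class RobustnessSummary:
    fp_fraction: float
    retained_count: int
    fractions: np.ndarray
    mean: float
    median: float
    p2_5: float
    p97_5: float

    @classmethod
    def from_fractions(cls, fp_fraction: float, retained: int,
                       fractions: np.ndarray) -> "RobustnessSummary":
        lo, hi = np.percentile(fractions, [2.5, 97.5])
        return cls(fp_fraction=fp_fraction, retained_count=retained,
                   fractions=fractions, mean=float(np.mean(fractions)),
                   median=float(np.median(fractions)), p2_5=float(lo), p97_5=float(hi))


def flagged_and_retained(total: int, fp_fraction: float) -> tuple[int, int]:
    """Half-up rounded flagged count and the retained remainder.

    674 candidates at fractions 0.50/0.80/0.90/0.95 flag 337/539/607/640
    and retain 337/135/67/34 — half-up is the rounding convention
    reproducing all four.
    """
    if not 0.0 <= fp_fraction <= 1.0:
        raise ValueError("fp_fraction must lie in [0,1]")
    if total < 0:
        raise ValueError("total must be non-negative")
    flagged = int(np.floor(total * fp_fraction + 0.5))
    return flagged, total - flagged


def patient_matched(profile: PatientProfile, candidates: Iterable[CandidateKey]) -> bool:
    """True iff some candidate's mutation AND allele both occur in the profile."""
    return any(c.change in profile.changes and c.allele in profile.hla_alleles
               for c in candidates)


def match_fraction(profiles: Sequence[PatientProfile],
                   candidates: Iterable[CandidateKey]) -> float:
    if not profiles:
        raise ValueError("no patient profiles")
    candidates = list(candidates)
    return sum(patient_matched(p, candidates) for p in profiles) / len(profiles)


def _incidence_matrix(profiles: Sequence[PatientProfile],
                      candidates: Sequence[CandidateKey]) -> np.ndarray:
    """Boolean patients x candidates match matrix."""
    M = np.zeros((len(profiles), len(candidates)), dtype=bool)
    for i, p in enumerate(profiles):
        for j, c in enumerate(candidates):
            M[i, j] = c.change in p.changes and c.allele in p.hla_alleles
    return M


def _sorted_candidates(candidates: Iterable[CandidateKey]) -> list[CandidateKey]:
    return sorted(set(candidates), key=lambda c: (c.change.token, c.allele))


def resample(profiles: Sequence[PatientProfile], candidates: Iterable[CandidateKey],
             config: ResamplingConfig) -> dict[float, RobustnessSummary]:
    """Random-flagging resampling of the matched patient fraction.

    For each false-positive fraction, `n_iterations` uniform draws
    without replacement flag candidates; the retained set's match
    fraction is recorded per iteration. Fully reproducible per seed.
    """
    summaries, _ = _resample_grouped(profiles, candidates, config, by_study=False)
    return summaries


def per_study_summaries(profiles: Sequence[PatientProfile],
                        candidates: Iterable[CandidateKey],
                        config: ResamplingConfig,
                        ) -> dict[tuple[str, float], RobustnessSummary]:
    """Per-study summaries sharing the global flagging draws.

    Within one iteration the same retained candidate set is applied to
    every study, so entities are compared on identical resampled sets.
    """
    _, per_study = _resample_grouped(profiles, candidates, config, by_study=True)
    return per_study


def _resample_grouped(profiles: Sequence[PatientProfile],
                      candidates: Iterable[CandidateKey],
                      config: ResamplingConfig, by_study: bool):
    if not profiles:
        raise ValueError("no patient profiles")
    cand = _sorted_candidates(candidates)
    if not cand:
        raise ValueError("no candidates to resample")
    M = _incidence_matrix(profiles, cand)
    n_cand = len(cand)
    studies = sorted({p.study_id for p in profiles})
    study_rows = {s: np.array([i for i, p in enumerate(profiles) if p.study_id == s])
                  for s in studies}
    rng = np.random.default_rng(config.seed)

    global_summaries: dict[float, RobustnessSummary] = {}
    per_study: dict[tuple[str, float], RobustnessSummary] = {}
    for fp in config.fp_fractions:
        flagged, retained = flagged_and_retained(n_cand, fp)
        fractions = np.empty(config.n_iterations)
        study_fracs = {s: np.empty(config.n_iterations) for s in studies}
        for it in range(config.n_iterations):
            keep = np.ones(n_cand, dtype=bool)
            if flagged:
                keep[rng.choice(n_cand, size=flagged, replace=False)] = False
            matched = M[:, keep].any(axis=1) if retained else np.zeros(len(profiles), bool)
            fractions[it] = matched.mean()
            if by_study:
                for s in studies:
                    study_fracs[s][it] = matched[study_rows[s]].mean()
        global_summaries[fp] = RobustnessSummary.from_fractions(fp, retained, fractions)
        if by_study:
            for s in studies:
                per_study[(s, fp)] = RobustnessSummary.from_fractions(
                    fp, retained, study_fracs[s])
    return global_summaries, per_study


# ---------------------------------------------------------------------------
# profile IO

def load_profiles(path: str | Path) -> list[PatientProfile]:
    """Profiles TSV: patient_id, study_id, hla_alleles (;-sep), changes (;-sep tokens)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples():
        alleles = {a for a in str(row.hla_alleles).split(";") if a}
        changes = {ProteinChange.from_token(t) for t in str(row.changes).split(";") if t}
        out.append(PatientProfile(str(row.patient_id), str(row.study_id),
                                  alleles, changes))
    return out


def profiles_to_frame(profiles: Iterable[PatientProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": p.patient_id,
        "study_id": p.study_id,
        "hla_alleles": ";".join(sorted(p.hla_alleles)),
        "changes": ";".join(sorted(c.token for c in p.changes)),
    } for p in profiles])


def summaries_to_frame(summaries: dict, per_study: bool = False) -> pd.DataFrame:
    rows = []
    for key, s in summaries.items():
        row = {}
        if per_study:
            row["study_id"], row["fp_fraction"] = key
        else:
            row["fp_fraction"] = key
        row.update(retained_count=s.retained_count, mean=s.mean, median=s.median,
                   p2_5=s.p2_5, p97_5=s.p97_5)
        rows.append(row)
    return pd.DataFrame(rows)
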