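"""Cohort QC: homopolymer-context artifact screening and gene-class enrichment.

Variant calls sitting inside long single-nucleotide repeats (poly-A/C/G/T
runs) are a classic sequencing-artifact signature. Each variant carries
its 11-base reference context (mutated base at the center, 5 flanking
bases each side); a call is "in a repeat" when a maximal run of identical
bases covering the center has length >= min_run (default 6). The observed
per-study fraction of such calls is compared against the fraction
expected if all 11-mers were equiprobable, via an exact upper binomial
tail, with Benjamini-Hochberg correction across studies.

A separate Pearson chi-square test asks whether variant sets (e.g. all
changes vs recurrent changes) are enriched in known oncogenes and tumor
suppressor genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NUCLEOTIDES = "ACGT"


@dataclass
class QcStudyResult:
    study_id: str
    n_variants: int
    n_in_repeat: int
    expected_fraction: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def in_homopolymer(context: str, min_run: int = 6) -> bool:
    """Whether the center base of an odd-length context sits in a run >= min_run.

    Only a maximal run of identical bases that *covers* the center
    position counts; adjacent runs not containing the variant base do
    not.
    """
    if len(context) % 2 == 0 or not context:
        raise ValueError("context must have odd length")
    bad = set(context) - set(NUCLEOTIDES)
    if bad:
        raise ValueError(f"non-ACGT base(s) in context: {sorted(bad)}")
    center = len(context) // 2
    base = context[center]
    run = 1
    for i in range(center - 1, -1, -1):
        if context[i] != base:
            break
        run += 1
    for i in range(center + 1, len(context)):
        if context[i] != base:
            break
        run += 1
    return run >= min_run


def expected_repeat_fraction(min_run: int, window: int = 11) -> float:
    """Exact P(center base lies in a run >= min_run) under iid uniform bases.

    The run covering the center is 1 + L + R where L and R are the
    matching extensions into each flank; each extension is geometric
    with success 1/4, truncated at the flank width. The closed form sums
    the exact rational mass of 1 + L + R >= min_run; `enumerate_repeat_fraction`
    recomputes it by brute force over all 4^window sequences.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if not 1 <= min_run <= window:
        raise ValueError("need 1 <= min_run <= window")
    m = window // 2  # flank width
    q = Fraction(1, 4)

    def ext_pmf(k: int) -> Fraction:
        return q**k * (1 - q) if k < m else q**m

    total = Fraction(0)
    for left in range(m + 1):
        for right in range(m + 1):
            if 1 + left + right >= min_run:
                total += ext_pmf(left) * ext_pmf(right)
    return float(total)


def enumerate_repeat_fraction(min_run: int, window: int = 11) -> float:
    """Brute-force enumeration of all 4^window contexts (vectorized)."""
    if window % 2 == 0 or not 1 <= min_run <= window:
        raise ValueError("window must be odd with 1 <= min_run <= window")
    n = 4 ** window
    idx = np.arange(n, dtype=np.int64)
    digits = np.empty((n, window), dtype=np.int8)
    for pos in range(window):
        digits[:, pos] = (idx >> (2 * pos)) & 3
    center = window // 2
    eq = digits == digits[:, [center]]
    left = np.cumprod(eq[:, center - 1::-1], axis=1).sum(axis=1) if center else 0
    right = np.cumprod(eq[:, center + 1:], axis=1).sum(axis=1) if center else 0
    runs = 1 + left + right
    return float(np.count_nonzero(runs >= min_run) / n)


def repeat_tail_probability(n_in_repeat: int, n_variants: int, p0: float) -> float:
    """Upper binomial tail P(X >= n_in_repeat), X ~ Binomial(n_variants, p0)."""
    if not 0 <= n_in_repeat <= n_variants:
        raise ValueError("need 0 <= n_in_repeat <= n_variants")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0,1]")
    if n_in_repeat == 0:
        return 1.0
    return float(stats.binom.sf(n_in_repeat - 1, n_variants, p0))


def bh_adjust(p_values: Sequence[float], alpha: float = 0.05,
              ) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up adjusted p values and rejection flags."""
    if len(p_values) == 0:
        return [], []
    reject, adjusted, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return [float(p) for p in adjusted], [bool(r) for r in reject]


def run_repeat_qc(contexts: pd.DataFrame, unique_only: bool,
                  min_run: int = 6, window: int = 11, alpha: float = 0.05,
                  ) -> tuple[list[QcStudyResult], int]:
    """Per-study homopolymer QC over one occurrence branch.

    `contexts` needs columns study_id, context (the reference window)
    and n_occurrences (patients carrying the variant in the cohort);
    `unique_only` selects the singleton branch (n_occurrences == 1)
    versus the recurrent branch (> 1). Rows with a missing context are
    excluded and counted. BH correction runs across the studies of the
    selected branch.
    """
    p0 = expected_repeat_fraction(min_run, window)
    missing = contexts["context"].isna() | (contexts["context"].astype(str).str.len() == 0)
    n_excluded = int(missing.sum())
    usable = contexts[~missing]
    branch = usable[usable["n_occurrences"] == 1] if unique_only \
        else usable[usable["n_occurrences"] > 1]

    results: list[QcStudyResult] = []
    for study in sorted(branch["study_id"].unique()):
        ctxs = branch.loc[branch["study_id"] == study, "context"].astype(str)
        n = len(ctxs)
        k = sum(in_homopolymer(c, min_run) for c in ctxs)
        results.append(QcStudyResult(
            study_id=str(study), n_variants=n, n_in_repeat=k,
            expected_fraction=p0,
            p_value=repeat_tail_probability(k, n, p0)))
    adjusted, rejected = bh_adjust([r.p_value for r in results], alpha)
    for r, adj, rej in zip(results, adjusted, rejected):
        r.p_adjusted, r.significant = adj, rej
    return results, n_excluded


def qc_results_to_frame(results: Iterable[QcStudyResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "study_id": r.study_id, "n_variants": r.n_variants,
        "n_in_repeat": r.n_in_repeat, "expected_fraction": r.expected_fraction,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        "significant": r.significant,
    } for r in results])


# ---------------------------------------------------------------------------
# gene-class enrichment

def enrichment_chisq(table: pd.DataFrame | np.ndarray,
                     ) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a contingency table.

    Returns (statistic, degrees of freedom, p value). Zero row/column
    margins are a hard error (the expected counts would vanish).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("negative cell counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def gene_class_table(variant_sets: Mapping[str, Iterable[str]],
                     gene_classes: Mapping[str, str],
                     classes: Sequence[str] = ("oncogene", "tsg", "other"),
                     ) -> pd.DataFrame:
    """Counts of genes-of-variants per annotation class, one row per variant set.

    `variant_sets` maps a set label (e.g. "all", "recurrent") to the
    genes of its variants (with multiplicity, as provided); genes absent
    from `gene_classes` count as "other".
    """
    rows = {}
    for label, genes in variant_sets.items():
        counts = dict.fromkeys(classes, 0)
        for gene in genes:
            counts[gene_classes.get(gene, "other")] += 1
        rows[label] = counts
    return pd.DataFrame.from_dict(rows, orient="index")[list(classes)]


def load_gene_classes(path) -> dict[str, str]:
    """TSV with columns gene, class in {oncogene, tsg, other}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    valid = {"oncogene", "tsg", "other"}
    table = {str(g): str(c) for g, c in zip(df["gene"], df["class"])}
    bad = set(table.values()) - valid
    if bad:
        raise ValueError(f"unknown gene classes: {sorted(bad)}")
    return table
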