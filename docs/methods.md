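# Methods

## Problem and scope

`recurneo` identifies somatic missense variants that recur across patients
of a cancer entity, derives MHC class I neo-epitope candidates from them,
and ranks the candidates by the number of patients expected to benefit.
The package operates strictly downstream of somatic variant calling: it
consumes MAF-dialect variant tables with read counts and a precomputed
maximum population allele frequency column, a clinical membership table,
protein sequences in FASTA, and binding predictions through a pluggable
interface. Variant calling, liftover, live population-database queries and
the internals of binding predictors are out of scope by design and treated
as preprocessing contracts.

## Variant filtering

A record survives when all of the following hold, applied as an ordered
cascade with per-stage bookkeeping (`in = out + rejected` at every stage):

1. *read*: all required MAF columns present; rows with a missing required
   field (notably an empty transcript ID) are rejected at read time, never
   imputed.
2. *consistency*: `Mutation_Status` equals "somatic" case-insensitively
   (the one case-insensitive field); `t_depth = t_ref_count + t_alt_count`
   exactly; ref and alt alleles are single nucleotides.
3. *missense SNV*: `Variant_Type == "SNP"`,
   `Variant_Classification == "Missense_Mutation"`, non-empty transcript,
   and a parsable single-residue exchange in `HGVSp_Short`
   (`p.<ref><pos><alt>`, standard 20-letter residues, ref ≠ alt).
4. *read support*: ≥ 5 alternate-allele reads **and** VAF ≥ 10%, both
   inclusive. The support threshold is interpreted on alternate reads, not
   total depth: a total-depth reading would admit single-read variants at
   any VAF ≥ 10%, defeating the false-positive rationale of the filter.
5. *population AF*: records whose annotated maximum population allele
   frequency is **strictly greater** than 1% are dropped; absent
   annotations are kept (absence of evidence).

Filtered records collapse to a (patient, protein change) carrier relation;
distinct genomic SNVs producing the same amino-acid exchange in one patient
count once (codon redundancy).

## Recurrence

Recurrence is defined at the protein level within each study. The
denominator is the full count of patients with clinical information,
including patients contributing no surviving variant — a deliberately
conservative choice. A change is recurrent when carriers / cohort ≥ 1%
(inclusive); cohorts with ≤ 100 patients are excluded (the eligibility
default is ≥ 101; the two readings "at least 100" and "more than 100" both
circulate, and only the strict reading guarantees every recurrent call has
at least two carriers, which is why it is the default — both are
configurable). Frequencies are carried as exact rationals
(`fractions.Fraction`), so the threshold comparison is never subject to
float rounding. Derived views: unique changes across studies, codon-merged
groups (e.g. IDH1 R132 mutated to H/C/G/S forms one group), and overlap
counting against a user-supplied hotspot list with an optional
presumptive-false-positive flag.

## Peptide generation

For each unique recurrent change the mutant protein is built (hard error
on reference-residue mismatch), and every 9-, 10- and 11-mer window that
lies fully inside the protein and contains the exchanged residue is
enumerated — 30 windows at interior positions, fewer near the termini.
Each window is scored against the default 11-allele panel (HLA-A*01:01,
A*02:01, A*03:01, A*11:01, B*07:02, B*08:01, B*15:01, C*04:01, C*06:02,
C*07:01, C*07:02). Overlap redundancy is collapsed per (variant, allele) to
the window with the lowest predicted **mutant** IC50; ties (possible with
coarse predictor output) break toward the shorter peptide, then the
smaller start coordinate, then lexicographic peptide order — the result is
a function of the prediction multiset only. The wild-type peptide at the
same coordinates is scored for comparison but plays no role in
classification, which uses the mutant peptide's rank-based class from the
predictor. Protein sequences are matched by FASTA id (gene symbol or
transcript); isoform choice is the caller's responsibility.

## Binding predictors

Predictors are pluggable behind a one-method interface returning
(IC50 nM, class ∈ {non, weak, strong}) per (peptide, allele).

* `TablePredictor` adapts precomputed NetMHCcons-style tables
  ("SB"/"WB" → strong/weak, anything else non-binder); a missing pair is a
  hard error carrying the pair.
* `ToyBindingPredictor` is a deterministic synthetic predictor for testing
  and simulation: IC50 is a log-uniform hash of (seed, allele, peptide) on
  [1, 50000] nM; each allele has a deterministic anchor motif (a
  position-2/C-terminal residue pair) whose match divides IC50 by 200,
  imitating anchor preferences; classes are assigned at fixed per-allele
  quantiles (strong 0.5%, weak 2%) of the predictor's own score
  distribution, estimated on a seeded 50 000-peptide reference sample —
  mirroring the rank-based class conventions of the NetMHC family. The
  quantiles are configuration, not a biological claim.

## Expected-patient ranking and coverage

For a candidate (change v, allele h) the ranking statistic is

    n_h = f_h * sum_d r_{v,d} * N_d

summed over diseases present in both the incidence table and the observed
frequency table. r_{v,d} is the observed per-cohort carrier fraction for
**all** eligible cohorts, sub-threshold frequencies included — the
recurrence call only gates which variants become candidates, not which
cohorts contribute patients. f_h is used as the allele frequency as
printed; an optional diploid flag substitutes the carrier frequency
1 − (1 − f_h)², since the convention behind published per-allele patient
tables is ambiguous. Expected counts are kept as reals internally and
additionally rounded for display.

Coverage cells aggregate candidates assuming variant occurrences are
statistically independent of each other and of HLA type:
cell(d, h) = N_d · f_h · (1 − Π_v (1 − r_{v,d})) over changes v with a
candidate for h. Cells obey the union bound with equality iff at most one
r is nonzero, are monotone in candidate sets and frequencies, and scale
linearly in N_d. A bundled U.S. reference fixture provides the 11 panel
allele frequencies (AFND North-American averages, e.g. HLA-A*02:01 at
20.36%) and 18 annual incidence values (GLOBOCAN 2012, e.g. melanoma
75 000); their sum, 1 161 958, is asserted in tests. Study → disease
mapping is identity by default, with an explicit mapping accepted.

## Robustness resampling

Given per-patient profiles (HLA allele set + protein-change set) and a
candidate set, a patient is *matched* when some candidate's change is in
the patient's change set **and** its allele is in the patient's HLA set.
For each false-positive fraction (defaults 50/80/90/95%), the flagged count
is the half-up rounded product of fraction and candidate count — the only
rounding convention consistent with flagging 337/539/607/640 of 674 — and
1000 iterations flag that many candidates uniformly without replacement,
recording the retained set's match fraction. Summaries report mean, median
and the empirical 2.5/97.5 percentiles (linear interpolation between order
statistics) as the 95% interval. Per-study summaries reuse the same
flagging draw within an iteration, so entities are compared on identical
retained sets. One named, seeded generator owns all randomness.

## Homopolymer QC and enrichment

Each variant carries its 11-base reference context (mutated base central,
5 flanking bases each side; the reference context, as alignment-artifact
propensity is reference-defined). A call is "in a repeat" when a maximal
run of identical bases **covering the center** has length ≥ 6; adjacent
runs not containing the variant base do not count. The expected fraction
under an equiprobable-context null is computed exactly in closed form: the
run covering the center is 1 + L + R with L, R independent flank-truncated
geometric extensions (match probability 1/4), giving 0.004638671875 for
runs ≥ 6 in 11-mers; a vectorised full enumeration of all 4^11 contexts is
implemented alongside and the two are cross-checked in tests for windows
3–11. Observed counts are tested with the exact upper binomial tail
(no normal approximation), Benjamini–Hochberg corrected across studies,
with the singleton branch (variants seen once per cohort) and the
multi-occurrence branch corrected separately. The run-length threshold is
configurable: ≥ 6 is the default, with the "> 6" reading available, as
both conventions appear in practice.

Gene-class enrichment (oncogene / tumor suppressor / other) uses Pearson's
χ² of independence without continuity correction; zero margins are a hard
error.

## Synthetic data

The generator emulates tumor/normal whole-exome cohort tables:

* **proteome** — uniform-random 20-letter sequences, minimum length 23 so
  interior positions admit all 11-mers.
* **cohorts** — default two studies of 400 and 250 patients (within the
  typical range of cohort sizes in public pan-cancer studies); planted
  changes get exact carrier counts or Binomial(n, f) carriers; background
  changes (Poisson mean 3 per patient) are unique across the cohort so no
  accidental recurrence can contaminate the planted truth; read depth is
  negative-binomial (mean 80, dispersion 10, floored at 30); VAF is
  Beta(8, 12) (mean 0.4, as in moderately impure tumors) truncated to keep
  pass/fail labels correct.
* **contaminants** — ten labelled violation types, each breaking exactly
  one filter stage (read, consistency, missense selection, support,
  population AF); truth records the MAF row indices per label.
* **HLA genotypes** — two independent draws per locus from per-locus allele
  frequencies (Hardy–Weinberg), remainder mass going to an anonymous
  non-panel allele.
* **nucleotide coordinates** are fabricated consistently (one gene per
  contig, codon start at 3·pos − 2) since downstream stages use only
  protein-level identity and the separately generated 11-base contexts.

What the simulation does **not** emulate: mutational signatures, gene
length/expression biases, linkage between HLA loci, shared background
mutations, or realistic binding physics. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic, determinism and
recovery behaviour — not predictive validity on real tumors.

## Numerical and design choices

* Recurrence threshold comparisons in exact rational arithmetic; all other
  statistics in double precision with explicit tolerances in tests.
* Deterministic sort orders everywhere a list is emitted (study, descending
  frequency, then lexicographic change key; candidates by n_h descending
  with lexicographic tie-break), so outputs are diffable.
* All intermediate artifacts persist as TSV; any stage can be re-run from
  the previous stage's file and yields identical results.
* Problem sizes in the test suite and acceptance script (two-study cohorts
  of a few hundred patients, 1000 resampling iterations, 10⁵-peptide
  predictor checks) are chosen so the full suite completes in a few
  minutes on one CPU while keeping Monte-Carlo standard errors well inside
  the asserted 2–3 SE bands.

## Known limitations

* Binding classification relies entirely on the plugged-in predictor; the
  toy predictor's scores carry no biology.
* The expected-patient model assumes cohort frequencies transfer to the
  incident population and that mutation and HLA type are independent; both
  are approximations.
* Sample-to-patient identity is taken from the clinical table by exact
  match; multi-sample donors are not merged beyond that.
* Indels, splice variants and class II prediction are out of scope.
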