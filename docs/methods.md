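# Methods

## Signal model

`pharmsig` screens candidate adverse drug events (ADEs) for one
(drug, indication) pair from two independent data streams and reconciles
the results against ADE knowledge bases.

**Reports stream.** Spontaneous reports are treated as exchangeable
drug/reaction co-mention records.  For each candidate outcome the report
population is partitioned into the standard disproportionality 2×2 table
and scored with the reporting odds ratio ROR = (a·d)/(b·c).  The ROR is a
measure of reporting imbalance, not incidence: the underlying assumption
is that, absent an association, an outcome is reported with the drug at
the same rate as with all other drugs.  Candidate outcomes are the
reaction codes appearing on reports that carry both the drug and the
indication; the comparator population for cells c and d is, by default,
the entire loaded report set (`comparator="all"`), with an
indication-restricted alternative available.  The signal rule is
one-sided: the 95% confidence interval's lower bound must exceed 1.

**Records stream.** Patient timelines are analysed with a case-crossover
design: each cohort member (≥1 indication diagnosis, ≥1 drug exposure,
earliest diagnosis strictly before first exposure) contributes a control
window `[t_dx, t_first)` and a case window `[t_first, t_last]`.  Outcome
occurrence is binary per window (≥1 mention; multiplicity is ignored), so
both rows of the resulting table cover the same cohort, a+b = c+d = n.
The analysis is *unconditional*: a pooled odds ratio over the two windows,
not a matched-pair (conditional/McNemar) estimate.  Self-matching removes
time-invariant confounders; it does not protect against time-varying ones
(disease progression, co-medication).  The signal rule is joint: CI lower
bound > 1 and two-sided p < 0.05.

**Interval and corrections.** Both streams share the Woolf (log-normal)
interval `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))` with z = 1.96.  If any cell
is zero the Haldane–Anscombe correction adds 0.5 to all four cells before
estimation (logged per table); a table with all four cells zero is an
error.  P-values use Pearson's χ² without continuity correction, switching
to Fisher's exact test whenever any expected cell is below 5
(`p_method="auto"`; both are selectable).  Bonferroni correction
multiplies p by the number of candidate outcomes tested for the drug
(overridable via `bonferroni_m`), capped at 1.

**Mapping and metrics.** All sources are joined on UMLS-style concept
identifiers (CUIs).  Exact mapping intersects flagged CUIs with the
knowledge base's CUIs.  Flexible mapping first expands every
knowledge-base term downward through the 5-level hierarchy (transitively,
to the lowest level terms; never upward), so specific detected terms match
broader recorded ones.  Precision = matched/discovered.  Recall divides by
the **un-expanded** confirmed set: expansion widens what counts as a
match, but inflating the denominator with thousands of descendants would
make exact and flexible recall incomparable.  In the rare case where more
discovered terms match than the knowledge base has entries, recall is
capped at 1.  F1 is the harmonic mean.  Combining sources takes the union
of flagged outcomes (per-outcome provenance retained; the record-stream
score, which carries a p-value, represents shared outcomes).  Flagged
outcomes outside the expanded knowledge base are ranked by descending odds
ratio (ties: ascending p, then CUI) as novel-ADE hypotheses — possibly
false positives, possibly genuinely unrecorded ADEs.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `z` | 1.96 | normal quantile of the 95% interval |
| `min_a` | 1 | minimum drug-and-outcome report count for a report-stream candidate (3 is common practice for sparse report databases) |
| `min_patients` | 1 | minimum case-window patients for a record-stream candidate |
| `p_method` | auto | χ², Fisher below expected cell 5 |
| `bonferroni_m` | n. candidates | multiple-comparison family size |
| `comparator` | all | population for report-stream cells c, d |
| `top_k` | 10 | novel-hypothesis table truncation |

Interval conventions: a mention on the first-exposure day belongs to the
case window (an on-treatment day is exposure).  A single-exposure patient
has a one-day case window; `exposure_tail_days` (default 0) can extend the
case window for drug persistence.  Outcomes that are the indication or one
of its hierarchy descendants are *flagged* as possible
confounding-by-indication, never excluded — indication-related
deterioration is a real and informative finding.

Concept mentions are restricted to the UMLS semantic types relevant to
clinical outcomes: Finding (T033), Laboratory or Test Result (T034), Sign
or Symptom (T184), Disease or Syndrome (T047), Mental or Behavioral
Dysfunction (T048), Neoplastic Process (T191), Cell or Molecular
Dysfunction (T049).  Drug-exposure and diagnosis events pass through the
filter untouched.

## Synthetic data: what it emulates, what it does not

The generator stands in for four licensed/large resources: a normalized
spontaneous-report extract, NLP-derived clinical-note concept streams, and
SIDER-/ADReCS-dialect knowledge-base files, over a generated 5-level
hierarchy.  A single master seed spawns independent per-stream generators
(reports, timelines, knowledge base), so any one table can be regenerated
without perturbing the others and equal seeds give byte-identical files.

Planted effects are analytic.  In reports, a (drug, outcome, target ROR)
triple sets P(outcome | exposed) so that the implied cell-probability odds
ratio equals the target exactly; infeasible configurations (implied
probability outside (0,1), non-positive target) are rejected at validation
time, not by rejection sampling.  In timelines, occurrence is one
Bernoulli draw per (patient, outcome, window): closed-form truth
OR = p_case(1−p_control)/((1−p_case)p_control).  Background outcomes use
one probability, `1 − exp(−background_mention_rate)` over a nominal
patient-year, in *both* windows, so their truth OR is exactly 1 regardless
of window lengths.  This deliberately sacrifices realism (longer windows
do not accumulate more occurrences) to make the null exact; a Poisson
mention process would reintroduce window-length confounding that the
unconditional design does not adjust for.

The bundled study conditions: 5,000 reports, 2,000 patients over 20 years
of observation, a (2,3,3,3)-branching hierarchy (81 terms, 54 leaves), 20
candidate outcomes, background reaction probability 0.02, background
mention rate 0.05/patient-year, exposure prevalence 0.10 in reports, 10%
of patients violating the cohort definition, 2% off-semantic-type noise
mentions.  Five planted ADEs (ROR 8; window probabilities 0.3 vs 0.1) sit
under five different preferred terms; the knowledge base records three of
them — two at their own level, one only at its parent preferred term, so
flexible mapping is genuinely exercised — plus three confirmed ADEs
outside the mention pool, and a decoy label under a different indication
whose terms must never survive the indication-restricted extraction.

Passing tests on these data show that the estimators, counting rules,
mapping and bookkeeping are correct, and that effects of the planted
strength are recovered at these sample sizes.  They do not show robustness
to what the generator omits: duplicate and incomplete reports, coding
noise, correlated outcomes, drug–drug interactions, carry-over of a
previous drug into the control window, or time-varying confounding.

## Numerical and design notes

- Hierarchy edges must connect adjacent levels, which structurally rules
  out cycles; multiple parents are allowed and expansion runs on the DAG.
  Serialization is canonical (one row per term–parent edge, sorted by
  term then parent code), so load → save round-trips bit-identically.
- The Woolf interval is asymptotic.  Its one-sided error at the nominal
  2.5% level is accurate for moderate cells but *anticonservative at
  small counts*: pure-binomial simulation of the report-stream null gives
  ≈2.9% at expected a ≈ 40 and ≈5% at expected a ≈ 4 (where conditioning
  on a ≥ 1 for candidacy also biases selection).  Practitioners screening
  rare outcomes should raise `min_a` or treat borderline lower bounds
  with caution.  The record-stream joint rule (CI and p) is conservative
  by construction.
- The test suite sizes its simulations for single-CPU runs: interval
  coverage and ln-OR recovery use 500 replicates of 2,000-patient cohorts;
  Type-I checks use ~1,900 null outcome-tests for the record stream and
  400 for the report stream (at 20,000 reports, inside the Wald
  asymptotic regime); end-to-end planted-ADE recovery uses 100 seeds at
  the full study size.
- Demographic summaries follow reporting-table conventions: report-stream
  gender percentages are taken over the full report count including
  unknown gender (so they need not sum to 100%); patient-stream
  percentages over the female+male sum; the F:M ratio is rounded half-up
  to one decimal; a zero male count yields an undefined (None) ratio.
- Ranking is fully deterministic: descending odds ratio, then ascending
  p-value, then lexicographic CUI.

## Limitations

Single-institution-style timelines with one focal drug; no NLP (inputs
are already-extracted, UMLS-normalized events — negation or sectioning
errors upstream propagate); no duplicate-report detection; no
standardised MedDRA queries or licensed-terminology handling; no
carry-over washout between control and case windows; semantic-granularity
mismatches are only partially addressed by downward expansion.
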