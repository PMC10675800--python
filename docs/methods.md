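# Methods

## The screening model

`faersig` implements disproportionality screening of a spontaneous
adverse-event report database. The unit of analysis is the *report*: one
deduplicated case version carrying a set of suspect drugs and a set of MedDRA
preferred terms (PTs). For a drug *D* and event *E* the database reduces to a
2×2 table

|                    | event (+) | event (−) |
|--------------------|-----------|-----------|
| reports with *D*   | a         | b         |
| comparator reports | c         | d         |

and the reporting odds ratio is ROR = (a/b)/(c/d) = ad/(bc). Disproportionality
statistics carry no denominator of drug *use*; an elevated ROR means the event
is over-represented *among reports* of the drug, not that the drug causes the
event at that rate.

### Comparator conventions

Two conventions for the comparator row are implemented behind the
`comparator` flag:

* `other_reports` — c and d count reports **without** the drug. The four
  cells partition the database; this is the convention of standard
  pharmacovigilance ROR tooling.
* `all_reports` (default) — c and d count **all** reports, drug reports
  included. This is the convention the package's per-event summary tables are
  defined against. Because drug reports appear in both rows, the `all_reports`
  ROR is shrunk toward 1 relative to `other_reports`; the two converge as the
  drug's report share goes to zero.

The default follows the summary-table definition; the documentation of every
output states which convention produced it, and nothing downstream depends on
the choice except the lnROR values themselves.

### Continuity correction, CI, and the exact test

The Haldane–Anscombe correction adds 0.5 to **all four cells
unconditionally** (not only when a zero is present), so lnROR is finite for
every pair including drugs or events with zero reports. The 95% CI is the
log-scale Wald interval on corrected counts,
exp(lnROR ± z·√(1/a′+1/b′+1/c′+1/d′)) with z = 1.959964.

The two-sided Fisher exact p uses the point-probability rule: the sum of
hypergeometric probabilities of all tables with the observed margins whose
probability is ≤ the observed table's, with a relative tie tolerance of 1e−7
(the dominant convention in scientific software). It runs on **raw integer
counts** — the correction affects only ROR/CI — and always on the
*partition* (`other_reports`) cells, because the hypergeometric model assumes
the four cells partition the reports; feeding it the `all_reports` cells
would double-count the drug's reports in the margins and destroy the test's
calibration. The comparator flag therefore changes ROR/CI only, never p.
The implementation vectorizes the hypergeometric pmf over the support with a
cached log-factorial table (~10 µs/table), which is what makes exhaustive
small-table verification and whole-database screens cheap; the test suite
checks it against exact integer enumeration on every table with margins ≤ 30
and against `scipy.stats.fisher_exact` on random tables.

Significance is declared at α = 0.05 with **no multiple-testing adjustment**;
in this screening design the report-count filter (below) plays the
false-discovery-limiting role, and the p-value is a screen, not an inference.

Degenerate pairs (a drug or event with zero reports) get a finite corrected
ROR but an undefined exact test; they are emitted with p = NaN and
`significant = False` so result grids stay rectangular.

## Event extraction and the signal matrix

The lnROR values form a drugs × events grid. Each event carries its total
report count over the whole database and the **unweighted** arithmetic mean
of its lnROR column over the drug panel (no weighting by drug report counts:
the mean answers "is this event over-reported for the panel as a class",
which should not be dominated by the most-reported drug). Filters are strict
inequalities: events with totals **>** `min_event_reports` (default 100,000,
the scale appropriate to a multi-year full-database extract; set it to the
data at hand) and, when `require_positive_mean` is on, mean lnROR **> 0**
(a mean of exactly 0 is excluded). Display values round half away from zero
to 2 decimals, which makes the summary's printed ROR column equal
`round(exp(mean lnROR), 2)` by construction.

## Two-way Ward clustering

Drugs are clustered with events as features, events with drugs as features,
both on **raw** (not display-rounded, not standardized) lnROR values;
column z-scoring is available behind a flag but off by default since lnROR
columns already share a scale. The linkage is Ward's minimum-variance
criterion via the Lance–Williams recurrence on squared Euclidean distances;
the dissimilarity carried for a pair of clusters equals twice the ESS
increase their merger would cost. Merge heights are reported as the square
root of that quantity (the Ward.D2 convention: two singletons merge at their
Euclidean distance), with the raw squared value available via
`height_convention="squared"`. Ward with Euclidean distance is reducible, so
heights are non-decreasing; the suite asserts this on every tree it builds.

Numerical choices: equal-dissimilarity ties break to the smallest
(left, right) node-index pair, making results order-stable; cutting at k
takes the partition after n−k merges, with cluster ids numbered 1..k by first
appearance in the dendrogram leaf order (depth-first, lower-index child
first). The implementation is checked two ways: against exhaustive
step-wise ESS minimization on small random matrices, and against
`scipy.cluster.hierarchy.linkage(method="ward")` heights on tie-free data.
Default cut counts are k_drugs = 5 and k_events = 7, matching the shape of
an 11-opioid × 47-event screen; they are explicit parameters for any other
matrix shape. Whether to cut at an explicit k or read clusters off the
dendrogram is a genuine design choice; the package requires explicit k so
results are reproducible.

## The synthetic report generator

The generator emulates what the pipeline consumes, not the epidemiology of
FAERS. Per report:

* each drug enters independently with its marginal probability, so
  drugs-per-report follows the induced Poisson-binomial law (reports with no
  suspect drug are legitimate and contribute to background totals);
* each event enters with probability min(1, baseline × θ_eff), where
  θ(drug, event) is a planted reporting-rate multiplier (θ = 1 ⇒ no
  association) and θ_eff aggregates the multipliers of the report's drugs —
  by maximum by default (a report's most-implicated drug drives the event's
  reporting), or by product via `aggregation="product"`. A drug-free report
  has θ_eff = 1. Cap hits (baseline × θ_eff > 1) are counted and reported.

File rendering adds the artefacts ingestion must undo: drug names drawn from
salt/hydrate/case variants ("MORPHINE SULFATE", "morphine hydrochloride", …),
PS/SS role codes with occasional concomitant (role C) rows that must be
filtered out, and a configurable fraction of cases emitted with a superseded
earlier version whose DEMO row differs only in demographics — so a
deduplication bug is visible purely as an inflated report count. Identical
seeds give byte-identical files.

`expected_lnror` evaluates the asymptotic lnROR of a pair exactly by
enumerating inclusion patterns of the drugs relevant to the event (the target
plus all drugs with θ ≠ 1 for it). Under `max` aggregation a present
non-relevant drug (θ = 1) lifts the maximum to ≥ 1, so its aggregate presence
probability enters the enumeration; capped pairs are rejected (no closed
form). This oracle is what parameter-recovery tests compare pipeline
estimates against.

What the generator does **not** emulate: realistic demographics, reporting
trends over time, event-event correlation beyond shared drugs,
drug–drug interaction signals, misspelled drug names, or MedDRA hierarchy.
Passing recovery and calibration tests therefore demonstrates correctness of
the computation under the generator's independence assumptions, not
robustness to real FAERS messiness.

## Verification studies and problem sizes

The suite's full-scale studies (also recomputed by `scripts/acceptance.py`)
use these sizes, chosen to make the Monte-Carlo error small relative to each
check's acceptance band while keeping a full run within a few minutes on one
CPU:

* **Fisher vs enumeration** — every 2×2 table with all margins ≤ 30
  (164,175 tables), agreement to 1e−10 against exact integer arithmetic.
* **Ward step-wise optimality** — 100 random matrices with 3–7 rows,
  exhaustive candidate-merge search at every step.
* **Wald coverage** — ~5,000 tables, 2,000 reports per arm, true odds ratio
  θ ∈ {0.5, 1, 4}, baseline event rate 0.2; observed coverage ≈ 95%.
* **Null calibration** — 200,000 reports, 25 drugs × 200 events = 5,000
  pairs, θ ≡ 1; drug marginals uniform on [0.01, 0.03] and event baselines
  uniform on [0.01, 0.05], so expected a-cells are ≥ 20 — the common-event
  regime the report-count filter targets, where the exact test's discreteness
  no longer dominates and the rejection fraction at α = 0.05 should sit near
  the nominal level (observed ≈ 0.05).
* **Parameter recovery** — 200 replicates of 50,000 reports; planted pairs
  at θ = 4, 2 and 0.5; mean corrected lnROR within 3 standard errors of the
  closed form.
* **Cluster recovery** — 100,000 reports, two drug groups × two event groups
  at profile separation ln 4, run through the complete file-based pipeline
  (render → ingest → map → screen → filter → cluster); both partitions
  recovered with adjusted Rand index 1.

## Known limitations

* Substring name mapping is deliberately dictionary-free; it resolves the
  nested-name collisions of its target list (CODEINE/DIHYDROCODEINE,
  MORPHINE/APOMORPHINE, FENTANYL/REMIFENTANIL) by exclusion vetoes, but a
  new drug list with other collisions needs its own vetoes, and misspellings
  are not matched.
* Case deduplication keeps the numerically greatest `primaryid` per
  `caseid` (later versions supersede earlier ones); databases with
  non-numeric identifiers fall back to lexicographic order.
* The Wald CI is the standard large-sample interval; it is not recommended
  at a-cells below ~5 even with correction.
* O(n³) linkage is ample for matrices up to a few hundred rows/columns
  (the intended scale) but not for clustering thousands of events.
* No stratification (age, sex, era), no Bayesian shrinkage statistics
  (IC, EBGM), and no PRR; the screen is ROR + exact test only.
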