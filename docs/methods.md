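# Methods

## Problem and data model

Spontaneous-reporting systems (SRS) such as JADER collect voluntary
reports of suspected adverse drug events.  Each case links a demographic
record (sex, decade age band), a list of drug records (name, route,
start/end dates as possibly truncated `YYYYMMDD` strings) and a list of
adverse events (MedDRA preferred terms with optional onset dates).  The
package asks, for one *index drug* and one target preferred term: which
concomitant-drug combinations stratify the cases into subgroups whose
reporting rate of the target event is significantly above the overall
("initial") rate?  A reporting rate is a within-database quantity — the
case population is conditioned on having reported *some* adverse event —
so results rank relative concomitant risk among reported cases and must
not be read as clinical incidence.

## Cleaning cascade

Stage order is fixed and each stage logs its exclusions:

1. **Index-drug selection.** A case qualifies if any drug record matches
   an index-drug name exactly (after whitespace trimming).  Orthographic
   variants (brand names, salt forms) are *not* unified; users must list
   the spellings they want.  This is a documented fidelity gap of
   exact-string matching.
2. **Injectable exclusion.** Any case containing a drug whose route
   matches an injectable term (case-insensitive substring) is removed
   whole.  Rationale: injectables in an SRS case often treat the event
   rather than precede it.
3. **Deduplication.** Cases identical on (sex, age band, full registered
   drug-name set) are duplicates; the first-registered case — DEMO row
   order, which reflects registration order in SRS extracts — is kept.
   Missing sex/age group by their literal empty value.
4. **Drug timing filter**, anchored at the case's earliest non-missing
   event onset date.  With onset `o` and inclusive windows:
   - start > `o` → excluded (started after the event);
   - end < `o` → kept iff `o − end ≤ 7` days (recent discontinuation can
     still interact);
   - start present, end missing → kept iff `o − start ≤ 365` days;
   - start ≤ `o` ≤ end, or no usable dates → kept;
   - no onset date at all → every drug kept.

   Partial dates (year or year-month precision) are treated as missing
   everywhere: the rules need day resolution and imputation would
   fabricate information.  Records with start > end are kept but treated
   as undated.  A case whose index drug is itself removed by the filter is
   dropped.  Enlarging the discontinuation window can only enlarge a
   case's retained drug set (tested property).

Several conventions here are deliberate choices where the procedure is
underdetermined: the onset anchor when a case has several events
(earliest non-missing onset), inclusive window boundaries, keeping
fully undated drugs, and judging drugs with only an end date by the
end-date rule alone.  Each follows the principle that only positive
evidence of non-use at onset excludes a drug.

## Analysis matrix

Monotherapy cases (no concomitant drug after cleaning) are removed — they
carry no interaction information.  The initial rate IR is computed *after*
this exclusion, over exactly the cases the tree will stratify, so the
node tests compare like with like.  Features are binary presence
indicators for every concomitant non-statin drug (all six statins are
removed from the concomitant set, not only the index one) plus the drug
count, which includes the index drug.  Columns are ordered
lexicographically; output is byte-stable for identical input.

## Recursive partitioning

At each node every drug indicator and every midpoint between consecutive
observed drug-count values is a candidate binary split.  The selection
criterion is the likelihood-ratio chi-square of the 2×2 group × event
table,

    G² = 2 Σ O ln(O/E),   0·ln(0/E) := 0,

the classic deviance-based splitting statistic for a binary outcome (a
Pearson chi-square alternative is available behind a flag for sensitivity
analysis; both orderings agree on a fixed 2×2 margin family).  A split is
admissible when both children have at least `min_node = 10` cases;
the best admissible split is accepted when `G² > 0`.  Ties break
deterministically: binary candidates before numeric, then lexicographic
variable name, then the smaller threshold.  The "drug present" /
"count ≥ threshold" side is always the right child so that a node's path
of presence conditions reads as a drug combination.  There is no pruning
or cross-validation: the tree's job is stratification; screening happens
downstream in the node tests.  Stopping rules: `min_node`, `max_depth`
(default 10) and event-pure nodes.

Numerical notes: the vectorised candidate scorer and the scalar
`g2_statistic` use the same cell formula; degenerate margins return 0;
the brute-force enumeration used in tests scores candidates with an
independent library routine (log-likelihood-ratio contingency test) so
split optimality is verified by a dual route.

## Node tests and the signal report

Every non-root node is tested two-sided against the IR with the exact
binomial test (the sum of all outcome probabilities no larger than the
observed outcome's).  An exact test is essential at the node sizes the
minimum-node rule produces (n as small as 10).  The Benjamini–Hochberg
step-up adjusts the p-values across the family of all non-root nodes of
*one* index drug's tree; index drugs are analyzed and adjusted
independently.  The headline table reports, below the IR row, the
significant nodes (adjusted p ≤ q = 0.05) whose path is purely presence
conditions and whose rate exceeds the IR; mixed presence/absence or
drug-count paths stay in the machine-readable JSON sidecar only.  A
degenerate null (IR = 0 contradicted by observed events) returns the
smallest positive float with a warning rather than p = 0, keeping the
adjustment well-defined.

**Post-selection caveat.** The tested nodes were chosen by maximizing G²
on the same data, so the binomial tests are anticonservative and the
procedure does *not* control FDR at the nominal q.  The package
quantifies this honestly instead of fixing it: `run_null_calibration`
(and the acceptance script) measure the frequency of datasets yielding at
least one reported signal under a null simulation, and the declared
acceptance property is only that this frequency stays below a lenient
bound of 0.25 at the default simulator configuration.  Detected signals
are hypotheses for external (e.g. experimental) validation, not
confirmed interactions.

## Synthetic-data generator

The generator emulates the structural features the cleaning cascade and
the analysis rely on: every case carries the index drug plus a
truncated-at-1 Poisson number (mean 4.0) of concomitant drugs drawn from
a 30-drug vocabulary of commonly co-prescribed medications; events follow
a multiplicative risk model `p = min(0.95, baseline × Π multipliers)`
where a planted effect's multiplier applies only when *all* of its drugs
are present (a pure interaction, no marginal main effects unless planted
separately).  The multiplicative form keeps planted effects in reporting-
rate units — a multiplier of 8 over baseline 0.05 is a planted node rate
of 0.40 — at the price of the cap.  An optional per-effect carrier
fraction forces that share of cases to carry the full drug set, giving
direct control over carrier prevalence rather than relying on chance
co-occurrence.

Default nuisance structure: 30% missing onset dates and 30% fully
missing drug dates (the deficiency level reported for real SRS data), 5%
duplicate near-copies (registered after their originals), 5% injectable
cases, 2% late-started extra drugs; drug start/end dates are drawn so
that by default every drug passes the timing filter, and the deliberate
violations are recorded per case in the ground truth.  Everything is
deterministic given the seed.

What the generator does **not** emulate: realistic co-prescription
correlation (drugs are drawn near-independently), multiple events per
case, MedDRA coding variety beyond one target and one filler term, dose
or duration.  Passing the simulation suites therefore shows that the
pipeline recovers planted multiplicative interactions under idealised
polypharmacy, not that real-database signals are reliable.

## Problem sizes used in the checks

The simulation-based checks use 20 replicates of 5000 cases for
planted-triple recovery (multiplier 8, baseline 0.05, ~4% carriers) and
200 replicates of the 2000-case default configuration for the null
frequency; the split-optimality check enumerates all candidates on 100
random matrices of up to 200 cases and 12 drugs.  These sizes give stable
Monte-Carlo estimates for the properties asserted while keeping the suite
quick to run.

## Known limitations

- Exact-string drug matching; no MedDRA hierarchy handling; no HIST
  (primary disease) or drug-role filtering.
- Greedy trees are unstable: small data changes can reorder splits, and
  a combination can be reported with spurious extra members appended
  below it.
- Per-index-drug BH families; a joint family across index drugs would be
  more conservative.
- The IR convention (computed after monotherapy exclusion) and the onset
  anchor (earliest event) are choices among defensible alternatives;
  both are isolated in config/code and documented above.
- Reporting rates are not incidences; see the opening section.
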