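# Methods

## Sequence extraction

A patient's record is a list of dated, categorized events: six
treatment categories (antiplatelet, lipid-lowering, smoking cessation,
exercise therapy, endovascular revascularization, revascularization
surgery) plus the amputation outcome event. Extraction reduces it to
one ordered tuple of distinct treatments:

1. **Outcome assignment.** AMPUTATION iff any amputation event exists,
   else NON_AMPUTATION.
2. **Truncation.** For amputation patients, only treatment events dated
   *strictly before* the first amputation date are considered. Events
   dated on the amputation day are dropped: at day resolution a same-day
   event cannot be shown to precede the outcome. Later amputation events
   are irrelevant — only the first defines the truncation point.
   Non-amputation patients contribute their entire record; no censoring
   date is imposed.
3. **First-occurrence deduplication.** Each category enters the
   sequence once, at its first qualifying date, in chronological order.
4. **Tie-breaking.** Two different treatments on the same date are
   ordered by the canonical category order (the listing order above).
   This makes extraction a pure function of the event *set*: shuffling
   input rows never changes any sequence, which the property tests
   verify.
5. **Inclusion.** Patients whose step list comes out empty (e.g. an
   amputation-only record, or all treatments after the amputation) are
   excluded and counted in the extraction report.

Patients present in the event log but missing from the person table are
kept for pathway statistics and flagged; they drop out only of
confounder stratification, which needs their attributes.

## Normalization conventions

**Cohort level.** Amputations are rare relative to non-amputations, so
pathway counts are divided by the total number of sequences in their
outcome cohort (one sequence per included patient) and reported as
percentages. Rounding is half away from zero at 2 decimals, computed in
exact decimal arithmetic (`100·count/N` as a `Decimal`), so printed
rates like 7.79 (6/77) and 32.29 (1777/5504) are reproduced exactly.
Per cohort, counts sum to the cohort size and rates to 100 % within
±0.05 per row.

**Node level.** In the Sankey graph, each link also carries its
cohort-normalized value rescaled so that a node's *outgoing* links sum
to 1. Normalizing in- and out-flows of every node simultaneously is not
generally satisfiable; the sum-to-1 guarantee is therefore defined on
outgoing flows, while incoming flow is conserved exactly at the
raw-count level (every patient entering a treatment node leaves it,
toward the next step or the outcome). Both values plus the raw count
are stored on every link.

## Sankey graph structure

Nodes are stage-indexed — the same treatment at stage 1 and stage 2 is
two nodes — and the two outcome labels share a single terminal stage.
Treatment→treatment links connect adjacent stages only; a sequence's
last treatment links directly to its outcome node from whatever stage
it occupies (the one sanctioned exception to adjacency). Flows of
different outcomes through a shared node are parallel links, never
merged, so every flow can be colored by its eventual outcome: deep
amber (#FF8C00) for amputation, pine green (#01796F) for
non-amputation; hexes are configurable. The JSON export is fully
deterministic (sorted nodes, links and keys); the HTML export is a
small static SVG view over the same structure, with stroke widths
proportional to node-normalized values (the display convention that
makes the small amputation cohort visually comparable).

## Odds-ratio analysis

Pathway membership for the 2×2 table is **exact full-sequence
equality** — the same counting unit as the pathway tables — not prefix
or subset containment. OR = (a·d)/(b·c); when any cell is zero the
Haldane–Anscombe correction adds 0.5 to all four cells and the result
is flagged `corrected` (pathways unique to one cohort are common at
these sample sizes). The odds→probability conversion is
p = OR/(1+OR): monotone, p(1) = 0.5, and it reproduces every published
(OR, probability) pair after two-decimal rounding, which is why it was
adopted. No confidence intervals or p-values are emitted by default; a
Woolf (log-normal) interval is available via
`pathflow.odds.confidence_interval` for users who want one.

Published per-pathway odds ratios from the source cohorts are *not*
reproduction targets: they cannot be reconstructed from the published
rate tables under exact-sequence membership (e.g. rates of 25.97 % and
32 % in cohorts of 77 and 5504 imply OR ≈ 0.75 where 0.62 is printed),
so the exact counting unit behind them is underdetermined. Only the
conversion is validated.

## Confounder stratification

A stratum is a single predicate over patient attributes: age > t or
≤ t (study thresholds 50/65/80; any integer via the API), gender, race
(case-insensitive match over {white, black, asian}; other values fall
outside every stratum), smoking, or one comorbidity flag. Filters
select sequences — they never modify them — so every per-stratum
statistic equals the unstratified pipeline run on the pre-filtered
input (tested as an equivalence property). `paper_strata()` returns
the study's 19 rows: full cohort, 6 comorbidities, 6 age cuts, 2
genders, 3 races, smokers. Age is a static attribute of the person
table; the reference date is the caller's choice. Derived age bands
(51–65, 66–80) are obtained by differencing the cumulative ≤-strata;
inconsistent cumulative counts raise an error. Race strata need not
partition the cohort — residual "other/unknown" values are simply
outside every race stratum, mirroring the source tables, whose race
rows do not sum to the full cohort.

## Synthetic cohort generator

The generator is the package's stand-in for non-redistributable EHR
extracts. A spec lists pathway allocations — (ordered steps, outcome,
n_patients), optionally with fixed attributes — and noise settings.
Its contract, enforced by property tests: **extraction over the
generated log reproduces the allocation table exactly, with or without
noise**, and equal (spec, seed) pairs give byte-identical output.

- **Dates.** First occurrences are strictly increasing (gap ≥ 1 day,
  1 + exponential with mean `mean_gap_days`, default 45), so fixture
  ordering is never tie-dependent; tie handling is exercised separately
  in the extraction tests. The date model is purely structural — no
  claim of clinical realism about treatment timing is intended.
- **Noise.** Duplicate-treatment events re-emit an already-present
  category between its first occurrence and the outcome;
  post-amputation events are arbitrary treatments after the amputation
  date. For non-amputation patients there is no outcome date, so
  trailing noise is restricted to duplicates of categories already in
  the record — any new category would by definition extend the
  sequence. Defaults: p = 0.25 per slot, 3 slots of each kind.
- **Attributes.** Unless fixed per allocation, attributes are
  independent draws: age ≈ round(N(69, 11)) clipped to [30, 95], gender
  50/50, race weights (white .60, black .06, asian .13, other .21),
  smoking .93, and comorbidity prevalences (diabetes .36, hypertension
  .69, heart failure .23, cerebrovascular disease .32, coronary artery
  disease .46, hyperlipidemia .90) taken from the overall stratum
  proportions of the published STARR risk-factor counts. No joint
  distribution between confounders is modelled — the source analysis
  states none — so stratified fixtures fix the relevant flag per
  allocation explicitly rather than relying on marginal draws.

### Worked-example fixtures

The published tables print cohort sizes and percentage rates, not
counts, so fixture counts are back-solved: k is the integer with
round(100·k/N) equal to the printed rate at its printed precision
(2 dp values at 2 dp, 1 dp values like 2.6 at 1 dp). The scan over
k = 0..N is the oracle; when several k round to the printed value the
smallest is used with a logged warning, and a rate with no matching
integer is rejected rather than approximated. Patients not accounted
for by printed rates are allocated to filler pathways disjoint from the
documented ones, so documented rates are exactly recoverable while
cohort sizes match the published totals (STARR 77/5504, All of Us
176/4085 amputation/non-amputation; hypertension stratum 56/3812;
age ≤ 50 stratum 3/265). Fixtures: `starr_amputation_table2` (which
also embeds the STARR amputation rates 25.97 and 15.58),
`allofus_table4`, `starr_table6_nonamp`, `starr_hypertension`,
`starr_age_le50`.

## What passing tests do and do not show

The synthetic cohorts exercise the pipeline's *mechanics* under
realistic structure: duplicate orders, post-outcome activity, mixed
strata, printed-table rate recovery. They do not emulate clinical
dynamics — treatment choice does not depend on disease severity,
confounders are independent of pathways unless explicitly assigned,
and inter-event timing is structural. Passing tests therefore validate
extraction, counting, normalization, odds arithmetic, graph
construction and stratification; they say nothing about the clinical
associations a real cohort would show.

## Numerical choices and degenerate inputs

- Percentages and probabilities round half away from zero (exact
  `Decimal` arithmetic), matching every printed example checked;
  comparisons against 2 dp printed values use equality at 2 dp.
- An all-zero contingency table is an error; a zero cohort with nonzero
  rows is an error; an empty event log yields empty outputs and an
  all-zero report, not an exception.
- Deterministic orderings throughout: pathway tables by descending
  rate then lexicographic pathway; odds tables by descending OR;
  Sankey JSON by (stage, label) and (source, target, outcome).

## Problem sizes

The test suite and the acceptance script run the full STARR-scale
cohorts (≈5.6 k patients, ≈20 k events with noise) end-to-end; a
complete run takes a few seconds on one CPU, so no down-scaling is
needed anywhere.
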