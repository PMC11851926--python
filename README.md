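# pathflow

Treatment-pathway analysis for peripheral artery disease (PAD) cohorts:
from raw patient event logs to ordered treatment sequences, cohort-
normalized pathway tables, per-pathway odds ratios, dual-normalized
Sankey flow graphs, and confounder-stratified re-analyses.

PAD is an atherosclerotic narrowing of limb arteries whose worst
outcome is amputation. Observational EHR studies ask which sequences of
the six standard interventions — antiplatelet therapy, lipid-lowering
therapy, smoking cessation, exercise therapy, endovascular
revascularization, revascularization surgery — are associated with
amputation versus non-amputation. `pathflow` implements that analysis
as a reusable, tested pipeline, together with a seeded synthetic cohort
generator that emulates the structure of the EHR extracts such studies
run on (which are not publicly redistributable).

## The method

For each patient, the pipeline records the **first occurrence of each
treatment category until an amputation occurs**, giving an ordered
tuple of distinct treatments *s* = (*s*₁, …, *s*_L), L ≤ 6, with a
binary outcome label. Patients with no treatment strictly before their
first amputation are excluded. Three statistics are computed over the
extracted sequences:

- **Cohort-normalized rate** — for pathway *p* in outcome cohort *c*
  with cohort size *N_c*:  rate(*p*, *c*) = 100 · count(*p*, *c*) / *N_c*,
  rounded half away from zero to 2 decimals. Within each cohort the
  rates sum to 100 % up to rounding.
- **Odds ratio** — from the 2×2 table of exact-sequence membership ×
  outcome, OR = (a·d)/(b·c), with the Haldane–Anscombe +0.5 correction
  when any cell is zero; the derived probability is p = OR/(1+OR), so
  OR > 1 ⇔ p > 0.5 (higher amputation likelihood).
- **Sankey flow graph** — stage-indexed nodes, outcome-colored links
  (deep amber = amputation, pine green = non-amputation), carrying raw
  counts, cohort-normalized values, and node-normalized values (each
  node's outgoing flows rescaled to sum to 1).

Confounder stratification re-runs the identical pipeline on sub-cohorts
defined by age cuts (>/≤ 50, 65, 80), gender, race, smoking status, or
a comorbidity flag (diabetes, hypertension, heart failure,
cerebrovascular disease, coronary artery disease, hyperlipidemia).

## Worked example

```python
from pathflow import (
    paper_fixture, generate_cohort, build_cohort,
    count_pathways, cohort_normalize, TreatmentCode as T, OutcomeLabel as O,
)

spec = paper_fixture("starr_amputation_table2", seed=7)  # 77 amputation patients
events, persons = generate_cohort(spec)                  # noisy synthetic event log
sequences, report = build_cohort(events, persons)        # extraction
table = cohort_normalize(count_pathways(sequences, "starr"))
print(report.n_amputation)
print(table.rate((T.ANTIPLATELET, T.LIPID_LOWERING,
                  T.ENDOVASCULAR_REVASCULARIZATION), O.AMPUTATION))
print(table.rate((T.ANTIPLATELET, T.LIPID_LOWERING), O.AMPUTATION))
```

prints

```
77
7.79
25.97
```

— 77 patients survive extraction (duplicate treatment orders and
post-amputation events in the log never change a sequence); 6 of 77
(7.79 %) follow antiplatelet → lipid lowering → endovascular
revascularization before amputation, and 20 of 77 (25.97 %) follow
antiplatelet → lipid lowering.

The same flows are available from a shell:

```sh
pathflow generate --fixture starr_amputation_table2 --seed 7 --out-dir data/
pathflow extract --events data/events.csv --persons data/persons.csv --out seqs.tsv
pathflow stats --sequences seqs.tsv --out pathways.tsv
pathflow sankey --sequences seqs.tsv --out graph.json --html graph.html
pathflow run --config run.yaml          # full pipeline incl. stratification
```

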