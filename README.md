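# stewardbench

Paired antimicrobial-stewardship benchmarking of empiric antibiotic
regimens.  For each admission, two regimens (a clinician-prescribed one and
a counterfactual recommendation) are scored against rule-based *contextual
guardrails* — unjustified carbapenem, antipseudomonal β-lactam, or
anti-MRSA use in the absence of structured severity / MDR-risk / prior-MRSA
justification proxies — and the complete prespecified paired-endpoint
statistics battery is computed: exact McNemar tests, matched odds ratios
with 0.5 continuity correction, paired risk differences, sign and Wilcoxon
signed-rank tests, seeded bootstrap CIs for medians, acquisition-cost and
DDD/AWaRe deltas, and Holm step-down adjustment over the six-member
paired-delta family.

## Modules

| module | role |
| --- | --- |
| `stewardbench.catalog` | agent dictionary: class flags, AWaRe class, DDD reference, unit cost |
| `stewardbench.guardrails` | justification proxies, component violations, weighted penalty (2/1/1) |
| `stewardbench.stats` | paired inference battery (McNemar, matched OR, sign, Wilcoxon, bootstrap, Holm) |
| `stewardbench.endpoints` | full endpoint pipeline, concordance, QC, results bundle |
| `stewardbench.synth` | stochastic cohort generator + deterministic 493-admission fixture |
| `stewardbench.cli` / `cohort_io` | `simulate` / `analyze` / `report` commands, CSV/JSON cohort formats |

The deterministic fixture (`stewardbench.table2_fixture()`) is a
493-admission cohort constructed by constraint assignment so that running
the pipeline on it reproduces every published paired count exactly
(primary 2×2 table, component tables, broad-spectrum composite,
penalty-delta sign pattern and moments, coverage subset, concordance
counts, and the five empty-recommendation admissions).

## CLI

```sh
# write the deterministic fixture cohort (or a random one with --n/--seed)
stewardbench simulate --fixture --out cohort.csv
stewardbench simulate --n 500 --seed 1 --out random.csv

# run the full endpoint battery (bundle JSON + summary CSV + log)
stewardbench analyze --cohort cohort.csv --out results/

# render a Markdown report from a bundle
stewardbench report --bundle results/bundle.json
```

Exit codes: 0 success, 2 validation error, 3 I/O error, 4 QC failure
(unmapped agent codes; a QC report file is written before aborting).

Guardrail weights and justification rules are configurable via
`--config` (YAML), e.g.:

```yaml
weights:
  CARB: 2
  APS: 1
  MRSA: 1
justification_rules:
  CARB: SEVERE or MDR_RISK
  APS: SEVERE or MDR_RISK
  MRSA: PRIOR_MRSA
```

## Conventions pinned in this implementation

- Two-sided exact McNemar / sign test: doubled smaller binomial tail capped at 1.
- Matched OR: (n01+0.5)/(n10+0.5) with Wald 95% CI on the log scale (z = 1.96).
- Wilcoxon signed-rank: zeros dropped, midranks for ties; exact sign-flip
  null for ≤ 25 nonzero deltas, else tie-corrected normal approximation
  with continuity correction.
- Bootstrap median CI: percentile method, n_boot = 5000, seed = 7, one
  generator drawing n indices per replicate.
- Missing context documentation is treated as absence of the condition at
  ingestion (substitutions are counted and logged).
- AWaRe numeric scores: ACCESS = 1, WATCH = 2, RESERVE = 3; empty regimens
  contribute 0 to AWaRe/cost/DDD.
- Costs are flat per-day unit prices × window days (1 day at 24 h, 3 days
  at 72 h in the continued-therapy subset); the shipped price list is
  synthetic reference data and fully overridable via `--catalog`.
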