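# trialpath

Reconstruction of drug-development paths from flat clinical-trial registry
tables, and estimation of the probability of success (POS) of clinical
development — per phase, overall (the likelihood of approval), by subgroup,
and over time.

## Who this is for

Registry extracts arrive as one row per (trial, drug, indication, sponsor)
quartet with a phase label, dates and a status.  Anyone who wants
phase-transition probabilities out of such data — biostatisticians,
portfolio analysts, policy researchers — faces the same obstacles: a drug's
trials must be grouped into *development programs* (one drug, one
indication), the record is right-censored at the extraction snapshot,
sponsors rarely report "we stopped", and interior phases are often simply
missing from the record even though the program demonstrably passed them.
`trialpath` packages the whole chain: cleaning and end-date repair, path
reconstruction, censoring-aware state classification, and estimation, with
a synthetic-registry generator so every stage can be validated against
known ground truth.

## The model

Programs are assumed to pass Phases 1 → 2 → 3 in order before approval.
For each path and phase *j*, the classifier assigns a state: **advanced**
(a higher phase or an approval is observed), **terminated** (the time from
the phase's latest trial end to the snapshot exceeds an allowance
*t<sub>j</sub>* — 360, 540, 900 days for Phases 1–3 — or every trial
failed), **in progress** (otherwise), or **missing/imputed** (no records,
but phases on both sides are observed: the passage is inferred).  Writing
*n<sup>j</sup>* for observed Phase-*j* paths, *n<sub>m</sub><sup>j</sup>*
for imputed ones and *n<sub>ip</sub>*, *n<sub>t</sub>* for the stopped
states, path flow obeys the conservation law

> n<sup>j+1</sup> = n<sup>j</sup> + n<sub>m</sub><sup>j</sup> −
> n<sub>ip</sub><sup>j</sup> − n<sub>t</sub><sup>j</sup>,  j = 1, 2, 3

(asserted on every tabulation).  Two estimators are provided:

* **path-by-path** — POS<sub>j,j+1</sub> = n<sup>j+1</sup> / (n<sup>j</sup> +
  n<sub>m</sub><sup>j</sup> − n<sub>ip</sub><sup>j</sup>), counting imputed
  passages in both numerator and denominator; the overall POS divides
  approvals by Phase-1 paths net of all in-progress paths.
* **phase-by-phase** — the older convention: observed transitions over
  observed programs, POS<sup>p</sup><sub>j,j+1</sub> = (n<sup>j+1</sup> −
  n<sub>m</sub><sup>j</sup>) / (n<sup>j</sup> − n<sub>ip</sub><sup>j</sup>),
  multiplied across phases.

The two coincide exactly on complete data (telescoping product); when
interior phase records are missing, the phase-by-phase product is biased
low while the path-by-path estimate is not.  Standard errors are binomial,
√(p(1−p)/n), on each estimate's own denominator.

## Worked example

```python
from trialpath import (GeneratorConfig, ThresholdConfig, build_programs,
                       generate, impute_end_dates, pos_path_overall,
                       tabulate_transitions)

records, approvals, truth = generate(GeneratorConfig(n_drugs=2000, seed=1))
records, report = impute_end_dates(records)
programs = build_programs(records, approvals)
counts = tabulate_transitions(programs, ThresholdConfig("2015-10-31"))
print(pos_path_overall(counts))
```

Running `python examples/01_simulate_and_estimate.py` (same data) prints:

```
14457 records, 1733 end dates imputed
3789 development paths; counts n(j) = {1: 3789, 2: 2536, 3: 1017} approvals = 159

    transition   path-by-path  phase-by-phase
  Phase 1 -> 2         68.0%          68.0%
  Phase 2 -> 3         59.6%          56.6%
Phase 3 -> APP         58.7%          58.7%
       overall          7.4%          22.6%
```

Per phase the two estimators differ only at Phase 2 → 3, where ~10% of
advancing programs had their Phase-2 records deleted by the generator: the
phase-by-phase value drops because those observed transitions are gone.
The overall columns differ for a second reason as well: the path-by-path
overall is the realized fraction of Phase-1 paths approved by the
snapshot (slow successes are still in the pipeline), while the
phase-by-phase product chains per-phase conditional rates.  The other
examples show the missingness experiment (`02`) and the rolling-window
time series with its flagged boundary window (`03`).

A thin CLI wraps the same pipeline:

```bash
trialpath simulate --seed 1 --n-drugs 500 --out sim/
trialpath estimate --registry sim/registry.csv --approvals sim/approvals.csv \
    --snapshot 2015-10-31 --out est/
trialpath timeseries --registry sim/registry.csv --approvals sim/approvals.csv \
    --snapshot 2015-10-31 --years 2006:2015 --out ts/
```

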