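# Methods

## The estimation problem

A trial registry is a flat table: one row per (trial, drug, indication,
sponsor) quartet, with a phase label (P1, P1/2, P2, P2/3, P3, P4), start
and end dates, and a status.  The quantity of interest is the probability
that a *development program* — one drug investigated for one indication —
advances from phase to phase and ultimately to approval.  The record is
doubly incomplete: it is right-censored at the snapshot date the extract
was taken, and interior phases of a program are often absent even when the
program demonstrably passed them (a path observed at Phases 1 and 3 must
have passed Phase 2).  The package reconstructs whole paths under an
idealized Phase 1 → 2 → 3 → approval process and estimates transition
probabilities from the reconstruction.

## Cleaning and end-date repair

Combined-phase labels map onto the higher phase (P1/2 → Phase 2,
P2/3 → Phase 3).  Records that ended before the analysis window
(default floor 2000-01-01) and records with no start date or an
unidentified sponsor are dropped, with every drop tallied in a
`FilterReport` whose arithmetic (`n_output = n_input − drops`) is
enforced.  Concluded records lacking an end date receive
`start + median duration` of donor records with similar features, where
"similar" walks the fallback chain (canonical phase, therapeutic group,
sponsor class) → (phase, group) → (phase) → global; donors are concluded
records with *observed* durations only, so repeated imputation is a
no-op.  Medians of even-sized donor sets average the two middle values;
durations are whole days (end − start, endpoints inclusive), half-up
rounded.  Ongoing and planned records keep absent end dates: they are
censored, not broken.

## Path reconstruction and state classification

Records group by (drug, indication) — (drug, indication, sponsor) is
available for sensitivity analyses — with trials deduplicated by trial id
inside a program, since one trial listed under several sponsors is still
one trial.  An approval table joins on (drug, indication); additionally a
Phase-4 trial implies approval (Phase 4 is post-marketing by definition),
dated at the earliest Phase-4 start, unless a real approval record exists.

Each path's phases are then classified:

* Every observed phase below the highest observed phase, or below an
  approval, is **advanced** — reaching Phase *i* implies the lower phases
  completed, even if some lower-phase trials failed (advancement evidence
  wins).
* Interior phases with no trials, bracketed by observed evidence on both
  sides (an approval counts as evidence), are **missing_imputed** — a
  successful passage.  Leading gaps are never fabricated: a path first
  seen at Phase 2 enters the analysis at Phase 2.  Fabricating Phase-1
  entries would inflate the overall-POS denominator with paths whose
  Phase-1 outcome was never at risk of observation.
* The highest observed phase of an unapproved path is **terminated** when
  the elapsed time from its most recent trial end to the snapshot strictly
  exceeds the phase allowance t_j, or when every trial in the phase
  failed; it is **in_progress** when any trial still lacks an end date or
  the elapsed time is within the allowance.  The defaults t = (360, 540,
  900) days for Phases 1–3 reflect the cadence of restarting development;
  the Phase-3 allowance also absorbs filing-and-review time, so no
  separate regulatory-event model exists (a deliberate simplification).
* Approved paths end in a terminal **approved** state.

A later snapshot can only move states from in-progress toward
terminated/advanced, never backwards.

## Counts and estimators

For phase j ∈ {1,2,3} the tabulator counts observed paths n_obs[j],
imputed paths n_m[j], in-progress n_ip[j] and terminated n_t[j], plus
approvals; n[j] = n_obs[j] + n_m[j] is the total path count at phase j.
Path flow gives the conservation law

    n[j+1] = n_obs[j] + n_m[j] − n_ip[j] − n_t[j] + n_entry[j+1]

with n[4] read as the approval count.  The n_entry term counts paths
first seen at phase j+1; it is identically zero when every path starts at
Phase 1 (as in all generated registries) and exists so the identity stays
exact on real data with late-entering paths.  The law is asserted, not
assumed, on every tabulation.

Estimators (standard errors binomial on the estimator's own denominator;
the product estimator uses a first-order delta method with independent
factors):

* path-by-path, per phase: `n[j+1] / (n[j] − n_ip[j])`
* path-by-path, phase i to approval:
  `n_approval / (n[i] − Σ_{k≥i} n_ip[k])`; i = 1 is the overall POS
* phase-by-phase, per phase: `(n[j+1] − n_m[j]) / (n_obs[j] − n_ip[j])` —
  observed transitions over observed programs; the n_m[j] subtraction
  removes transitions whose source phase was imputed
* phase-by-phase, overall: the product over j of the per-phase factors.

With no imputation and no censoring, n_obs = n and the phase-by-phase
product telescopes to exactly the path-by-path overall value.  When whole
interior phase record sets are missing, the path-by-path estimator is
unbiased by construction (the passage is restored in both numerator and
denominator) while the phase-by-phase product loses numerator transitions
and is biased low, increasingly so in the missingness rate — the package's
tests quantify both claims against the generator's latent truth.

Undefined estimates (empty denominators) raise a typed error carrying the
offending counts; the windowed variant instead reports absent values so
time series remain aligned.

## Windowed and subgroup analyses

Rolling series use the phase-by-phase form only: over a short window,
whole-path reconstruction over-credits success because failures need time
to manifest.  A phase observation belongs to window [t1, t2] when its
*decisive date* — the latest end date among that phase's trials — falls
inside; the transition outcome is taken from the full-sample
classification.  Windows for year t span January 1 of t−2 to December 31
of t (3-year default), the final window clipped at the snapshot and
flagged `boundary_biased`: near the snapshot, pending terminations still
look in-progress, shrinking the denominator and inflating the estimate.

Subgroups: strata compose conjunctively over therapeutic group, orphan
flag, sponsor class, lead-indication status and partner count.  The lead
indication of a drug is the program with the earliest first trial start
(ties: earliest end date, then smallest indication id) — a documented
operational choice, since no standard definition exists.  Biomarker
comparisons are phase-wise (a program's Phase-j observation joins the
biomarker stratum iff some Phase-j trial carries the flag, in
`selection_only` or `expanded` mode) and by default exclude records whose
status was observed before 2005-01-01, when biomarker tagging becomes
dense; biomarker + non-biomarker counts partition the unstratified tally
per phase.  Completion rates count completed trials (early positive stops
included) over concluded trials.  Durations use a 365.25-day year and
30.4375-day month; clinic time is the sum of the Phase 1–3 medians.

## The synthetic registry generator

The generator emulates the data features the pipeline must survive:
multiple indications per drug (truncated geometric, mean 1.9), Bernoulli
phase advancement with per-phase probabilities θ (defaults (0.664, 0.583,
0.590)), one-or-more trials per phase (1 + Poisson; means 1.7/2.0/2.8/3.2
for Phases 1–4), lognormal trial durations (default medians 1.6/2.9/3.8/2
years, σ = 0.45), inter-phase and approval gaps, right-censoring at the
snapshot (trials ending later are emitted without end dates; trials
starting later are not emitted), ~15% of concluded trials with blanked
end dates, and — the pattern the two estimators disagree on — deletion of
an advancing program's entire Phase-2 record set with probability m
(default 0.10).  Deletion requires an emitted Phase-3 trial so the gap is
always interior.  Terminal-phase trials of stopping programs run about
`duration_gap_terminated_months` (default 8) shorter than advancing ones,
and a fraction are tagged failed.  Biomarker, orphan, sponsor-class and
partner attributes are drawn per program, with optional multiplicative
effects on θ (validated so no effective probability exceeds 1).
Determinism: each program draws from a sub-stream keyed by (seed, program
counter), so output is byte-identical across runs.

`truth_summary` provides two oracles: the uncensored latent tally, and a
censored replay of the termination heuristics over the latent bookkeeping
that matches the pipeline's tabulation exactly when end-date blanking is
off (blanked dates are repaired by medians, which can nudge a decisive
date across a threshold).

What the generator does **not** emulate — and hence what passing tests do
not establish about real extracts: entity-resolution noise (drug synonyms,
indication ontologies), time-varying θ, reporting biases that correlate
missingness with outcome (deletion here is independent of everything but
advancement), duplicate quartets beyond sponsor multiplicity, and
disease-specific trial calendars.

## Numerical and design choices

* Whole-day date arithmetic; strict `> t_j` triggers termination.
* Even-count medians average the middle pair; imputed durations round
  half-up to whole days.
* Imputed end dates are ≥ start dates, so cleaning is idempotent whenever
  record starts lie inside the analysis window.
* The conservation check is exact integer arithmetic, never tolerance.
* Problem sizes in the test-suite experiments (10 000 drugs for parameter
  recovery, 20 replicate seeds for the robustness and boundary studies,
  200 random registries for the conservation property) were chosen to keep
  Monte-Carlo error well below the effects being demonstrated while the
  whole suite runs in well under a minute of compute.

## Known limitations

* The termination heuristic is a heuristic: a dormant program that later
  resumes is first counted terminated, then (with more data) advanced.
* The overall path-by-path POS under censoring is a realized fraction of
  resolved paths; because successes take longer to resolve than failures,
  it sits below the stationary product of per-phase rates on simulated
  data.  The per-phase estimates and the phase-by-phase product do not
  share this duration effect.
* SEs treat paths as independent Bernoulli draws; drugs spanning several
  indications violate independence mildly.
* No Bayesian shrinkage or interval estimates beyond the reported SE.
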