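"""Why reconstruct whole paths: robustness to missing interior phases.

Deletes the Phase-2 records of advancing programs with probability m and
compares both overall estimators with the known latent truth.  The
path-by-path estimator imputes the missing passage and stays unbiased;
the phase-by-phase product loses observed transitions and drifts low.
"""

from trialpath import (
    GeneratorConfig,
    ThresholdConfig,
    build_programs,
    generate,
    latent_pos,
    pos_path_overall,
    pos_phase_overall,
    tabulate_transitions,
)

print(f"{'m':>5s} {'truth':>8s} {'path-by-path':>13s} {'phase-by-phase':>15s}")
for m in (0.0, 0.2, 0.5):
    cfg = GeneratorConfig(
        n_drugs=1500, seed=3, theta=(0.65, 0.55, 0.60),
        missingness_m=m, end_date_missing_fraction=0.0,
        biomarker_effect=1.0, partner_effect=1.0,
        snapshot_date="2050-01-01",   # uncensored: every path has resolved
    )
    records, approvals, truth = generate(cfg)
    counts = tabulate_transitions(
        build_programs(records, approvals), ThresholdConfig("2050-01-01")
    )
    print(f"{m:5.1f} {latent_pos(truth)['overall']:8.1%}"
          f" {pos_path_overall(counts).value:12.1%}"
          f" {pos_phase_overall(counts).value:14.1%}")
print("\nEach row is one registry; 'truth' is the realized latent approval"
      "\nfraction.  Only the phase-by-phase column moves with m.")
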