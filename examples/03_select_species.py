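"""Consensus selection of arthritis-correlated species.

Runs the full selection procedure — rat-prevalence filter, log10/z-score
normalization, then 5-fold x 10-repeat cross-validated non-negative
elastic-net regression of arthritis scores on the species profile — and
compares the consensus set (species with a positive coefficient in more
than 25 of the 50 models) against the planted ground truth.
"""

from microtraj import SimConfig, select_arthritis_species, selection_report, simulate_cohort

config = SimConfig.planted_signal(seed=1)  # 5 planted species, rest noise
profile, meta, _, truth = simulate_cohort(config)

result = select_arthritis_species(profile, meta, seed=1)
print(f"fitted {result.total_models_fit} models, retained {result.n_retained} "
      f"with >= {result.min_nonzero} nonzero coefficients")
print(f"consensus set (> {result.consensus_threshold} models): "
      f"{len(result.selected_species)} species\n")

report = selection_report(result)
print(report.head(10).to_string(index=False), "\n")

planted = set(truth.signal_species)
selected = set(result.selected_species)
print(f"recovered {len(selected & planted)}/{len(planted)} planted species, "
      f"{len(selected - planted)} false selection(s)")
print("Inclusion counts near 50 mean a species entered virtually every "
      "resampled model — the stability signature of a real association.")
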