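"""Normal-referenced fold changes and the >16-fold consistency rule.

Normalizes each diseased/treated rat's species abundances by the healthy
control group's mean at the same time point, computes per-rat log10 fold
changes against the rat's own baseline (TP1), and calls a (species, group,
time point) change significant when more than 80% of rats show a >16-fold
change in the same direction.
"""

from microtraj import (
    SimConfig,
    call_significant,
    calls_table,
    fold_threshold_log10,
    log10_fc_vs_baseline,
    normalize_to_reference,
    simulate_cohort,
)

profile, meta, _, truth = simulate_cohort(SimConfig(seed=1))

normalized = normalize_to_reference(profile, meta, reference_group="normal")
fc = log10_fc_vs_baseline(normalized, meta, baseline="TP1")
calls = calls_table(call_significant(fc, threshold_fold=16.0, rat_fraction=0.8))

print(f"|log10 FC| cutoff for a 16-fold change: {fold_threshold_log10(16.0):.2f}\n")

sig = calls[calls["significant"]]
print("significant calls per group and time point:")
print(sig.groupby(["group", "timepoint"]).size().unstack(fill_value=0), "\n")

tp5 = sig[(sig["group"] == "model") & (sig["timepoint"] == "TP5")]
drifters = set(truth.drift_directions)
hits = set(tp5["species"]) & drifters
print(f"model group at TP5: {len(tp5)} significant species, "
      f"{len(hits)} of them planted community drifters "
      f"({len(hits)}/{len(drifters)} planted shifts recovered)")
print("Direction +1 = enriched in disease, -1 = depleted; under per-rat noise "
      "the strict consistency rule favours specificity over recall.")
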