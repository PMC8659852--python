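"""Screen feature combinations that separate LC from H plasma samples.

Simulates a small labelled cohort of paired before/after measurements,
builds the base+change feature table and ranks every feature pair by
leave-one-out cross-validated accuracy over the nine-classifier bank.
(The full study conditions use 10+10 samples and triples as well; this
example stays small so it runs in seconds.)
"""

from aptascreen import (CohortConfig, build_feature_table,
                        extract_sample_record, screen_combinations,
                        simulate_cohort, summarize_screen)

records = simulate_cohort(CohortConfig(n_lc=5, n_h=5, seed=2))
feature_records = [
    extract_sample_record(r.sample_id, r.label,
                          cv_before=r.before.cv, eis_before=r.before.eis,
                          cv_after=r.after.cv, eis_after=r.after.eis)
    for r in records
]
table = build_feature_table(feature_records, "full")
results = screen_combinations(table, 2)
report = summarize_screen(results, top_n=5)

print(f"{len(table)} samples, {len(table.feature_names)} features, "
      f"{report['n_results']} (pair, classifier) scores")
print(f"max LOOCV accuracy: {report['max_accuracy']:.3f}")
print("top pairs (best classifier each):")
for combo in report["top_combinations"]:
    print(f"  {combo['features']}  {combo['family']}"
          f"(C/k={combo['hyperparameter']:g})  acc={combo['accuracy']:.3f}")
print()
print("Accuracy 1.0 means every held-out sample was classified correctly;")
print("the winning features track the planted capacitance and cathodic")
print("effects of tumour-marker binding.")
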