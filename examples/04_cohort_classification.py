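"""Synthetic cohort -> 220-feature table -> LOO-CV response classification.

Generates a labelled cohort whose responder and non-responder tumours
differ in scatterer microstructure, extracts the full core/margin feature
table through the RF pipeline, and evaluates an LDA response model with
nested forward feature selection (4-feature cap, F1 metric) under
leave-one-out cross-validation.  The non-nested variant (one global
selection before the LOO loop) is reported alongside for comparison.
"""

from collections import Counter

from qusresp import (ClassifierSpec, CohortConfig, assemble_feature_table,
                     generate_cohort, loocv_evaluate)

config = CohortConfig(n_patients=12, responder_fraction=0.5, seed=11,
                      n_planes=1, effect_size=1.0)
records = generate_cohort(config)
table = assemble_feature_table(records)
print(f"cohort: {len(table)} patients, "
      f"{table.shape[1] - 1} features + label "
      f"({Counter(table['label']).most_common()})")

for nested in (True, False):
    res = loocv_evaluate(table, ClassifierSpec("LDA"),
                         nested_selection=nested)
    m = res.metrics
    tag = "nested SFS " if nested else "global SFS"
    print(f"{tag}: sens {m['sensitivity']:.0%}  spec {m['specificity']:.0%}  "
          f"acc {m['accuracy']:.0%}  AUC {m['auc']:.2f}")
    print(f"   features (first fold): {res.selected_features[0]}")

print("\nWith a strong simulated class effect both protocols classify the"
      "\ncohort nearly perfectly; on weak effects the global variant is"
      "\noptimistically biased, which is why nested selection is the default.")
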