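"""Turn clusters into human-readable decision rules and validate them on an
independent holdout population with a longer assessment-to-index window.
"""

import pandas as pd

from riskcarver import studies, synthetic
from riskcarver.holdout import assign_clusters, compare_populations
from riskcarver.rules import rules_for_clusters

# discovery population with known archetypes; rules are induced one-vs-rest
# on the original input values (here: ground-truth archetype labels stand in
# for a clustering, so the planted thresholds are known)
cohort = synthetic.generate_subjects(studies.five_rule_config(seed=41))
labels = cohort.frame["true_archetype"].to_numpy()
ruleset = rules_for_clusters(cohort.features, labels, seed=42)

print("planted rules vs induced rules (out-of-bag scores):")
for k, planted in enumerate(studies.FIVE_RULES):
    text = " and ".join(f"{f} {op} {t}" for f, op, t in planted)
    rule = ruleset.selected[k]
    print(f"  planted : {text}")
    print(f"  induced : {rule}   (precision {rule.oob_precision:.3f}, "
          f"recall {rule.oob_recall:.3f}, trees {rule.tree_count})")

# holdout population: same generator, different seed, 5-11 year window
holdout = synthetic.generate_subjects(studies.five_rule_config(seed=43))
feats = holdout.features.copy()
feats.index = holdout.frame["subject_id"]
disc = pd.DataFrame({
    "case_frac": [cohort.frame.loc[labels == c, "is_case"].mean()
                  for c in sorted(set(labels))],
    "size": [int((labels == c).sum()) for c in sorted(set(labels))],
}, index=sorted(set(labels)))
disc["size_frac"] = disc["size"] / disc["size"].sum()

assignment = assign_clusters(ruleset, feats,
                             (disc["case_frac"] * 100).to_dict(), disc["size"].to_dict())
fr = assignment.category_fractions()
print(f"\nholdout assignment: {fr['unique']:.1%} unique, "
      f"{fr['ambiguous']:.1%} ambiguous, {fr['unassigned']:.1%} unassigned")
report = compare_populations(
    disc, assignment, pd.Series(holdout.labels, index=holdout.frame["subject_id"])
)
print(f"discovery/holdout concordance: case-fraction R^2 = "
      f"{report.r2_case_fraction:.3f}, size-fraction R^2 = {report.r2_size_fraction:.3f}")
print("\nAmbiguous subjects go to the matching cluster with the highest")
print("discovery case percentage, minimising false negatives.")
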