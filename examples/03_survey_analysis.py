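"""The survey analysis chain on a synthetic cohort.

Generates a full synthetic study (food tables -> compilation -> recall
survey), then runs misreporter exclusion, content categorization,
intake quartiles, the obesity association model and the food-group
contribution table, printing each stage's headline numbers.
"""

from bcaadb import SimConfig
from bcaadb.pipeline import run_pipeline

result = run_pipeline(SimConfig(seed=42, n_items=200, n_subjects=800))

summary = result["report_summary"]
print(f"compilation: {summary['total_compiled']}/{summary['total_items']} items, "
      f"shares (%) {summary['method_share_pct']}")

print(f"exclusion: kept {len(result['kept'])} subjects, "
      f"excluded {len(result['excluded'])} misreporters")

print(f"content categories (items per category): "
      f"{result['categories'].value_counts().sort_index().to_dict()}")
print(f"computed breaks (g/100 g): {result['breaks'].thresholds}")

assoc = result["association"]
for q in sorted(assoc.odds_ratios):
    print(f"  Q{q}: OR {assoc.odds_ratios[q]:.2f} "
          f"[{assoc.ci_low[q]:.2f}, {assoc.ci_high[q]:.2f}]")
print(f"overall p = {assoc.p_overall:.3f} (adjusted for {', '.join(assoc.covariates)})")

top = result["contribution"]["BCAA"].sort_values(ascending=False).head(5)
print("top contributors to population total BCAA intake (%):")
for group, pct in top.items():
    print(f"  {group:<28s} {pct:5.1f}")
print("\nThe cohort was generated with no planted quartile effect, so odds ratios\n"
      "hover around 1 and the overall p-value is typically non-significant; the\n"
      "contribution column sums to 100% across the 18 food groups.")
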