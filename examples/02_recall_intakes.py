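"""Turn one subject's 24-h recalls into daily BCAA intakes.

Builds a two-day recall for one subject over a tiny compiled table and
prints per-day and mean daily intakes plus the food-group split.
"""

from bcaadb import BCAATriple, FoodItem, RecallRecord, summarize_subject


def item(item_id, name, group18, protein, bcaa, energy):
    group10 = {"Red meat and poultry": "Meat, poultry, and fish",
               "Milk and dairy products": "Dairy products and cheese",
               "Bread, Pasta, cereals": "Cereals and pasta"}[group18]
    return FoodItem(item_id=item_id, names={"en": name}, group10=group10,
                    group18=group18, protein=protein, bcaa=BCAATriple(*bcaa),
                    provenance="source_table", energy_kcal=energy)


table = [
    item("beef", "minced beef", "Red meat and poultry", 26.0, (1.18, 2.08, 1.29), 250.0),
    item("milk", "whole milk", "Milk and dairy products", 3.3, (0.20, 0.32, 0.22), 64.0),
    item("bread", "baguette", "Bread, Pasta, cereals", 8.8, (0.33, 0.62, 0.40), 274.0),
]

records = [
    RecallRecord("s01", 1, "breakfast", "milk", 250.0),
    RecallRecord("s01", 1, "breakfast", "bread", 80.0),
    RecallRecord("s01", 1, "dinner", "beef", 120.0),
    RecallRecord("s01", 2, "lunch", "beef", 150.0),
    RecallRecord("s01", 2, "lunch", "bread", 60.0),
    RecallRecord("s01", 2, "snacks", "milk", 200.0),
]

summary = summarize_subject(records, table)
for day, totals in summary.per_day.items():
    print(f"day {day}: energy {totals['energy_kcal']:7.1f} kcal, "
          f"total BCAA {totals['total_bcaa_g']:.2f} g")
print(f"mean over {summary.days} days: {summary.mean['total_bcaa_g']:.2f} g/day "
      f"(ile {summary.mean['isoleucine_g']:.2f}, leu {summary.mean['leucine_g']:.2f}, "
      f"val {summary.mean['valine_g']:.2f})")
print("\nfood-group split of mean daily total BCAA (g/day):")
for group, amounts in sorted(summary.group_bcaa.items()):
    print(f"  {group:<28s} {amounts['total_bcaa']:.2f}")
print("\nIntakes are grams consumed x composition per 100 g; the subject-level value\n"
      "is the unweighted mean over recorded days, and group amounts partition it.")
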