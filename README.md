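# bcaadb

Branched-chain amino acid (BCAA — isoleucine, leucine, valine) intakes are
candidate biomarkers for insulin resistance and type-2 diabetes, but most
national food-composition tables (e.g. the French CIQUAL table) do not list
amino acids, so BCAA exposure cannot be estimated from dietary surveys
directly. `bcaadb` is a Python library for nutritional epidemiologists that
covers both halves of that problem:

1. **Compiling a BCAA food-composition database.** Missing amino-acid values
   are filled by a provenance-tracked cascade of five methods:
   transfer from an international reference table with nitrogen adjustment
   (method 1), published HPLC/GC measurements (method 2), similarity transfer
   from a raw counterpart for cooked foods (method 3), recipe calculation for
   mixed dishes (method 4), and zero assignment for protein-free items
   (method 5). The transfer rule for methods 1 and 3 is

   *BCAA(query) = BCAA(reference) × N(query) / N(reference)*,

   where N = protein / nitrogen-to-protein conversion factor (6.25 for crude
   protein in the target table; each reference table's own factor otherwise).
   Candidate references must match by name and lie within a ±5 g/100 g
   protein tolerance. Recipe dishes are per-100 g weighted sums of their
   ingredients, with raw ingredients substituted by cooked equivalents via
   yield factors.

2. **Analysing 24-h dietary recalls (24HDR).** Recalls (subject, day, meal,
   item, grams) become per-subject mean daily intakes; under- and
   over-reporters are screened out (energy intake > 4000 or < 1000 kcal/day
   when activity data are missing, a Goldberg-style EI/BMR ratio otherwise,
   with Harris–Benedict BMR and WHO-style GPAQ activity scoring); food items
   are stratified into six content categories (A = zero … F > 4.168 g/100 g);
   intakes are split into quartiles and related to obesity by logistic
   regression adjusted for age and energy (odds ratios with Wald 95% CIs and
   a likelihood-ratio overall p); and population intake is attributed to 18
   food groups as Block-style percentage contributions.

A deterministic synthetic-study generator (`bcaadb.simulate`) produces food
tables, reference tables, recipes, recall surveys and subject profiles with
known ground truth, so the entire chain is testable without licensed data.

## Worked example

`examples/01_compile_food_table.py` compiles a five-item toy table:

```
item            provenance   ile    leu    val   (g/100 g)
roast chicken breast   method1    1.586  2.496  1.629
white rice cooked      method1    0.101  0.202  0.147
chicken rice bowl      method4    0.695  1.120  0.739
spring water           method5    0.000  0.000  0.000
goat brousse           method2    0.440  0.820  0.570

compiled 5/5 items; method shares (%): {'method1': 40, 'method2': 20, 'method3': 0, 'method4': 20, 'method5': 20}
```

The chicken row is its reference's triple scaled by the nitrogen ratio
(30/28 ≈ 1.07); the rice bowl is the 60 g chicken + 90 g rice recipe summed
per 100 g of dish; water is protein-free, hence zero by rule; the cheese
value is a literature measurement stored verbatim with its citation.

The other examples cover per-subject recall summaries
(`02_recall_intakes.py`), the full synthetic survey analysis with odds
ratios and contribution shares (`03_survey_analysis.py`), and BMR/GPAQ
scoring with misreporter screening (`04_bmr_and_gpaq.py`). The same
functionality is available from a shell via the `bcaadb` command
(`compile`, `report`, `intake`, `analyze`, `simulate`).

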