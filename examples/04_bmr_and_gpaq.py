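"""Basal metabolic rate and GPAQ physical-activity scoring.

Computes Harris–Benedict BMR for a reference adult, scores two GPAQ
answer sets, and shows how the misreporter screen uses them.
"""

import pandas as pd

from bcaadb import (
    GPAQAnswers,
    SubjectProfile,
    exclude_misreporters,
    gpaq_met_minutes,
    harris_benedict_bmr,
)

bmr_m = harris_benedict_bmr("male", weight=70, height=175, age=30)
bmr_f = harris_benedict_bmr("female", weight=70, height=175, age=30)
print(f"Harris-Benedict BMR, 70 kg / 175 cm / 30 y: male {bmr_m:.1f}, "
      f"female {bmr_f:.1f} kcal/day")

office = GPAQAnswers(work_moderate=(5, 30.0))
athlete = GPAQAnswers(leisure_vigorous=(4, 60.0), transport=(5, 20.0))
for label, answers in (("office worker", office), ("athlete", athlete)):
    met, level = gpaq_met_minutes(answers)
    print(f"{label}: {met:.0f} MET-min/week -> {level}")

profiles = [
    SubjectProfile("p1", 30, "male", 70, 175, energy_kcal=2400.0, activity_level="low"),
    SubjectProfile("p2", 30, "male", 70, 175, energy_kcal=4500.0),
    SubjectProfile("p3", 30, "male", 70, 175, energy_kcal=900.0),
]
intakes = pd.DataFrame({"energy_kcal": {"p1": 2400.0, "p2": 4500.0, "p3": 900.0}})
kept, excluded = exclude_misreporters(profiles, intakes)
print(f"kept: {[p.subject_id for p in kept]}")
for sid, reason in excluded.items():
    print(f"excluded {sid}: {reason}")
print("\nWith activity data the screen compares energy intake to BMR (Goldberg-style\n"
      "ratio); without it, intakes above 4000 or below 1000 kcal/day are excluded.")
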