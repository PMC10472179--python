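"""From raw 3-day meal-review records to per-subject nutrient profiles.

Food-mode records (grams of foods per subject-day) are joined against a
food-composition table (nutrients per 100 g), summed per day, and averaged
across the recall days.
"""

import pandas as pd

from diisurv import aggregate_recalls, compose_nutrients, profiles_from_means

fct = pd.DataFrame(
    {
        "carbohydrate": [25.9, 48.0, 2.0, 7.0],
        "protein": [2.6, 10.0, 8.1, 2.0],
        "total_fat": [0.3, 1.0, 3.7, 0.2],
        "energy": [116.0, 245.0, 76.0, 35.0],
    },
    index=pd.Index(["steamed_rice", "wheat_noodles", "tofu", "bok_choy"],
                   name="food"),
)

records = pd.DataFrame(
    [
        (1, 1, "steamed_rice", 300.0), (1, 1, "tofu", 150.0),
        (1, 2, "wheat_noodles", 250.0), (1, 2, "bok_choy", 200.0),
        (1, 3, "steamed_rice", 350.0), (1, 3, "bok_choy", 150.0),
    ],
    columns=["subject_id", "day_index", "item", "amount"],
)

per_day = compose_nutrients(records, fct)
print("per-day totals (g, kcal):")
print(per_day.round(1))

means = aggregate_recalls(per_day, expected_days=3)
print("\n3-day mean intake:")
print(means.round(1))
# The mean row is what gets scored: e.g. the protein figure is this
# subject's average daily protein in grams over the recall window.

profile = next(profiles_from_means(means))
print(f"\nprofile energy: {profile.energy_kcal:.0f} kcal/day, "
      f"basis: {profile.basis}")
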