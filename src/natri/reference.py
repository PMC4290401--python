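"""Packaged reference tables for the salt-microsphere reformulation scenario.

Two small tables are built programmatically:

* the 953-food scenario definition (seven food-group batches with 20–30%
  targeted maximum sodium reduction) as announced for the technology's
  potential applications; and
* the published NHANES 2007–2010 subgroup report of that scenario at 100%
  market penetration (mean ± SE reduction, current and post-reduction usual
  intake, percent reduction), used for layout and arithmetic-consistency
  checks.  These printed values summarize the real US survey and are *not*
  reproduced by the synthetic pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import food_code

#: (group_id, n_foods, min_reduction, max_reduction) for the seven targeted
#: food-group batches; 17+304+20+30+511+35+36 = 953 foods.
SCENARIO_CATEGORY_SPECS = (
    (1, 17, 0.20, 0.20),    # Milk & Milk Products
    (2, 304, 0.20, 0.25),   # Meat, Poultry, Fish & Mixtures
    (3, 20, 0.25, 0.25),    # Eggs
    (4, 30, 0.25, 0.25),    # Dry Beans, Peas, Other Legumes, Nuts & Seeds
    (5, 511, 0.25, 0.25),   # Grain Products
    (7, 35, 0.20, 0.30),    # Vegetables
    (8, 36, 0.25, 0.25),    # Fats, Oils & Salad Dressings
)


def reference_scenario_table() -> pd.DataFrame:
    """Expand the category batches to one row per food (953 rows).

    Within a ranged category the per-food maximum reduction is spread
    linearly from the low to the high end of the announced range.
    """
    rows = []
    for gid, n, lo, hi in SCENARIO_CATEGORY_SPECS:
        fracs = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
        for i, r in enumerate(fracs):
            rows.append({"food_code": food_code(gid, i), "group_id": gid,
                         "max_reduction_fraction": round(float(r), 6)})
    return pd.DataFrame(rows)


#: Published subgroup report (ethnicity × age group, genders combined):
#: mean ± SE of the per-person reduction, current usual intake, usual intake
#: after reduction, and percent reduction, all mg/day except the percents.
_REPORT_ROWS = [
    # ethnicity, age_group, reduction, se, current, se, post, se, pct, se
    ("Mexican American", "19-50", 250, 14, 3558, 68, 3309, 59, 6.8, 0.3),
    ("Mexican American", "51+", 196, 12, 2898, 86, 2702, 78, 6.8, 0.4),
    ("Other Hispanic", "19-50", 252, 11, 3599, 45, 3347, 39, 6.9, 0.3),
    ("Other Hispanic", "51+", 185, 11, 2916, 68, 2731, 63, 6.3, 0.3),
    ("Non-Hispanic White", "19-50", 323, 8, 3903, 55, 3581, 53, 8.3, 0.2),
    ("Non-Hispanic White", "51+", 242, 5, 3320, 49, 3078, 47, 7.3, 0.2),
    ("Non-Hispanic Black", "19-50", 296, 10, 3544, 66, 3248, 60, 8.4, 0.2),
    ("Non-Hispanic Black", "51+", 222, 9, 3046, 74, 2824, 67, 7.2, 0.2),
]


def reference_subgroup_report() -> pd.DataFrame:
    """Published scenario report for the US population subgroups."""
    df = pd.DataFrame(_REPORT_ROWS, columns=[
        "ethnicity", "age_group", "reduction_mg", "reduction_se",
        "current_mg", "current_se", "post_mg", "post_se",
        "pct_reduction", "pct_se"])
    df["identity_consistent"] = (
        df["current_mg"] - df["reduction_mg"] == df["post_mg"])
    return df
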