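"""Attribution of total dietary sodium to the 9 FNDDS food groups.

Contributions are ratios of survey-weighted sodium totals over the observed
recall days (no usual-intake modeling is applied per group): for a domain,
percent(group) = 100 * sum_w(sodium in group) / sum_w(all sodium).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import FOOD_GROUPS, REPORTED_ETHNICITIES, assign_age_groups

UNMAPPED_GROUP_ID = 10


def group_contributions(recalls: pd.DataFrame, food_groups: pd.DataFrame,
                        demo: pd.DataFrame,
                        by=("age_group", "gender", "ethnicity"),
                        strict: bool = True) -> pd.DataFrame:
    """Percent of total dietary sodium by food group per demographic domain.

    ``strict=True`` raises on unmapped food codes; otherwise they are pooled
    into an "unmapped" bucket (group id 10).  Percentages sum to 100 within
    each domain and are invariant to weight rescaling.
    """
    if "age_group" not in demo.columns:
        demo = assign_age_groups(demo)
    rec = recalls.merge(food_groups, on="food_code", how="left")
    unmapped = rec["group_id"].isna()
    if unmapped.any():
        codes = sorted(rec.loc[unmapped, "food_code"].unique())
        if strict:
            raise ValidationError(
                f"unmapped food codes: {', '.join(codes[:10])}"
                + ("..." if len(codes) > 10 else ""))
        rec.loc[unmapped, "group_id"] = UNMAPPED_GROUP_ID
    rec["group_id"] = rec["group_id"].astype(int)

    person_group = (rec.groupby(["person_id", "group_id"], sort=True)
                    ["sodium_mg"].sum().reset_index())
    df = person_group.merge(demo[["person_id", "weight", *by]],
                            on="person_id", how="inner")
    df = df[df["ethnicity"].isin(REPORTED_ETHNICITIES)] \
        if "ethnicity" in by else df
    df["wsod"] = df["weight"] * df["sodium_mg"]

    rows = []
    for dom, sub in df.groupby(list(by), sort=True, observed=True):
        dom = dom if isinstance(dom, tuple) else (dom,)
        total = sub["wsod"].sum()
        gsum = sub.groupby("group_id")["wsod"].sum()
        for gid in list(FOOD_GROUPS) + ([UNMAPPED_GROUP_ID] if not strict else []):
            rows.append({**dict(zip(by, dom)), "group_id": gid,
                         "group_name": FOOD_GROUPS.get(gid, "Unmapped"),
                         "percent_of_total_sodium":
                             float(100.0 * gsum.get(gid, 0.0) / total)})
    out = pd.DataFrame(rows)
    sums = out.groupby(list(by), observed=True)["percent_of_total_sodium"].sum()
    assert np.allclose(sums, 100.0, atol=0.01)
    return out
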