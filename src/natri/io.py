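"""Flat-file input/output and population filtering.

The pipeline exchanges four CSV tables (UTF-8, comma-separated, header row,
"." decimal separator):

* ``demographics.csv`` — one row per participant with survey-design columns
  (stratum, PSU, weight) and the covariates used downstream.
* ``recalls.csv`` — one row per food eaten by one person on one 24-hour
  recall day (day 1 in person, day 2 by telephone).
* ``foodgroups.csv`` — food code → one of the 9 broad FNDDS food groups.
* ``scenario.csv`` — food code → maximum achievable sodium-reduction
  fraction under the reformulation technology.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

log = logging.getLogger(__name__)

#: The 9 top-level FNDDS food groups used for source attribution.
FOOD_GROUPS: dict[int, str] = {
    1: "Milk & Milk Products",
    2: "Meat, Poultry, Fish & Mixtures",
    3: "Eggs",
    4: "Dry Beans, Peas, Other Legumes, Nuts & Seeds",
    5: "Grain Products",
    6: "Fruits",
    7: "Vegetables",
    8: "Fats, Oils & Salad Dressings",
    9: "Sugars, Sweets & Beverages",
}

#: Ethnicity labels reported in subgroup summaries ("Other" is retained by
#: filters and model fits but excluded from subgroup reporting).
REPORTED_ETHNICITIES = (
    "Mexican American",
    "Other Hispanic",
    "Non-Hispanic White",
    "Non-Hispanic Black",
)

AGE_GROUPS = ("2-18", "19-50", "51+")
GENDERS = ("male", "female")

DEMO_COLUMNS = {
    "person_id": str,
    "age_years": int,
    "gender": str,
    "ethnicity": str,
    "pregnant_or_lactating": bool,
    "stratum": str,
    "psu": str,
    "weight": float,
    "cycle": str,
}
RECALL_COLUMNS = {
    "person_id": str,
    "day": int,
    "food_code": str,
    "grams": float,
    "sodium_mg": float,
    "energy_kcal": float,
    "weekend": bool,
    "mode": str,
}
FOODGROUP_COLUMNS = {"food_code": str, "group_id": int}
SCENARIO_COLUMNS = {"food_code": str, "max_reduction_fraction": float}


def _read_csv(path: str | Path, columns: dict[str, type], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} file {path} is missing column(s): {', '.join(missing)}")
    out = {}
    for col, typ in columns.items():
        raw = df[col]
        if typ is str:
            out[col] = raw
        elif typ is bool:
            low = raw.str.strip().str.lower()
            bad = ~low.isin(["true", "false", "1", "0"])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
                raise ParseError(f"{table} column '{col}': non-boolean value "
                                 f"{raw[bad].iloc[0]!r} at line {row}")
            out[col] = low.isin(["true", "1"])
        else:
            coerced = pd.to_numeric(raw, errors="coerce")
            bad = coerced.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise ParseError(f"{table} column '{col}': non-numeric value "
                                 f"{raw[bad].iloc[0]!r} at line {row}")
            out[col] = coerced.astype(typ)
    result = pd.DataFrame(out)
    log.info("read %d %s rows from %s", len(result), table, path)
    return result


def validate_demographics(demo: pd.DataFrame) -> pd.DataFrame:
    if demo["person_id"].duplicated().any():
        dup = demo.loc[demo["person_id"].duplicated(), "person_id"].iloc[0]
        raise ValidationError(f"demographics: duplicate person_id {dup!r}")
    bad = demo["weight"] <= 0
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"demographics: non-positive weight {demo['weight'].iloc[row]} "
            f"for person {demo['person_id'].iloc[row]!r} (row {row})")
    if (demo["age_years"] < 0).any():
        raise ValidationError("demographics: negative age_years")
    return demo


def validate_recalls(recalls: pd.DataFrame) -> pd.DataFrame:
    if not recalls["day"].isin([1, 2]).all():
        bad = recalls.loc[~recalls["day"].isin([1, 2]), "day"].iloc[0]
        raise ValidationError(f"recalls: day must be 1 or 2, got {bad}")
    if (recalls["grams"] <= 0).any():
        raise ValidationError("recalls: grams must be > 0")
    if (recalls["sodium_mg"] < 0).any():
        raise ValidationError("recalls: sodium_mg must be >= 0")
    if (recalls["energy_kcal"] < 0).any():
        raise ValidationError("recalls: energy_kcal must be >= 0")
    return recalls


def validate_food_groups(fg: pd.DataFrame) -> pd.DataFrame:
    if fg["food_code"].duplicated().any():
        dup = fg.loc[fg["food_code"].duplicated(), "food_code"].iloc[0]
        raise ValidationError(f"food-group map: food_code {dup!r} maps to more than one group")
    if not fg["group_id"].isin(list(FOOD_GROUPS)).all():
        raise ValidationError("food-group map: group_id must be in 1..9")
    return fg


def validate_scenario(sc: pd.DataFrame) -> pd.DataFrame:
    if sc["food_code"].duplicated().any():
        dup = sc.loc[sc["food_code"].duplicated(), "food_code"].iloc[0]
        raise ValidationError(f"scenario: duplicate food_code {dup!r}")
    frac = sc["max_reduction_fraction"]
    if ((frac < 0) | (frac > 1)).any():
        raise ValidationError("scenario: max_reduction_fraction must lie in [0, 1]")
    return sc


def read_demographics(path: str | Path) -> pd.DataFrame:
    return validate_demographics(_read_csv(path, DEMO_COLUMNS, "demographics"))


def read_recalls(path: str | Path) -> pd.DataFrame:
    return validate_recalls(_read_csv(path, RECALL_COLUMNS, "recalls"))


def read_food_groups(path: str | Path) -> pd.DataFrame:
    return validate_food_groups(_read_csv(path, FOODGROUP_COLUMNS, "food-group map"))


def read_scenario(path: str | Path) -> pd.DataFrame:
    return validate_scenario(_read_csv(path, SCENARIO_COLUMNS, "scenario"))


def read_tables(demo_path, recalls_path, groups_path=None, scenario_path=None):
    """Read the full set of pipeline inputs; group map and scenario optional."""
    demo = read_demographics(demo_path)
    recalls = read_recalls(recalls_path)
    groups = read_food_groups(groups_path) if groups_path else None
    scenario = read_scenario(scenario_path) if scenario_path else None
    return demo, recalls, groups, scenario


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def apply_population_filters(demo: pd.DataFrame) -> pd.DataFrame:
    """Drop participants under age 2 and pregnant/lactating females.

    Exclusion counts are logged and attached under
    ``result.attrs['exclusions']``.  Idempotent.
    """
    under2 = demo["age_years"] < 2
    preg = demo["pregnant_or_lactating"].astype(bool)
    keep = ~(under2 | preg)
    out = demo.loc[keep].reset_index(drop=True)
    counts = {
        "under_2": int(under2.sum()),
        "pregnant_or_lactating": int((preg & ~under2).sum()),
        "retained": int(keep.sum()),
    }
    out.attrs["exclusions"] = counts
    if len(out) == 0:
        log.warning("population filters removed every row")
    log.info("population filters: %s", counts)
    return out


def assign_age_groups(demo: pd.DataFrame) -> pd.DataFrame:
    """Attach the reporting age groups 2-18 / 19-50 / 51+.

    Ages below 2 must have been filtered out first.
    """
    if (demo["age_years"] < 2).any():
        raise ValidationError("assign_age_groups: ages < 2 present; "
                              "apply_population_filters first")
    out = demo.copy()
    out["age_group"] = pd.cut(
        out["age_years"], bins=[1, 18, 50, np.inf], labels=AGE_GROUPS
    ).astype(str)
    return out
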