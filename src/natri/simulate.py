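"""Synthetic NHANES-shaped cohort generator with known ground truth.

Daily sodium intake is simulated on the log scale as

    log T_ij = mu(cell_i) + shift(cycle_i) + u_i + b_wk * W_ij + b_seq * S_ij + e_ij

with a person-level random effect ``u_i ~ N(0, sigma_between^2)``, day-level
noise ``e_ij ~ N(0, sigma_within^2)``, a weekend indicator ``W`` and a
day-2/telephone indicator ``S``.  Each person contributes exactly two recall
days (day 1 in person, day 2 by telephone).  The day total is partitioned
across food records according to a 9-group composition vector, so the food
sources and reformulation-scenario stages see realistic food-level data.

The generator also emits a truth table with each person's long-run average
daily intake, enabling parameter-recovery tests of the whole estimation chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AGE_GROUPS, FOOD_GROUPS, GENDERS, REPORTED_ETHNICITIES

_ALL_ETHNICITIES = REPORTED_ETHNICITIES + ("Other",)

#: Baseline mean *day-total* sodium (mg) by ethnicity for adults 19-50, both
#: genders combined; age and gender multipliers below spread these over the
#: 24 reporting cells.  Levels mirror typical US survey estimates (adult males
#: near 4000 mg/day, White > Black ~ Hispanic, adults > children/older adults).
_ETHNICITY_BASE_MG = {
    "Mexican American": 3560.0,
    "Other Hispanic": 3600.0,
    "Non-Hispanic White": 3900.0,
    "Non-Hispanic Black": 3540.0,
    "Other": 3650.0,
}
_GENDER_MULT = {"male": 1.18, "female": 0.84}
_AGE_MULT = {"2-18": 0.82, "19-50": 1.0, "51+": 0.84}

#: Expected share of daily sodium by FNDDS group (sums to 1).  Grain + Meat
#: carry about two thirds; the top four groups about 86%.
DEFAULT_GROUP_COMPOSITION = (0.10, 0.27, 0.02, 0.02, 0.40, 0.01, 0.09, 0.04, 0.05)

_ETHNICITY_SHARES = {
    "Mexican American": 0.17,
    "Other Hispanic": 0.10,
    "Non-Hispanic White": 0.45,
    "Non-Hispanic Black": 0.23,
    "Other": 0.05,
}
_AGE_SHARES = {"2-18": 0.30, "19-50": 0.40, "51+": 0.30}
_AGE_RANGES = {"2-18": (2, 18), "19-50": (19, 50), "51+": (51, 85)}


def default_subgroup_log_means(sigma_between: float, sigma_within: float,
                               beta_weekend: float = 0.0, beta_sequence: float = 0.0,
                               p_weekend: float = 3 / 7) -> dict:
    """Log-scale cell locations calibrated so E[day total] hits the mg table."""
    adj = (sigma_between ** 2 + sigma_within ** 2) / 2.0
    adj += np.log((1 - p_weekend) + p_weekend * np.exp(beta_weekend))
    adj += np.log(0.5 + 0.5 * np.exp(beta_sequence))
    means = {}
    for eth, base in _ETHNICITY_BASE_MG.items():
        for g, gm in _GENDER_MULT.items():
            for a, am in _AGE_MULT.items():
                means[(a, g, eth)] = float(np.log(base * gm * am) - adj)
    return means


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort; defaults are the study conditions.

    ``n_persons`` is per cycle.  ``subgroup_log_means`` maps
    ``(age_group, gender, ethnicity)`` to the log-scale location ``mu``;
    when ``None`` it is derived from a realistic mg table via
    :func:`default_subgroup_log_means`.
    """

    n_persons: int = 2000
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_cv: float = 0.5
    subgroup_log_means: dict | None = None
    sigma_between: float = 0.25
    sigma_within: float = 0.35
    beta_weekend: float = 0.05
    beta_sequence: float = -0.05
    p_weekend: float = 3 / 7
    group_composition: tuple = DEFAULT_GROUP_COMPOSITION
    foods_per_group: int = 4
    dirichlet_concentration: float | None = 60.0
    energy_kcal_per_mg_sodium: float = 0.60
    energy_ratio_sigma: float = 0.10
    grams_per_mg_sodium: float = 0.64
    grams_ratio_sigma: float = 0.10
    pregnancy_rate: float = 0.02
    toddler_rate: float = 0.01
    other_ethnicity_share: float = 0.05
    seed: int = 0
    cycle_labels: tuple = ("2007-2008",)
    cycle_log_mean_shifts: tuple | None = None
    cycle_mg_per_g: tuple | None = None

    def validate(self) -> "SimConfig":
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if self.psus_per_stratum < 2:
            raise ValidationError("psus_per_stratum must be >= 2 "
                                  "(variance estimation needs >= 2 PSUs per stratum)")
        comp = np.asarray(self.group_composition, dtype=float)
        if comp.shape != (9,):
            raise ValidationError("group_composition must have 9 entries")
        if (comp < 0).any():
            raise ValidationError("group_composition entries must be nonnegative")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"group_composition must sum to 1 (got {comp.sum():.12f})")
        if self.sigma_between <= 0:
            raise ValidationError("sigma_between must be > 0")
        if self.sigma_within < 0:
            raise ValidationError("sigma_within must be >= 0")
        if self.weight_cv < 0:
            raise ValidationError("weight_cv must be >= 0")
        if self.foods_per_group < 1:
            raise ValidationError("foods_per_group must be >= 1")
        if not 0 <= self.p_weekend <= 1:
            raise ValidationError("p_weekend must lie in [0, 1]")
        for name in ("cycle_log_mean_shifts", "cycle_mg_per_g"):
            val = getattr(self, name)
            if val is not None and len(val) != len(self.cycle_labels):
                raise ValidationError(f"{name} must match cycle_labels in length")
        return self

    def resolved_log_means(self) -> dict:
        if self.subgroup_log_means is not None:
            return dict(self.subgroup_log_means)
        return default_subgroup_log_means(
            self.sigma_between, self.sigma_within,
            self.beta_weekend, self.beta_sequence, self.p_weekend)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["subgroup_log_means"] is not None:
            d["subgroup_log_means"] = {
                "|".join(k): v for k, v in d["subgroup_log_means"].items()}
        return d


def food_code(group_id: int, index: int) -> str:
    """FNDDS-style 8-digit code: leading digit is the food group."""
    return f"{group_id}{index + 1:07d}"


def partition_day_sodium(total_mg: float, composition, foods_per_group: int,
                         rng: np.random.Generator,
                         concentration: float | None = 60.0) -> pd.DataFrame:
    """Split one person-day sodium total across food records.

    Group shares are Dirichlet-distributed around ``composition`` (exact
    proportional shares when ``concentration`` is None); within a group the
    share is split uniformly-Dirichlet across that group's food codes.
    Conservation: record sodium sums back to ``total_mg``.
    """
    comp = np.asarray(composition, dtype=float)
    if comp.size == 0:
        raise ValidationError("composition must be non-empty")
    if total_mg <= 0:
        raise ValidationError("total_mg must be > 0")
    if abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
        raise ValidationError("composition must be nonnegative and sum to 1")
    active = np.flatnonzero(comp > 0)
    if concentration is None:
        shares = comp[active]
        food_shares = np.repeat(shares / foods_per_group, foods_per_group)
    else:
        shares = rng.dirichlet(concentration * comp[active])
        within = rng.dirichlet(np.ones(foods_per_group), size=active.size)
        food_shares = (shares[:, None] * within).ravel()
    groups = np.repeat(active + 1, foods_per_group)
    idx = np.tile(np.arange(foods_per_group), active.size)
    sodium = total_mg * food_shares
    keep = sodium > 0
    return pd.DataFrame({
        "food_code": [food_code(g, i) for g, i in zip(groups[keep], idx[keep])],
        "group_id": groups[keep],
        "sodium_mg": sodium[keep],
    })


def _assign_categorical(rng, n, shares: dict):
    labels = list(shares)
    p = np.asarray([shares[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def generate_cohort(config: SimConfig):
    """Generate (demographics, recalls, truth) tables.

    Deterministic given ``config.seed``.  Multi-cycle configs emit
    ``n_persons`` fresh participants per cycle.
    """
    cfg = config.validate()
    log_means = cfg.resolved_log_means()
    root = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(ss) for name, ss in
               zip(("demo", "intake", "foods", "ratios"), root.spawn(4))}

    n_cycles = len(cfg.cycle_labels)
    shifts = cfg.cycle_log_mean_shifts or (0.0,) * n_cycles
    mg_per_g = cfg.cycle_mg_per_g
    comp = np.asarray(cfg.group_composition, dtype=float)

    demo_parts, recall_parts, truth_parts = [], [], []
    for ci, cycle in enumerate(cfg.cycle_labels):
        n = cfg.n_persons
        rng = streams["demo"]
        pid = np.array([f"P{ci}_{i:06d}" for i in range(n)])
        eshares = dict(_ETHNICITY_SHARES)
        eshares["Other"] = cfg.other_ethnicity_share
        eth = _assign_categorical(rng, n, eshares)
        gender = _assign_categorical(rng, n, {"male": 0.5, "female": 0.5})
        age_group = _assign_categorical(rng, n, _AGE_SHARES)
        lo = np.array([_AGE_RANGES[a][0] for a in age_group])
        hi = np.array([_AGE_RANGES[a][1] for a in age_group])
        age = rng.integers(lo, hi + 1)
        toddler = rng.random(n) < cfg.toddler_rate
        age = np.where(toddler, rng.integers(0, 2, size=n), age)
        preg = ((gender == "female") & (age >= 15) & (age <= 50)
                & (rng.random(n) < cfg.pregnancy_rate / 0.2))
        stratum_idx = np.arange(n) % cfg.n_strata
        psu_idx = (np.arange(n) // cfg.n_strata) % cfg.psus_per_stratum
        sigw = np.sqrt(np.log1p(cfg.weight_cv ** 2))
        weight = 100.0 * np.exp(rng.normal(-sigw ** 2 / 2, sigw, size=n))

        demo = pd.DataFrame({
            "person_id": pid,
            "age_years": age.astype(int),
            "gender": gender,
            "ethnicity": eth,
            "pregnant_or_lactating": preg,
            "stratum": [f"S{cycle}:{s + 1:02d}" for s in stratum_idx],
            "psu": [f"S{s + 1:02d}-U{p + 1}" for s, p in zip(stratum_idx, psu_idx)],
            "weight": weight,
            "cycle": cycle,
        })
        demo["age_group"] = np.where(age < 2, "2-18",
                             np.where(age <= 18, "2-18",
                              np.where(age <= 50, "19-50", "51+")))

        rng_i = streams["intake"]
        mu = np.array([log_means[(a, g, e)] for a, g, e in
                       zip(demo["age_group"], gender, eth)]) + shifts[ci]
        u = rng_i.normal(0.0, cfg.sigma_between, size=n)
        eps = (rng_i.normal(0.0, cfg.sigma_within, size=(n, 2))
               if cfg.sigma_within > 0 else np.zeros((n, 2)))
        weekend = rng_i.random((n, 2)) < cfg.p_weekend
        day2 = np.array([0.0, 1.0])
        log_day = (mu[:, None] + u[:, None] + cfg.beta_weekend * weekend
                   + cfg.beta_sequence * day2[None, :] + eps)
        day_total = np.exp(log_day)  # (n, 2) mg

        # long-run average over the day-covariate distribution
        wk_factor = (1 - cfg.p_weekend) + cfg.p_weekend * np.exp(cfg.beta_weekend)
        seq_factor = 0.5 + 0.5 * np.exp(cfg.beta_sequence)
        true_usual = (np.exp(mu + u + cfg.sigma_within ** 2 / 2)
                      * wk_factor * seq_factor)

        recalls = _emit_food_records(
            cfg, comp, pid, day_total, weekend, streams["foods"], streams["ratios"],
            grams_per_mg=(1.0 / mg_per_g[ci]) if mg_per_g else cfg.grams_per_mg_sodium)

        demo_parts.append(demo.drop(columns=["age_group"]))
        recall_parts.append(recalls)
        truth_parts.append(pd.DataFrame({
            "person_id": pid,
            "true_usual_intake_mg": true_usual,
            "person_random_effect": u,
        }))

    demo = pd.concat(demo_parts, ignore_index=True)
    recalls = pd.concat(recall_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    assert (truth["true_usual_intake_mg"] > 0).all()
    return demo, recalls, truth


def _emit_food_records(cfg, comp, pid, day_total, weekend, rng_f, rng_r,
                       grams_per_mg):
    """Vectorised partition of every person-day total into food records."""
    n = day_total.shape[0]
    active = np.flatnonzero(comp > 0)
    G, F = active.size, cfg.foods_per_group
    nd = n * 2
    if cfg.dirichlet_concentration is None:
        food_shares = np.tile(np.repeat(comp[active] / F, F), (nd, 1))
    else:
        alpha = cfg.dirichlet_concentration * comp[active]
        gam = rng_f.standard_gamma(np.tile(alpha, (nd, 1)))
        gshares = gam / gam.sum(axis=1, keepdims=True)
        wgam = rng_f.standard_gamma(1.0, size=(nd, G, F))
        wshares = wgam / wgam.sum(axis=2, keepdims=True)
        food_shares = (gshares[:, :, None] * wshares).reshape(nd, G * F)

    totals = day_total.ravel()  # person-major, day within person
    sodium = totals[:, None] * food_shares  # (nd, G*F)

    # person-level density jitter: grams and kcal per mg sodium
    g_jit = np.exp(rng_r.normal(-cfg.grams_ratio_sigma ** 2 / 2,
                                cfg.grams_ratio_sigma, size=n))
    e_jit = np.exp(rng_r.normal(-cfg.energy_ratio_sigma ** 2 / 2,
                                cfg.energy_ratio_sigma, size=n))
    g_ratio = np.repeat(grams_per_mg * g_jit, 2)
    e_ratio = np.repeat(cfg.energy_kcal_per_mg_sodium * e_jit, 2)

    groups = np.repeat(active + 1, F)
    codes = np.array([food_code(g, i) for g in active + 1 for i in range(F)])

    keep = sodium > 0
    rows, cols = np.nonzero(keep)
    sod = sodium[rows, cols]
    rec = pd.DataFrame({
        "person_id": np.repeat(pid, 2)[rows],
        "day": np.tile([1, 2], n)[rows],
        "food_code": codes[cols],
        "grams": sod * g_ratio[rows],
        "sodium_mg": sod,
        "energy_kcal": sod * e_ratio[rows],
        "weekend": weekend.ravel()[rows],
        "mode": np.where(np.tile([1, 2], n)[rows] == 2, "telephone", "in_person"),
    })
    rec["_group_id"] = groups[cols]
    return rec.drop(columns=["_group_id"])


def food_group_map(foods_per_group: int) -> pd.DataFrame:
    """Food-code → group map covering every code the generator can emit."""
    rows = [(food_code(g, i), g) for g in FOOD_GROUPS for i in range(foods_per_group)]
    return pd.DataFrame(rows, columns=["food_code", "group_id"])
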