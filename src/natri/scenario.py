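"""Food-reformulation scenario engine.

A scenario assigns each targeted food a maximum achievable sodium-reduction
fraction r (20–30% by category for the salt-microsphere technology).  The
realized per-food cut is r × reduction_scaling × market_penetration: in the
default expected-value mode penetration acts as a deterministic multiplier on
every targeted record; in stochastic mode each targeted food code is
independently reformulated (fully) with probability equal to the penetration,
emulating a marketplace where a product either is or is not reformulated.

``run_scenario`` re-estimates usual intake on the modified recalls with the
same estimator settings as the baseline arm (the Box–Cox exponent is profiled
once on the baseline and shared, so the two arms differ only in the data),
and reports per-person reductions averaged within demographic domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import REPORTED_ETHNICITIES, assign_age_groups
from .usual import (UsualIntakeModel, fit_amount_model, usual_intake_per_person,
                    _bootstrap_multipliers, _solve_at, _mu_ref)


@dataclass
class Scenario:
    """Per-food maximum reduction fractions plus global scaling knobs."""

    reductions: pd.Series  # food_code -> max_reduction_fraction
    reduction_scaling: float = 1.0
    penetration: float = 1.0
    mode: str = "expected_value"

    def __post_init__(self):
        if isinstance(self.reductions, pd.DataFrame):
            self.reductions = self.reductions.set_index("food_code")[
                "max_reduction_fraction"]
        frac = np.asarray(self.reductions, dtype=float)
        if frac.size and (np.min(frac) < 0 or np.max(frac) > 1):
            raise ValidationError("max_reduction_fraction must lie in [0, 1]")
        for name in ("reduction_scaling", "penetration"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.mode not in ("expected_value", "stochastic_assignment"):
            raise ValidationError(f"unknown scenario mode {self.mode!r}")

    def replace(self, **kw) -> "Scenario":
        d = dict(reductions=self.reductions, reduction_scaling=self.reduction_scaling,
                 penetration=self.penetration, mode=self.mode)
        d.update(kw)
        return Scenario(**d)


def apply_scenario(recalls: pd.DataFrame, scenario: Scenario,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Scale sodium in targeted food records; grams and kcal are unchanged.

    Returns a copy of the recall table with modified ``sodium_mg`` plus a
    ``reduction_mg`` column (old − new, zero for untargeted foods).
    """
    out = recalls.copy()
    r = out["food_code"].map(scenario.reductions).fillna(0.0).to_numpy()
    if scenario.mode == "expected_value":
        factor = r * scenario.reduction_scaling * scenario.penetration
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        codes = pd.Index(scenario.reductions.index)
        adopted = codes[rng.random(len(codes)) < scenario.penetration]
        hit = out["food_code"].isin(adopted).to_numpy()
        factor = r * scenario.reduction_scaling * hit
    if (factor < 0).any() or (factor > 1).any():
        raise ValidationError("effective reduction factor outside [0, 1]")
    new = out["sodium_mg"].to_numpy() * (1.0 - factor)
    out["reduction_mg"] = out["sodium_mg"].to_numpy() - new
    out["sodium_mg"] = new
    return out


def _domain_frame(model: UsualIntakeModel, demo: pd.DataFrame, by) -> pd.DataFrame:
    per = model.persons.merge(demo[["person_id", "stratum", "psu"]],
                              on="person_id", how="left")
    if "ethnicity" in by:
        per = per[per["ethnicity"].isin(REPORTED_ETHNICITIES)].copy()
    return per


def run_scenario(recalls: pd.DataFrame, demo: pd.DataFrame, scenario: Scenario,
                 by=("ethnicity", "age_group"), food_groups: pd.DataFrame | None = None,
                 lam: float | None = None, n_quadrature: int = 41,
                 weekend_frac: float = 3 / 7, day2_frac: float = 0.5,
                 n_boot: int = 0, seed: int = 0, share_lambda: bool = True,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Estimate usual intake before and after reformulation; report reductions.

    Per-person reduction = usual(before) − usual(after); the percent
    reduction uses each person's own baseline as denominator and is then
    averaged over the domain ("average of reductions in individuals"); the
    ratio-of-means variant is reported alongside.  When ``food_groups`` is
    given, single-group sub-scenarios decompose the reduction by food group.
    SEs come from a stratified PSU bootstrap shared across both arms.
    """
    if "age_group" not in demo.columns:
        demo = assign_age_groups(demo)
    model_b = fit_amount_model(recalls, demo, lam=lam, n_quadrature=n_quadrature,
                               weekend_frac=weekend_frac, day2_frac=day2_frac)
    lam_shared = model_b.lam if share_lambda else lam
    modified = apply_scenario(recalls, scenario, rng=rng)
    model_a = fit_amount_model(modified, demo, lam=lam_shared,
                               n_quadrature=n_quadrature,
                               weekend_frac=weekend_frac, day2_frac=day2_frac)
    ub = usual_intake_per_person(model_b)
    ua = usual_intake_per_person(model_a).reindex(ub.index)

    per = _domain_frame(model_b, demo, by)
    per["current_mg"] = ub.loc[per["person_id"]].to_numpy()
    per["post_mg"] = ua.loc[per["person_id"]].to_numpy()
    per["reduction_mg"] = per["current_mg"] - per["post_mg"]
    per["pct_reduction"] = 100.0 * per["reduction_mg"] / per["current_mg"]

    group_cols = {}
    if food_groups is not None:
        targeted = food_groups[food_groups["food_code"]
                               .isin(scenario.reductions.index)]
        for gid, codes in targeted.groupby("group_id")["food_code"]:
            sub_sc = scenario.replace(
                reductions=scenario.reductions.loc[
                    scenario.reductions.index.isin(codes)])
            mod_g = apply_scenario(recalls, sub_sc, rng=rng)
            model_g = fit_amount_model(mod_g, demo, lam=lam_shared,
                                       n_quadrature=n_quadrature,
                                       weekend_frac=weekend_frac,
                                       day2_frac=day2_frac)
            ug = usual_intake_per_person(model_g).reindex(ub.index)
            red_g = (ub - ug).loc[per["person_id"]].to_numpy()
            per[f"reduction_mg_group{gid}"] = red_g
            # observed share of the person's sodium coming from this group
            in_g = recalls["food_code"].isin(
                food_groups.loc[food_groups["group_id"] == gid, "food_code"])
            gshare = (recalls[in_g].groupby("person_id")["sodium_mg"].sum()
                      / recalls.groupby("person_id")["sodium_mg"].sum()).fillna(0.0)
            per[f"_gshare{gid}"] = gshare.reindex(per["person_id"]).fillna(0.0).to_numpy()
            group_cols[gid] = f"reduction_mg_group{gid}"

    rows = []
    for dom, sub in per.groupby(list(by), sort=True, observed=True):
        dom = dom if isinstance(dom, tuple) else (dom,)
        w = sub["weight"].to_numpy()
        row = {**dict(zip(by, dom)), "n": len(sub)}
        for col in ("reduction_mg", "current_mg", "post_mg", "pct_reduction"):
            row[col] = float(np.average(sub[col], weights=w))
        row["pct_reduction_ratio_of_means"] = float(
            100.0 * row["reduction_mg"] / row["current_mg"])
        for gid, col in group_cols.items():
            red_g = float(np.average(sub[col], weights=w))
            row[f"group{gid}_reduction_mg"] = red_g
            row[f"group{gid}_share_of_total_pct"] = float(
                100.0 * red_g / row["reduction_mg"]) if row["reduction_mg"] > 0 else 0.0
            g_usual = np.average(sub[f"_gshare{gid}"] * sub["current_mg"], weights=w)
            row[f"group{gid}_within_group_pct"] = float(
                100.0 * red_g / g_usual) if g_usual > 0 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)

    if n_boot > 0:
        out = _attach_bootstrap_ses(out, per, demo, model_b, model_a, by,
                                    n_boot, seed)
    else:
        out["reduction_se"] = np.nan
        out["pct_reduction_se"] = np.nan
    return out


def _attach_bootstrap_ses(out, per, demo, model_b, model_a, by, n_boot, seed):
    """Rao–Wu bootstrap SEs for the domain mean reduction and percent."""
    rng = np.random.default_rng(seed)
    fdb, fda = model_b._fd, model_a._fd
    base_w = fdb.base_person_w / fdb.base_person_w.mean()
    pos = {pid: i for i, pid in enumerate(fdb.person_ids)}
    per_pos = per["person_id"].map(pos).to_numpy()
    dom_masks = {tuple(r[list(by)]): (per[list(by)].apply(tuple, axis=1)
                                      == tuple(r[list(by)])).to_numpy()
                 for _, r in out.iterrows()}
    red_reps = {d: [] for d in dom_masks}
    pct_reps = {d: [] for d in dom_masks}
    # stratum/PSU labels aligned with the fit's person order
    merged = pd.DataFrame({"person_id": fdb.person_ids}).merge(
        demo[["person_id", "stratum", "psu"]].drop_duplicates("person_id"),
        on="person_id", how="left")
    for _ in range(n_boot):
        mult = _bootstrap_multipliers(merged[["stratum", "psu"]], rng)
        bw = base_w * mult
        if not (bw > 0).any():
            continue
        usual = {}
        for tag, m, fd in (("b", model_b, fdb), ("a", model_a, fda)):
            beta, r, rbar, s2b, s2w = _solve_at(fd, m.lam, bw)
            mu, pv = _mu_ref(fd, beta, rbar, s2b, s2w)
            rep = UsualIntakeModel(lam=m.lam, beta=m.beta,
                                   sigma2_between=s2b, sigma2_within=s2w,
                                   n_quadrature=m.n_quadrature)
            usual[tag] = rep.usual_with_var(mu, s2w + pv)
        red = usual["b"] - usual["a"]
        pct = 100.0 * red / usual["b"]
        wrep = fdb.base_person_w * mult
        for d, mask in dom_masks.items():
            p = per_pos[mask]
            wd = wrep[p]
            if wd.sum() > 0:
                red_reps[d].append(np.average(red[p], weights=wd))
                pct_reps[d].append(np.average(pct[p], weights=wd))
    out["reduction_se"] = [float(np.std(red_reps[tuple(r[list(by)])], ddof=1))
                           if len(red_reps[tuple(r[list(by)])]) > 1 else np.nan
                           for _, r in out.iterrows()]
    out["pct_reduction_se"] = [float(np.std(pct_reps[tuple(r[list(by)])], ddof=1))
                               if len(pct_reps[tuple(r[list(by)])]) > 1 else np.nan
                               for _, r in out.iterrows()]
    return out


def penetration_sweep(recalls, demo, scenario: Scenario, penetrations,
                      **kwargs) -> pd.DataFrame:
    """One scenario report per market penetration (sorted ascending)."""
    pens = sorted(float(p) for p in penetrations)
    if any(not 0 <= p <= 1 for p in pens):
        raise ValidationError("penetrations must lie in [0, 1]")
    parts = []
    for p in pens:
        rep = run_scenario(recalls, demo, scenario.replace(penetration=p), **kwargs)
        rep.insert(0, "penetration", p)
        parts.append(rep)
    return pd.concat(parts, ignore_index=True)
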