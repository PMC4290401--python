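"""Usual (long-run average) sodium intake from two-day 24-hour recalls.

Sodium is consumed at some level on nearly every day, so a one-part
"amount" measurement-error model suffices: Box–Cox-transformed person-day
totals are modeled as

    g(T_ij; lambda) = x_ij' beta + u_i + e_ij,
    u_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_w^2),

with fixed effects for the (age group × gender × ethnicity) cell, the
weekend indicator and the day-2/telephone indicator.  A person's usual
intake is the expectation of the back-transform over the day-level noise,

    U_i = E_e[ g^{-1}(mu_i + e) ],   mu_i = x_ref' beta + BLUP(u_i),

evaluated by Gauss–Hermite quadrature at reference covariates (weekend at
its population frequency, the interview-sequence indicator balanced at 1/2).

Estimation is survey-weighted throughout: the transform exponent lambda is
profiled over a grid by a weighted residual-normality score, fixed effects
come from weighted least squares, and the two variance components from
weighted method-of-moments on the residuals (the within-person variance from
day-1/day-2 residual differences).  Estimates are invariant to rescaling of
the survey weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, IdentifiabilityError, ValidationError
from .io import REPORTED_ETHNICITIES, assign_age_groups
from .survey import _psu_variance

LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
CELL_COLS = ("age_group", "gender", "ethnicity")


def boxcox(x, lam: float):
    """Box–Cox transform: (x^lam - 1)/lam, log at lam = 0.  Requires x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("boxcox requires strictly positive input")
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def inv_boxcox(z, lam: float):
    """Back-transform; values below the transform's lower bound clip to 0."""
    z = np.asarray(z, dtype=float)
    if lam == 0:
        return np.exp(z)
    return np.power(np.maximum(lam * z + 1.0, 0.0), 1.0 / lam)


def person_day_totals(recalls: pd.DataFrame) -> pd.DataFrame:
    """Sum food records to person-day totals, keeping day covariates."""
    g = recalls.groupby(["person_id", "day"], sort=True)
    out = g.agg(sodium_mg=("sodium_mg", "sum"),
                weekend=("weekend", "first")).reset_index()
    return out


class _FitData:
    """Pre-built arrays shared between the initial fit and bootstrap refits."""

    def __init__(self, recalls, demo, weekend_frac, day2_frac):
        if "age_group" not in demo.columns:
            demo = assign_age_groups(demo)
        d = person_day_totals(recalls)
        if (d["sodium_mg"] <= 0).any():
            raise DomainError("non-positive person-day sodium total; filter "
                              "zero-intake days upstream")
        d = d.merge(demo[["person_id", "weight", *CELL_COLS]],
                    on="person_id", how="inner")
        if d.empty:
            raise ValidationError("no overlap between recalls and demographics")
        d = d.sort_values(["person_id", "day"], kind="stable").reset_index(drop=True)

        persons = d.drop_duplicates("person_id").reset_index(drop=True)
        self.person_ids = persons["person_id"].to_numpy()
        pid_code = {p: i for i, p in enumerate(self.person_ids)}
        self.person_idx = d["person_id"].map(pid_code).to_numpy()
        self.n_persons = len(self.person_ids)
        self.n_days = np.bincount(self.person_idx, minlength=self.n_persons)
        if int((self.n_days >= 2).sum()) < 2:
            raise IdentifiabilityError(
                "within-person variance needs >= 2 persons with 2 recall days")

        self.y = d["sodium_mg"].to_numpy(dtype=float)
        self.cell = persons[list(CELL_COLS)].copy()
        self.cell_key = (persons["age_group"] + "|" + persons["gender"]
                         + "|" + persons["ethnicity"]).to_numpy()
        cells = sorted(set(self.cell_key))
        cell_code = {c: i for i, c in enumerate(cells)}
        self.cells = cells
        day_cell = np.array([cell_code[c] for c in self.cell_key])[self.person_idx]

        n_cells = len(cells)
        X = np.zeros((len(d), n_cells + 2))
        X[np.arange(len(d)), day_cell] = 1.0
        X[:, n_cells] = d["weekend"].to_numpy(dtype=float)
        X[:, n_cells + 1] = (d["day"] == 2).to_numpy(dtype=float)
        self.columns = [f"cell:{c}" for c in cells] + ["weekend", "day2"]
        # drop constant-zero covariate columns (e.g. a no-weekend fixture)
        keep = np.ones(X.shape[1], dtype=bool)
        for j in (n_cells, n_cells + 1):
            if np.ptp(X[:, j]) == 0:
                keep[j] = False
        self.col_keep = keep
        self.X = X[:, keep]
        self.columns = [c for c, k in zip(self.columns, keep) if k]

        Xref = np.zeros((self.n_persons, n_cells + 2))
        Xref[np.arange(self.n_persons),
             np.array([cell_code[c] for c in self.cell_key])] = 1.0
        Xref[:, n_cells] = weekend_frac
        Xref[:, n_cells + 1] = day2_frac
        self.Xref = Xref[:, keep]

        # row index of each person's first/second day (-1 when single-day)
        first = np.full(self.n_persons, -1, dtype=int)
        second = np.full(self.n_persons, -1, dtype=int)
        for row, p in enumerate(self.person_idx):
            if first[p] < 0:
                first[p] = row
            else:
                second[p] = row
        self.first_row, self.second_row = first, second
        self.base_person_w = persons["weight"].to_numpy(dtype=float)


def _wls(X, y, w):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def _solve_at(fd: _FitData, lam: float, person_w: np.ndarray):
    """WLS + moment variance components at a fixed lambda and person weights."""
    w_day = person_w[fd.person_idx]
    z = boxcox(fd.y, lam)
    beta = _wls(fd.X, z, w_day)
    r = z - fd.X @ beta
    rsum = np.bincount(fd.person_idx, weights=r, minlength=fd.n_persons)
    rbar = rsum / fd.n_days
    two = fd.second_row >= 0
    active = person_w > 0
    wt = person_w[two & active]
    if wt.sum() > 0:
        diff = r[fd.first_row[two & active]] - r[fd.second_row[two & active]]
        sigma2_w = float(0.5 * np.sum(wt * diff ** 2) / wt.sum())
    else:
        sigma2_w = 0.0
    wa = person_w[active]
    mean_inv_n = float(np.sum(wa / fd.n_days[active]) / wa.sum())
    sigma2_b = float(max(np.sum(wa * rbar[active] ** 2) / wa.sum()
                         - sigma2_w * mean_inv_n, 0.0))
    return beta, r, rbar, sigma2_b, sigma2_w


def _normality_score(r, w):
    """Weighted Jarque–Bera-style distance of residuals from normality."""
    m = np.average(r, weights=w)
    c = r - m
    s2 = np.average(c ** 2, weights=w)
    if s2 <= 0:
        return 0.0
    g1 = np.average(c ** 3, weights=w) / s2 ** 1.5
    g2 = np.average(c ** 4, weights=w) / s2 ** 2
    return float(g1 ** 2 + 0.25 * (g2 - 3.0) ** 2)


def _mu_ref(fd, beta, rbar, sigma2_b, sigma2_w):
    """Conditional person location and its posterior variance.

    The person effect enters through its full conditional distribution
    N(kappa * rbar, kappa * sigma_w^2 / n): integrating the back-transform
    over this posterior (rather than plugging in the point shrinkage
    estimate) removes the shrinkage bias of subgroup means — exactly so in
    the lognormal case.
    """
    denom = sigma2_b + sigma2_w / fd.n_days
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(denom > 0, sigma2_b / np.where(denom > 0, denom, 1.0), 0.0)
    if sigma2_b == 0 and sigma2_w == 0:
        kappa = np.ones(fd.n_persons)
    post_var = kappa * sigma2_w / fd.n_days
    return fd.Xref @ beta + kappa * rbar, post_var


@dataclass
class UsualIntakeModel:
    """Fitted amount model plus the per-person state needed for prediction."""

    lam: float
    beta: pd.Series
    sigma2_between: float
    sigma2_within: float
    n_quadrature: int = 41
    weekend_frac: float = 3 / 7
    day2_frac: float = 0.5
    persons: pd.DataFrame = None
    lambda_scores: pd.Series | None = None
    _fd: _FitData = field(default=None, repr=False)

    def usual_with_var(self, mu, var):
        """E[g^{-1}(mu + Z)], Z ~ N(0, var), by Gauss–Hermite quadrature."""
        mu = np.asarray(mu, dtype=float)
        sd = np.sqrt(np.broadcast_to(np.asarray(var, dtype=float), mu.shape))
        if np.all(sd == 0):
            return inv_boxcox(mu, self.lam)
        nodes, wts = np.polynomial.hermite.hermgauss(self.n_quadrature)
        vals = inv_boxcox(mu[..., None] + np.sqrt(2.0) * sd[..., None] * nodes,
                          self.lam)
        return vals @ (wts / np.sqrt(np.pi))

    def usual_of_mu(self, mu):
        """Usual intake of a person with known location mu (day noise only)."""
        return self.usual_with_var(mu, self.sigma2_within)


def fit_amount_model(recalls: pd.DataFrame, demo: pd.DataFrame,
                     lam: float | None = None,
                     lambda_grid=LAMBDA_GRID,
                     n_quadrature: int = 41,
                     weekend_frac: float = 3 / 7,
                     day2_frac: float = 0.5) -> UsualIntakeModel:
    """Fit the survey-weighted one-part amount model.

    ``lam=None`` profiles the Box–Cox exponent over ``lambda_grid`` by the
    weighted residual-normality score; pass a float to fix it.
    """
    if n_quadrature < 3:
        raise ValidationError("n_quadrature must be >= 3")
    fd = _FitData(recalls, demo, weekend_frac, day2_frac)
    person_w = fd.base_person_w / fd.base_person_w.mean()

    scores = None
    if lam is None:
        score_vals = []
        for lg in lambda_grid:
            _, r, *_ = _solve_at(fd, float(lg), person_w)
            score_vals.append(_normality_score(r, person_w[fd.person_idx]))
        scores = pd.Series(score_vals, index=list(lambda_grid))
        lam = float(scores.idxmin())

    beta, r, rbar, s2b, s2w = _solve_at(fd, lam, person_w)
    mu, post_var = _mu_ref(fd, beta, rbar, s2b, s2w)
    persons = fd.cell.copy()
    persons.insert(0, "person_id", fd.person_ids)
    persons["n_days"] = fd.n_days
    persons["weight"] = fd.base_person_w
    persons["rbar"] = rbar
    persons["mu_ref"] = mu
    persons["post_var"] = post_var
    model = UsualIntakeModel(
        lam=lam, beta=pd.Series(beta, index=fd.columns),
        sigma2_between=s2b, sigma2_within=s2w,
        n_quadrature=n_quadrature, weekend_frac=weekend_frac,
        day2_frac=day2_frac, persons=persons, lambda_scores=scores, _fd=fd)
    return model


def usual_intake_per_person(model: UsualIntakeModel,
                            demo: pd.DataFrame | None = None) -> pd.Series:
    """Per-person usual intake (mg/day), strictly positive.

    When ``demo`` is given the result is restricted to (and ordered by) its
    ``person_id`` column.
    """
    ui = pd.Series(
        model.usual_with_var(
            model.persons["mu_ref"].to_numpy(),
            model.sigma2_within + model.persons["post_var"].to_numpy()),
        index=model.persons["person_id"], name="usual_intake_mg")
    if demo is not None:
        ui = ui.reindex(demo["person_id"])
    return ui


def _threshold_mu(model: UsualIntakeModel, threshold: float) -> float:
    """Transformed-scale location at which usual intake equals the threshold."""
    z0 = float(boxcox(threshold, model.lam))
    lo, hi = z0 - 10.0, z0 + 10.0
    f = lambda m: float(model.usual_of_mu(np.array([m]))[0]) - threshold
    while f(lo) > 0:
        lo -= 10.0
    while f(hi) < 0:
        hi += 10.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def prop_below(model: UsualIntakeModel, thresholds=(1500.0, 2300.0)) -> pd.DataFrame:
    """Model-implied P(usual intake < threshold) per person.

    Person effects are integrated over their fitted N(0, sigma_b^2)
    distribution at the person's covariate cell, so the proportions describe
    the subgroup usual-intake *distribution* rather than the point estimates.
    """
    cell_mu = model._fd.Xref @ model.beta.to_numpy()
    sb = np.sqrt(model.sigma2_between)
    out = pd.DataFrame({"person_id": model.persons["person_id"]})
    for thr in thresholds:
        mu_star = _threshold_mu(model, float(thr))
        if sb > 0:
            p = stats.norm.cdf((mu_star - cell_mu) / sb)
        else:
            p = (cell_mu < mu_star).astype(float)
        out[f"prop_below_{int(thr)}"] = p
    return out


def _bootstrap_multipliers(demo_p: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Rao–Wu rescaled bootstrap weight multipliers, one per person row."""
    mult = np.zeros(len(demo_p))
    for stratum, sub in demo_p.groupby("stratum", sort=True):
        psus = sorted(sub["psu"].unique())
        nh = len(psus)
        if nh < 2:
            mult[sub.index] = 1.0
            continue
        draws = rng.integers(0, nh, size=nh - 1)
        counts = np.bincount(draws, minlength=nh)
        factor = {p: nh / (nh - 1) * counts[i] for i, p in enumerate(psus)}
        mult[sub.index] = sub["psu"].map(factor).to_numpy()
    return mult


def subgroup_summary(recalls: pd.DataFrame, demo: pd.DataFrame,
                     by=CELL_COLS, thresholds=(1500.0, 2300.0),
                     n_boot: int = 200, seed: int = 0,
                     lam: float | None = None, n_quadrature: int = 41,
                     weekend_frac: float = 3 / 7, day2_frac: float = 0.5,
                     model: UsualIntakeModel | None = None) -> pd.DataFrame:
    """Weighted usual-intake summary per demographic domain.

    Point estimates are survey-weighted means of per-person usual intakes;
    SEs come from a stratified PSU (Rao–Wu) bootstrap that refits the whole
    estimation chain, with the Box–Cox exponent held at its point estimate.
    ``prop_below_*`` columns are model-implied; ``*_empirical`` counterparts
    use the per-person point estimates.  Ethnicity "Other" is retained in the
    fit but excluded from the report.
    """
    if "age_group" not in demo.columns:
        demo = assign_age_groups(demo)
    if model is None:
        model = fit_amount_model(recalls, demo, lam=lam,
                                 n_quadrature=n_quadrature,
                                 weekend_frac=weekend_frac, day2_frac=day2_frac)
    fd = model._fd
    ui = usual_intake_per_person(model)
    props = prop_below(model, thresholds)

    extra = [c for c in by if c not in model.persons.columns]
    per = model.persons.merge(
        demo[["person_id", "stratum", "psu", *extra]], on="person_id", how="left")
    per["usual"] = ui.to_numpy()
    per = per.merge(props, on="person_id")
    report = per[per["ethnicity"].isin(REPORTED_ETHNICITIES)
                 | ("ethnicity" not in by)].copy()

    rows = []
    for dom, sub in report.groupby(list(by), sort=True, observed=True):
        dom = dom if isinstance(dom, tuple) else (dom,)
        w = sub["weight"].to_numpy()
        row = {**dict(zip(by, dom)), "n": len(sub),
               "mean": float(np.average(sub["usual"], weights=w))}
        for thr in thresholds:
            col = f"prop_below_{int(thr)}"
            row[col] = float(np.average(sub[col], weights=w))
            row[col + "_empirical"] = float(
                np.average((sub["usual"] < thr).astype(float), weights=w))
        row["_n_psu"] = sub.groupby(["stratum", "psu"]).ngroups
        rows.append(row)
    out = pd.DataFrame(rows)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        base_w = fd.base_person_w / fd.base_person_w.mean()
        reps = {tuple(r[list(by)]): [] for _, r in out.iterrows()}
        dom_masks = {d: (report[list(by)].apply(tuple, axis=1) == d).to_numpy()
                     for d in reps}
        report_pos = report.index.to_numpy()  # positions into per/person arrays
        for _ in range(n_boot):
            mult = _bootstrap_multipliers(per[["stratum", "psu"]], rng)
            bw = base_w * mult
            if not (bw > 0).any():
                continue
            beta, r, rbar, s2b, s2w = _solve_at(fd, model.lam, bw)
            mu, pv = _mu_ref(fd, beta, rbar, s2b, s2w)
            rep_model = UsualIntakeModel(
                lam=model.lam, beta=pd.Series(beta, index=fd.columns),
                sigma2_between=s2b, sigma2_within=s2w,
                n_quadrature=model.n_quadrature)
            usual_rep = rep_model.usual_with_var(mu, s2w + pv)
            wrep = fd.base_person_w * mult
            for d, mask in dom_masks.items():
                pos = report_pos[mask]
                wd = wrep[pos]
                if wd.sum() > 0:
                    reps[d].append(np.average(usual_rep[pos], weights=wd))
        ses = {d: (float(np.std(v, ddof=1)) if len(v) > 1 else np.nan)
               for d, v in reps.items()}
        out["se"] = [ses[tuple(r[list(by)])] for _, r in out.iterrows()]
    else:
        out["se"] = np.nan
    out.loc[out["_n_psu"] < 2, "se"] = np.nan
    out = out.drop(columns=["_n_psu"])
    cols = [*by, "n", "mean", "se"] + [c for c in out.columns
                                       if c.startswith("prop_below")]
    return out[cols]
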