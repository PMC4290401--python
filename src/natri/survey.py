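"""Design-based descriptive statistics, sodium-density metrics, and trends.

Variance estimation follows the standard with-replacement approximation for
stratified multistage samples: influence contributions are summed to PSU
totals and the between-PSU variance within each stratum is accumulated with
the ``n_h / (n_h - 1)`` factor (Taylor linearization).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, ValidationError

METRICS = ("sodium_mg_day", "sodium_per_gram", "sodium_per_kcal")


def _psu_variance(scores: np.ndarray, strata, psu, lonely_psu: str = "error"):
    """Design variance of a total of linearized scores.

    ``scores`` is (n,) or (n, k); returns the k×k covariance (scalar for k=1).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    df = pd.DataFrame(scores)
    df["_stratum"] = np.asarray(strata)
    df["_psu"] = np.asarray(psu)
    psu_tot = df.groupby(["_stratum", "_psu"], sort=True).sum()
    counts = psu_tot.groupby(level="_stratum").size()
    lonely = counts[counts < 2]
    if len(lonely) > 0:
        if lonely_psu == "error":
            raise DesignError(
                "stratum with a single PSU: " + ", ".join(map(str, lonely.index))
                + " (set lonely_psu='collapse' to merge adjacent strata)")
        elif lonely_psu == "collapse":
            order = sorted(counts.index)
            merge = {}
            for i, s in enumerate(order):
                if counts[s] < 2:
                    target = order[i + 1] if i + 1 < len(order) else order[i - 1]
                    merge[s] = target
            new_strata = pd.Series(strata).map(lambda s: merge.get(s, s)).to_numpy()
            return _psu_variance(scores, new_strata, psu, lonely_psu="error")
        else:
            raise ValueError(f"unknown lonely_psu policy {lonely_psu!r}")
    k = scores.shape[1]
    cov = np.zeros((k, k))
    for s, block in psu_tot.groupby(level="_stratum"):
        a = block.to_numpy()
        nh = a.shape[0]
        dev = a - a.mean(axis=0, keepdims=True)
        cov += nh / (nh - 1) * dev.T @ dev
    n_psu, n_strata = len(psu_tot), len(counts)
    return (cov[0, 0] if k == 1 else cov), n_psu - n_strata


def weighted_mean_se(values, weights, strata, psu, lonely_psu: str = "error"):
    """Horvitz–Thompson weighted mean with Taylor-linearized SE.

    Returns ``(mean, se)``.  The mean is invariant to rescaling of weights.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValidationError("weights must be positive")
    W = w.sum()
    mean = float(np.sum(w * y) / W)
    scores = w * (y - mean) / W
    var, _ = _psu_variance(scores, strata, psu, lonely_psu)
    return mean, float(np.sqrt(var))


def density_metrics(recalls: pd.DataFrame) -> pd.DataFrame:
    """Person-level sodium density: mg/day, mg/g food, mg/kcal.

    Densities are the person's 2-day mean sodium divided by the 2-day mean
    grams (resp. kcal).  Persons with zero kcal or gram totals are excluded
    (flagged in ``result.attrs['excluded_persons']``).
    """
    day = recalls.groupby(["person_id", "day"], sort=True).agg(
        sodium=("sodium_mg", "sum"), grams=("grams", "sum"),
        kcal=("energy_kcal", "sum"))
    per = day.groupby(level="person_id").mean()
    bad = (per["grams"] <= 0) | (per["kcal"] <= 0)
    out = per.loc[~bad].reset_index()
    out = out.rename(columns={"sodium": "sodium_mg_day"})
    out["sodium_per_gram"] = out["sodium_mg_day"] / out["grams"]
    out["sodium_per_kcal"] = out["sodium_mg_day"] / out["kcal"]
    out = out.drop(columns=["grams", "kcal"])
    out.attrs["excluded_persons"] = list(per.index[bad])
    return out


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def trend_regression(density: pd.DataFrame, demo: pd.DataFrame,
                     metrics=METRICS, by=("ethnicity", "age_group", "gender"),
                     alpha: float = 0.01, cycle_order=None,
                     granularity: str = "person",
                     lonely_psu: str = "error") -> pd.DataFrame:
    """Survey-weighted linear trend of each density metric across cycles.

    Cycles are coded 0, 1, 2, … in ``cycle_order`` (sorted labels when None);
    per-cycle weights are divided by the number of cycles combined, the
    standard practice when pooling survey cycles.  The slope's variance is
    design-based (PSU/stratum linearization of the WLS estimating equations)
    and the Wald p-value uses a t reference with (PSUs − strata) degrees of
    freedom.  ``granularity='cycle'`` instead regresses the per-cycle weighted
    means on the cycle index (OLS on one point per cycle).
    """
    df = density.merge(
        demo[["person_id", "cycle", "weight", "stratum", "psu", *by]],
        on="person_id", how="inner")
    cycles = cycle_order or sorted(df["cycle"].unique())
    if len(cycles) < 2:
        raise ValidationError("trend regression needs at least 2 cycles")
    code = {c: i for i, c in enumerate(cycles)}
    df = df[df["cycle"].isin(code)].copy()
    df["_t"] = df["cycle"].map(code).astype(float)
    df["_w"] = df["weight"] / len(cycles)

    rows = []
    all_strata = df["stratum"].to_numpy()
    all_psu = df["psu"].to_numpy()
    for dom, sub in df.groupby(list(by), sort=True, observed=True):
        dom = dom if isinstance(dom, tuple) else (dom,)
        for metric in metrics:
            y = sub[metric].to_numpy(dtype=float)
            t = sub["_t"].to_numpy()
            w = sub["_w"].to_numpy()
            X = np.column_stack([np.ones_like(t), t])
            if np.ptp(y) == 0:  # constant metric: no trend by construction
                rows.append({**dict(zip(by, dom)), "metric": metric,
                             "beta": 0.0, "se": 0.0, "p_value": 1.0,
                             "significant": False})
                continue
            if granularity == "cycle":
                cyc = sub.groupby("_t").apply(
                    lambda s: np.average(s[metric], weights=s["_w"]),
                    include_groups=False)
                res = stats.linregress(cyc.index.to_numpy(), cyc.to_numpy())
                beta, se, p = res.slope, res.stderr, res.pvalue
            else:
                beta_hat = _wls(X, y, w)
                e = y - X @ beta_hat
                A = (X * w[:, None]).T @ X
                Ainv = np.linalg.inv(A)
                psi = (w * e)[:, None] * X @ Ainv.T  # influence per obs, (n, 2)
                # domain estimation: zero scores outside the domain, full design
                psi_full = np.zeros((len(df), 2))
                psi_full[df.index.get_indexer(sub.index)] = psi
                cov, dof = _psu_variance(psi_full, all_strata, all_psu,
                                         lonely_psu)
                beta = float(beta_hat[1])
                se = float(np.sqrt(cov[1, 1]))
                if se > 0:
                    p = float(2 * stats.t.sf(abs(beta / se), df=max(dof, 1)))
                else:
                    p = 1.0 if beta == 0 else 0.0
            rows.append({**dict(zip(by, dom)), "metric": metric,
                         "beta": float(beta), "se": float(se),
                         "p_value": float(p),
                         "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
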