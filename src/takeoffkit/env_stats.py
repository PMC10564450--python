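"""Per-event behaviour/environment join and the statistical analyses.

Covers: lift-off air speed from the headwind component, the v-test for a
directional bias of take-off headings toward the wind, linear mixed
models (per-bird random intercept, ML fit) compared by AIC against a
null, Weibull/lognormal mode thresholds splitting conditions into four
wind x wave categories, variance inflation factors, and the rank/
correlation group tests. No multiple-testing correction is applied; all
p-values are reported raw.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf

from ._utils import ParameterError, wrap_pi

__all__ = ["air_speed", "relative_angle", "v_test", "fit_lmm_compare",
           "categorize_conditions", "vif", "group_tests",
           "slope_through_origin", "ModelComparison"]

DEFAULT_FIXED_SETS = {
    "null": [],
    "wave": ["Hs"],
    "wind": ["Vw"],
    "wind+wave": ["Vw", "Hs"],
    "wind+wave+interaction": ["Vw", "Hs", "Vw:Hs"],
}


def air_speed(Vr, Vw, theta_t, dir_from):
    """Air speed at lift-off: Va = Vr + Vw cos(theta_t - dir_from).

    With the coming-from wind convention a pure headwind
    (theta_t == dir_from) gives Vr + Vw and a pure tailwind Vr - Vw.
    """
    return Vr + Vw * np.cos(np.asarray(theta_t) - np.asarray(dir_from))


def relative_angle(a, b):
    """Wrapped signed difference a - b in (-pi, pi]; the tie at pi -> +pi."""
    return wrap_pi(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def v_test(angles, mu0):
    """v-test (modified Rayleigh) for concentration around ``mu0``.

    V is the mean resultant length projected onto mu0, u = V*sqrt(2n),
    and p is the upper tail of the standard normal at u.
    Returns (V, u, p).
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 5:
        raise ParameterError(f"v-test needs n >= 5, got {n}")
    V = float(np.mean(np.cos(a - mu0)))
    u = float(V * np.sqrt(2.0 * n))
    p = float(sps.norm.sf(u))
    return V, u, p


@dataclass
class ModelComparison:
    """AIC table for one response across nested fixed-effect sets."""

    response: str
    table: pd.DataFrame  # columns: model, k_fixed, aic, p_chisq, converged
    best: str

    def as_records(self):
        out = self.table.copy()
        out.insert(0, "response", self.response)
        out["best"] = out["model"] == self.best
        return out


def _lmm_fit(df, response, terms, group):
    formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[group])
        try:
            res = model.fit(reml=False)
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell")
    k_fixed = len(res.fe_params)
    # Gaussian random-intercept LMM: fixed effects + RE variance + resid var
    aic = -2.0 * res.llf + 2.0 * (k_fixed + 2)
    return res, k_fixed, aic


def fit_lmm_compare(data: pd.DataFrame, response: str,
                    fixed_sets: dict | None = None,
                    group: str = "bird_id") -> ModelComparison:
    """Fit mixed models (per-bird random intercept, ML) and compare by AIC.

    Each entry of ``fixed_sets`` maps a label to a list of fixed-effect
    terms (patsy syntax; [] is the null model). Reports AIC per model and
    a likelihood-ratio chi-square p-value against the null; the best model
    is the converged row with minimal AIC.
    """
    fixed_sets = fixed_sets or DEFAULT_FIXED_SETS
    needed = {response, group} | {
        t for terms in fixed_sets.values() for t in terms if ":" not in t
    }
    df = data.dropna(subset=[c for c in needed if c in data.columns])
    if len(df) < 30:
        raise ParameterError(
            f"{response}: only {len(df)} complete rows; need >= 30"
        )
    if df[group].nunique() < 5:
        raise ParameterError(
            f"{response}: only {df[group].nunique()} groups; need >= 5"
        )
    rows = []
    fits = {}
    for label, terms in fixed_sets.items():
        try:
            res, k_fixed, aic = _lmm_fit(df, response, terms, group)
            converged = bool(res.converged)
        except Exception:
            res, k_fixed, aic, converged = None, len(terms) + 1, np.nan, False
        fits[label] = res
        rows.append({"model": label, "k_fixed": k_fixed, "aic": aic,
                     "converged": converged})
    table = pd.DataFrame(rows)
    null_label = next((l for l, t in fixed_sets.items() if not t), None)
    if null_label is not None and fits.get(null_label) is not None:
        llf0 = fits[null_label].llf
        k0 = len(fits[null_label].fe_params)
        pvals = []
        for r in rows:
            res = fits[r["model"]]
            if r["model"] == null_label or res is None:
                pvals.append(np.nan)
            else:
                lr = 2.0 * (res.llf - llf0)
                ddf = r["k_fixed"] - k0
                pvals.append(float(sps.chi2.sf(max(lr, 0.0), ddf))
                             if ddf > 0 else np.nan)
        table["p_chisq"] = pvals
    ok = table[table["converged"] & table["aic"].notna()]
    best = str(ok.loc[ok["aic"].idxmin(), "model"]) if len(ok) else ""
    return ModelComparison(response=response, table=table, best=best)


def weibull_mode(k, lam):
    """Mode of a Weibull(k, lam) density; requires k > 1."""
    if k <= 1:
        raise ParameterError(
            f"Weibull shape k={k:.3f} <= 1: density has no interior mode; "
            "supply explicit thresholds"
        )
    return lam * ((k - 1.0) / k) ** (1.0 / k)


def lognormal_mode(mu, sigma):
    """Mode of a lognormal(mu, sigma) density: exp(mu - sigma^2)."""
    return np.exp(mu - sigma**2)


def categorize_conditions(Vw, Hs, thresholds=None):
    """Split (wind, wave) pairs into the four categories WL/WH/SL/SH.

    Thresholds default to the density modes of a Weibull fitted to wind
    speed and a lognormal fitted to wave height (both by maximum
    likelihood, location fixed at 0). W/S = wind below/at-or-above the
    wind mode; L/H = wave below/at-or-above the wave mode.
    Returns ((wind_thr, wave_thr), labels array).
    """
    Vw = np.asarray(Vw, dtype=float)
    Hs = np.asarray(Hs, dtype=float)
    if thresholds is None:
        if Vw.size < 30:
            raise ParameterError("need >= 30 paired observations")
        k, _, lam = sps.weibull_min.fit(Vw, floc=0)
        wind_thr = float(weibull_mode(k, lam))
        s, _, scale = sps.lognorm.fit(Hs, floc=0)
        wave_thr = float(lognormal_mode(np.log(scale), s))
    else:
        wind_thr, wave_thr = thresholds
    strong = Vw >= wind_thr
    high = Hs >= wave_thr
    labels = np.where(strong, np.where(high, "SH", "SL"),
                      np.where(high, "WH", "WL"))
    return (wind_thr, wave_thr), labels


def vif(X: pd.DataFrame, add_interaction: bool = False) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j on the remaining columns plus an
    intercept. ``add_interaction`` appends the uncentred product of the
    first two columns before computing. Perfect collinearity reports inf.
    """
    X = pd.DataFrame(X).astype(float).dropna()
    if add_interaction:
        c0, c1 = X.columns[:2]
        X = X.assign(**{f"{c0}:{c1}": X[c0] * X[c1]})
    out = {}
    cols = list(X.columns)
    for j, col in enumerate(cols):
        y = X[col].to_numpy()
        others = X[[c for c in cols if c != col]].to_numpy()
        A = np.column_stack([np.ones(len(X)), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        ssr = float(resid @ resid)
        r2 = 1.0 - ssr / sst if sst > 0 else 1.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def slope_through_origin(x, y):
    """Least-squares slope of y = b*x with the intercept fixed at zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(x * y) / np.sum(x * x))


def group_tests(groups: dict[str, np.ndarray] | None = None,
                paired: tuple | None = None) -> dict:
    """Rank and correlation tests used by the category comparisons.

    ``groups`` maps label -> sample; two groups run a two-sided
    Mann-Whitney U (exact when both n <= 8 and tie-free), more run a
    Kruskal-Wallis. ``paired`` = (x, y) adds a Pearson correlation and
    the through-origin regression slope. Degenerate (all-tied) input
    reports p = 1 with a flag.
    """
    report: dict = {}
    if groups:
        samples = [np.asarray(v, dtype=float) for v in groups.values()]
        if len(samples) < 2 or any(s.size < 3 for s in samples):
            raise ParameterError("need >= 2 groups with n >= 3 each")
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            report["degenerate"] = True
            key = "mannwhitney_p" if len(samples) == 2 else "kruskal_p"
            report[key] = 1.0
            return report
        report["degenerate"] = False
        if len(samples) == 2:
            x, y = samples
            method = ("exact" if x.size <= 8 and y.size <= 8
                      and np.unique(pooled).size == pooled.size else "auto")
            res = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method=method)
            report["mannwhitney_U"] = float(res.statistic)
            report["mannwhitney_p"] = float(res.pvalue)
        else:
            res = sps.kruskal(*samples)
            report["kruskal_H"] = float(res.statistic)
            report["kruskal_p"] = float(res.pvalue)
    if paired is not None:
        x, y = (np.asarray(v, dtype=float) for v in paired)
        r, p = sps.pearsonr(x, y)
        report["pearson_r"] = float(r)
        report["pearson_p"] = float(p)
        report["slope_origin"] = slope_through_origin(x, y)
    return report
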