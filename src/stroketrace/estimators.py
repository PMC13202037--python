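"""Estimators: direct standardisation, competing risks, Cox, adjusted means.

* Direct age-sex standardisation to the European Standard Population (ESP
  2013) with gamma (Fay-Feuer) confidence intervals.
* Aalen-Johansen cumulative incidence of first dispensing with death as a
  competing event.
* Cause-specific Cox proportional hazards (partial likelihood via
  lifelines, Breslow ties) with in-package Breslow baseline hazards and a
  g-computation (marginal standardisation) covariate-adjusted cumulative
  incidence.
* Crude and linear-model-adjusted marginal mean home-time.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EVENT_CODES = ("censored", "dispensed", "death")


# ----------------------------------------------------------------------
# direct standardisation


def load_esp_weights() -> pd.Series:
    """ESP 2013 weights by 5-year age band (sums to 100 000)."""
    ref = importlib.resources.files("stroketrace.data") / "esp2013.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("age_band")["weight"]


def adult_esp_weights(bands) -> dict:
    """ESP weights restricted to adult bands.

    The 18-19 sliver inherits the 15-19 band's weight; bands below 18 are
    dropped.  Normalisation happens inside the estimator, so raw weights
    are returned.
    """
    esp = load_esp_weights()
    out = {}
    for band in bands:
        key = "15-19" if band == "18-19" else band
        out[band] = float(esp[key])
    return out


@dataclass
class RatePoint:
    """A standardised rate with its gamma 95% CI, per 100 000 person-years."""
    rate: float
    ci_low: float
    ci_high: float
    crude_rate: float
    events: float
    person_years: float


def direct_standardised_rate(strata: pd.DataFrame, weights: dict,
                             per: float = 100_000.0,
                             alpha: float = 0.05) -> RatePoint:
    """Directly standardised rate over strata of events and person-time.

    ``strata`` needs columns ``age_band``, ``events``, ``person_years`` and
    optionally ``sex``; when sex is present the ESP age weight is split
    equally between the sexes.  ``weights`` maps age_band to standard
    population weight.  The CI is the gamma interval of Fay & Feuer, which
    retains coverage at small event counts.
    """
    df = strata.copy()
    if df.empty:
        raise ValueError("no strata supplied")
    n_sex = df["sex"].nunique() if "sex" in df.columns else 1
    w = df["age_band"].map(weights).astype(float) / max(n_sex, 1)
    if w.isna().any():
        missing = df.loc[w.isna(), "age_band"].unique().tolist()
        raise ValueError(f"no standard weight for age band(s) {missing}")
    bad = (w > 0) & (df["person_years"] <= 0)
    if bad.any():
        strat = df.loc[bad].iloc[0]
        label = strat["age_band"] + (f"/{strat['sex']}" if "sex" in df.columns else "")
        raise ValueError(f"stratum {label} has positive weight but no person-time")

    wn = (w / w.sum()).to_numpy()
    d = df["events"].to_numpy(dtype=float)
    t = df["person_years"].to_numpy(dtype=float)
    x = float(np.sum(wn * d / t))          # standardised rate per person-year
    v = float(np.sum(wn ** 2 * d / t ** 2))
    wmax = float(np.max(wn / t))

    if x > 0:
        lo = v / (2 * x) * stats.chi2.ppf(alpha / 2, 2 * x ** 2 / v)
    else:
        lo = 0.0
    hi = ((v + wmax ** 2) / (2 * (x + wmax))
          * stats.chi2.ppf(1 - alpha / 2, 2 * (x + wmax) ** 2 / (v + wmax ** 2)))
    crude = float(d.sum() / t.sum())
    return RatePoint(rate=x * per, ci_low=lo * per, ci_high=hi * per,
                     crude_rate=crude * per, events=float(d.sum()),
                     person_years=float(t.sum()))


# ----------------------------------------------------------------------
# Aalen-Johansen cumulative incidence with competing death


@dataclass
class CifCurve:
    """Cumulative incidence functions on a shared event-time grid.

    ``table`` has columns time, n_risk, surv and cif_<cause>; survival and
    the CIFs partition unity at every event time.
    """
    table: pd.DataFrame
    causes: tuple

    def cif_at(self, cause: str, t: float) -> float:
        col = f"cif_{cause}"
        sel = self.table[self.table["time"] <= t]
        return float(sel[col].iloc[-1]) if len(sel) else 0.0

    def surv_at(self, t: float) -> float:
        sel = self.table[self.table["time"] <= t]
        return float(sel["surv"].iloc[-1]) if len(sel) else 1.0


def aalen_johansen(times, events, causes=("dispensed", "death")) -> CifCurve:
    """Aalen-Johansen estimator of the cause-specific CIFs.

    ``events`` holds "censored" or one of ``causes``.  Ties between events
    and censorings at the same time keep the censored subjects in the risk
    set (the usual convention).  CIF_k(t) = sum over event times u <= t of
    S(u-) d_k(u)/n(u) with S the all-cause product-limit survival.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=object)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative event times")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    n = times.size

    uniq = np.unique(times[np.isin(events, causes)])
    rows = []
    surv = 1.0
    cif = {c: 0.0 for c in causes}
    for t in uniq:
        at_risk = int(np.sum(times >= t))
        d = {c: int(np.sum((times == t) & (events == c))) for c in causes}
        d_tot = sum(d.values())
        if at_risk == 0:
            break
        for c in causes:
            cif[c] += surv * d[c] / at_risk
        surv *= 1.0 - d_tot / at_risk
        rows.append({"time": t, "n_risk": at_risk, "surv": surv,
                     **{f"cif_{c}": cif[c] for c in causes},
                     **{f"d_{c}": d[c] for c in causes}})
    table = pd.DataFrame(rows, columns=["time", "n_risk", "surv"]
                         + [f"cif_{c}" for c in causes] + [f"d_{c}" for c in causes])
    return CifCurve(table=table, causes=tuple(causes))


# ----------------------------------------------------------------------
# cause-specific Cox with Breslow baselines


@dataclass
class ModelFit:
    """A fitted cause-specific Cox model (or a flagged non-convergent one)."""
    cause: str
    converged: bool
    params: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    se: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    baseline: pd.DataFrame = field(default_factory=pd.DataFrame)  # time, dH0


def _breslow_baseline(times, is_cause, eta) -> pd.DataFrame:
    """Breslow jumps dH0(t) = d(t) / sum_{at risk} exp(x'beta)."""
    order = np.argsort(times, kind="mergesort")
    t, ev, e = times[order], is_cause[order], eta[order]
    uniq = np.unique(t[ev])
    rows = []
    for u in uniq:
        denom = e[t >= u].sum()
        d = int(ev[t == u].sum())
        rows.append({"time": u, "dH0": d / denom})
    return pd.DataFrame(rows, columns=["time", "dH0"])


def fit_cox_cause_specific(X: pd.DataFrame, times, events, cause: str,
                           max_steps: int = 100) -> ModelFit:
    """Cause-specific Cox model: other-cause events are censored.

    Partial-likelihood maximisation is delegated to lifelines (Breslow tie
    handling, Newton-Raphson); a fit that fails to converge — separation,
    no events — is returned flagged with no estimates.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=object)
    is_cause = events == cause
    if X.shape[1] == 0:
        # null model: baseline only, exactly the non-parametric hazard
        base = _breslow_baseline(times, is_cause, np.ones_like(times))
        return ModelFit(cause=cause, converged=True, baseline=base)
    if is_cause.sum() == 0:
        return ModelFit(cause=cause, converged=False)

    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = X.reset_index(drop=True).copy()
    df["_T"] = times
    df["_E"] = is_cause.astype(int)
    cph = CoxPHFitter(baseline_estimation_method="breslow")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_T", event_col="_E",
                    fit_options={"max_steps": max_steps, "precision": 1e-9})
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return ModelFit(cause=cause, converged=False)
    params = cph.params_
    se = cph.standard_errors_
    # monotone partial likelihood (separation) shows up as a drifting
    # coefficient with an enormous standard error rather than an exception
    if not (np.isfinite(params).all() and np.isfinite(se).all()
            and np.abs(params).max() < 10 and se.max() < 20):
        return ModelFit(cause=cause, converged=False)
    eta = np.exp(X.to_numpy(dtype=float) @ params.to_numpy())
    base = _breslow_baseline(times, is_cause, eta)
    return ModelFit(cause=cause, converged=True, params=params, se=se, baseline=base)


def adjusted_cif(fits: dict, X: pd.DataFrame,
                 causes=("dispensed", "death")) -> CifCurve:
    """Covariate-adjusted CIFs by g-computation (marginal standardisation).

    Per covariate pattern, the two cause-specific hazards are combined in
    discrete product-limit form — S(t|x) = prod(1 - sum_k dH_k(u|x)) — and
    the resulting per-pattern CIFs are averaged over the observed covariate
    distribution.  With null covariate effects this reduces exactly to the
    Aalen-Johansen estimator.
    """
    for c in causes:
        if not fits[c].converged:
            raise ValueError(f"cause-specific fit for {c!r} did not converge")

    grid = np.unique(np.concatenate([
        fits[c].baseline["time"].to_numpy() for c in causes
        if len(fits[c].baseline)]))
    if grid.size == 0:
        raise ValueError("no events in either cause")
    jumps = {}
    for c in causes:
        base = fits[c].baseline.set_index("time")["dH0"]
        jumps[c] = base.reindex(grid, fill_value=0.0).to_numpy(dtype=float)

    if X.shape[1] == 0:
        patterns = np.zeros((1, 0))
        weights = np.array([1.0])
    else:
        counts = X.groupby(list(X.columns), sort=False).size()
        Xu = counts.index.to_frame(index=False)
        patterns = Xu.to_numpy(dtype=float)
        weights = counts.to_numpy(dtype=float) / len(X)

    m = grid.size
    cif_acc = {c: np.zeros(m) for c in causes}
    surv_acc = np.zeros(m)
    for pat, w in zip(patterns, weights):
        j = {}
        for c in causes:
            beta = fits[c].params.to_numpy() if len(fits[c].params) else np.zeros(0)
            eta = float(np.exp(pat @ beta)) if beta.size else 1.0
            j[c] = jumps[c] * eta
        total = sum(j.values())
        surv_factors = np.clip(1.0 - total, 0.0, 1.0)
        surv = np.cumprod(surv_factors)
        surv_prev = np.concatenate([[1.0], surv[:-1]])
        for c in causes:
            cif_acc[c] += w * np.cumsum(surv_prev * j[c])
        surv_acc += w * surv

    table = pd.DataFrame({"time": grid, "n_risk": np.nan, "surv": surv_acc,
                          **{f"cif_{c}": cif_acc[c] for c in causes}})
    return CifCurve(table=table, causes=tuple(causes))


# ----------------------------------------------------------------------
# crude and adjusted mean home-time


def mean_home_time(df: pd.DataFrame, stratum: str, outcome: str = "home_days",
                   adjust_for: list | None = None, alpha: float = 0.05):
    """Crude mean home-time per stratum and OLS-adjusted marginal means.

    Returns a DataFrame with one row per stratum level: n, crude mean with
    normal-approximation CI, and (when ``adjust_for`` is given) the
    g-computation marginal mean — the average model prediction with every
    subject's stratum set to that level.  Empty strata are omitted.
    """
    import statsmodels.formula.api as smf

    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for level, grp in df.groupby(stratum, observed=True, sort=True):
        n = len(grp)
        mean = grp[outcome].mean()
        se = grp[outcome].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        se = 0.0 if not np.isfinite(se) else se
        rows.append({stratum: level, "n": n, "crude_mean": mean,
                     "ci_low": mean - z * se, "ci_high": mean + z * se})
    out = pd.DataFrame(rows)

    if adjust_for is not None:
        work = df.dropna(subset=[outcome, stratum] + adjust_for).copy()
        terms = [f"C({stratum})"]
        for cov in adjust_for:
            terms.append(f"C({cov})" if work[cov].dtype == object or str(work[cov].dtype) == "category"
                         else cov)
        model = smf.ols(f"{outcome} ~ {' + '.join(terms)}", data=work).fit()
        adjusted = []
        for level in out[stratum]:
            counterfactual = work.copy()
            counterfactual[stratum] = level
            adjusted.append(float(model.predict(counterfactual).mean()))
        out["adjusted_mean"] = adjusted
    return out
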