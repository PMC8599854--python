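"""Cohort-level and survival statistics.

Thin, contract-checked wrappers over scipy and lifelines for the tests used
in cohort comparisons: two-sided Mann-Whitney (exact for small untied
samples), Spearman rank correlation, Pearson chi-squared on contingency
tables *without* continuity correction (the convention that reproduces the
printed clinical-table p-values), Kaplan-Meier curves with the two-sided
log-rank test, univariate Cox proportional-hazards fits (Efron ties), and
median / positivity dichotomization of continuous biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


def compare_groups(x, y) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact p-value when combined n <= 20 and there are no ties; otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "method": "exact" if exact else "asymptotic"}


def correlate(x, y) -> dict:
    """Spearman rank correlation with two-tailed p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return {"rho": float("nan"), "p_value": float("nan"), "flag": "constant_input"}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "flag": ""}


def contingency_chi2(table) -> dict:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p_value": float(p)}


def dichotomize(values: pd.Series, rule: str = "median") -> pd.Series:
    """Assign 'high'/'low' by median split, or 'positive'/'negative' by > 0.

    Median rule: high iff value > median (values at the median go low).
    Errors on a degenerate median split (all values identical).
    """
    v = pd.Series(values, dtype=float)
    if rule == "median":
        if len(v) < 2:
            raise ValueError("median split needs at least 2 values")
        if v.nunique() == 1:
            raise ValueError("degenerate median split: all values identical")
        med = float(v.median())
        return pd.Series(np.where(v > med, "high", "low"), index=v.index)
    if rule == "positive":
        return pd.Series(np.where(v > 0, "positive", "negative"), index=v.index)
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival
    statistic: float
    p_value: float
    flagged_groups: list[str]  # groups with zero events


def km_logrank(records: pd.DataFrame, groups: pd.Series) -> KmResult:
    """Kaplan-Meier curves per group plus the two-sided log-rank test.

    ``records`` needs columns time and event (1 = death). Errors with a
    single group; groups with zero events are computed but flagged.
    """
    g = pd.Series(groups)
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    curves, flagged = {}, []
    for lab in labels:
        sub = records[g == lab]
        if sub["event"].sum() == 0:
            flagged.append(lab)
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[lab] = sf
    res = multivariate_logrank_test(records["time"], g, records["event"])
    return KmResult(curves, float(res.test_statistic), float(res.p_value), flagged)


def cox_univariate(records: pd.DataFrame, covariate: pd.Series) -> dict:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Returns the hazard ratio per unit of the covariate with its 95% CI and
    Wald p. Pre-conditions follow standard practice for a stable fit:
    >=10 patients, >=5 events, non-constant covariate.
    """
    df = pd.DataFrame({
        "time": records["time"].to_numpy(dtype=float),
        "event": records["event"].to_numpy(dtype=int),
        "x": np.asarray(covariate, dtype=float),
    })
    if len(df) < 10:
        raise ValueError("need at least 10 patients")
    if df["event"].sum() < 5:
        raise ValueError("need at least 5 events")
    if df["x"].nunique() == 1:
        raise ValueError("constant covariate")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence failure
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary.loc["x"]
    return {
        "log_hr": float(s["coef"]),
        "hr": float(s["exp(coef)"]),
        "ci_low": float(np.exp(s["coef lower 95%"])),
        "ci_high": float(np.exp(s["coef upper 95%"])),
        "p_value": float(s["p"]),
        "n": int(len(df)),
        "n_events": int(df["event"].sum()),
    }
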