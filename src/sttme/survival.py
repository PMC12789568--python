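"""Triple-marker TME stratification and survival / relapse analysis.

The uncommon, macrophage-rich / CD40LG-poor microenvironment is defined
per patient as CD68 > cut AND CD163 > cut AND CD40LG <= cut, with
cohort-median cut points by default.  Event-free survival runs from
diagnosis to refractoriness, relapse or death; overall survival to
death.  Kaplan-Meier curves and the two-group log-rank test are
implemented natively (Mantel-Haenszel treatment of ties); multivariate
Cox regression is delegated to lifelines behind a thin contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MARKERS = ("CD68", "CD163", "CD40LG")
UNCOMMON = "uncommon_TME"
OTHER = "other"

ENDPOINTS = {"efs": ("efs_days", "efs_event"), "os": ("os_days", "os_event")}


@dataclass
class StratificationResult:
    groups: pd.Series  # per patient: uncommon_TME / other
    cutpoints: dict[str, float]


def stratify(cohort: pd.DataFrame,
             cutpoints: dict[str, float] | None = None) -> StratificationResult:
    """Assign each patient to uncommon_TME or other by the triple rule.

    uncommon_TME iff CD68 > cut68 AND CD163 > cut163 AND CD40LG <=
    cut40lg.  Default cut points are the per-marker cohort medians
    (explicit overrides accepted).  Patients missing any marker are
    excluded with a warning.
    """
    missing_cols = [m for m in MARKERS if m not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort missing marker columns: {missing_cols}")
    complete = cohort[list(MARKERS)].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"{int((~complete).sum())} patients missing a marker; excluded")
    sub = cohort[complete]
    cuts = dict(cutpoints) if cutpoints else {
        m: float(sub[m].median()) for m in MARKERS}
    uncommon = ((sub["CD68"] > cuts["CD68"])
                & (sub["CD163"] > cuts["CD163"])
                & (sub["CD40LG"] <= cuts["CD40LG"]))
    groups = pd.Series(np.where(uncommon, UNCOMMON, OTHER), index=sub.index, name="group")
    return StratificationResult(groups=groups, cutpoints=cuts)


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with event/censor tables.

    Returns one row per distinct event time: n_risk, n_events,
    n_censored (in (previous time, t]) and the survival estimate.  With
    no censoring the curve equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)
    rows = []
    surv = 1.0
    at_risk = n
    i = 0
    while i < n:
        t = times[i]
        d = c = 0
        while i < n and times[i] == t:
            d += events[i]
            c += 1 - events[i]
            i += 1
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append({"time": t, "n_risk": at_risk, "n_events": d,
                         "n_censored": c, "survival": surv})
        at_risk -= d + c
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events", "n_censored", "survival"])


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank chi-square and p (hypergeometric variance).

    All subjects tied at an event time share the same risk set.  A
    degenerate comparison (no events, or one group empty of risk) gives
    statistic 0, p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {len(labels)}")
    g1 = groups == labels[0]
    observed = expected = variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def km_logrank(cohort: pd.DataFrame, groups: pd.Series,
               endpoint: str = "efs") -> tuple[dict[str, pd.DataFrame], float, float]:
    """KM curves per group plus the two-group log-rank test."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}")
    tcol, ecol = ENDPOINTS[endpoint]
    sub = cohort.loc[groups.index]
    if sub[ecol].sum() < 1:
        raise ValueError("no events at all; survival comparison undefined")
    curves = {}
    for label, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {label} is empty")
        curves[str(label)] = km_curve(sub.loc[idx, tcol], sub.loc[idx, ecol])
    chi2, p = logrank(sub[tcol], sub[ecol], groups.to_numpy())
    return curves, chi2, p


def relapse_test(cohort: pd.DataFrame, groups: pd.Series) -> tuple[pd.DataFrame, float]:
    """Two-sided Fisher exact test of relapse x group.

    Returns the 2x2 table (groups x relapse yes/no) and p.  A table with
    a zero margin reports p = 1 with a warning.
    """
    sub = cohort.loc[groups.index]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("relapse test needs exactly two groups")
    table = pd.DataFrame(
        [[int(((groups == g) & (sub["relapse"] == 1)).sum()),
          int(((groups == g) & (sub["relapse"] == 0)).sum())] for g in labels],
        index=labels, columns=["relapse", "no_relapse"])
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate relapse table; p set to 1")
        return table, 1.0
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return table, float(p)


def cox_multivariate(cohort: pd.DataFrame, groups: pd.Series,
                     covariates: list[str] | None = None,
                     endpoint: str = "efs") -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit (lifelines backend).

    The group indicator (1 = uncommon_TME) enters alongside the listed
    covariates; returns hazard ratios with 95% CIs and p per term.
    Constant covariates and non-convergence raise explicit errors.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = covariates or []
    tcol, ecol = ENDPOINTS[endpoint]
    df = cohort.loc[groups.index, [tcol, ecol] + covariates].copy()
    df["group_uncommon"] = (groups == UNCOMMON).astype(float)
    for c in covariates + ["group_uncommon"]:
        if df[c].dtype == object:
            df[c] = pd.factorize(df[c], sort=True)[0].astype(float)
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c} is constant")
    n_events = int(df[ecol].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(f"{n_events} events cannot support {len(covariates) + 1} terms")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=tcol, event_col=ecol)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    summ = cph.summary
    return pd.DataFrame({
        "term": summ.index,
        "hr": np.exp(summ["coef"]).to_numpy(),
        "hr_ci_low": np.exp(summ["coef lower 95%"]).to_numpy(),
        "hr_ci_high": np.exp(summ["coef upper 95%"]).to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
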