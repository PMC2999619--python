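"""Cohort-level statistics: chi-square association tables, Kaplan-Meier /
log-rank survival comparisons, Cox proportional-hazards models (Efron ties)
and Spearman rank correlation.

Conventions: Pearson chi-square without continuity correction (df = 1 for
2x2 tables); p-values formatted to three decimals with "<0.001" below that
resolution; subgroup analyses are row filters, not interaction terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

#: Covariate set of the adjusted (multivariate) models.
MULTIVARIATE_COVARIATES = (
    "nodal", "grade", "er", "pr", "her2", "size_group", "age_group",
)


def format_p(p: float) -> str:
    """Three-decimal p-value string, '<0.001' below resolution."""
    if math.isnan(p):
        return "NA"
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi_square: float
    df: int
    p: float


def contingency_test(table) -> ContingencyResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table < 0).any():
        raise ValueError("cell counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(table=table, chi_square=float(chi2), df=int(df), p=float(p))


def build_table1(
    cohort: pd.DataFrame,
    stratifier: str,
    covariates: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """Association table: counts, within-stratum percentages and chi-square p
    per covariate, with per-covariate unknown (missing) rows carried along.

    ``stratifier`` must be a two-level column (e.g. ``cnr_group``); rows with
    a missing stratifier value are excluded up front.
    """
    strat = cohort[cohort[stratifier].notna()]
    strata = sorted(strat[stratifier].dropna().unique().tolist())
    if len(strata) != 2:
        raise ValueError(f"stratifier {stratifier} must have exactly 2 levels, got {strata}")
    for s in strata:
        if not (strat[stratifier] == s).any():
            raise ValueError(f"empty stratum {s}")

    rows = []
    for cov, levels in covariates.items():
        known = strat[strat[cov].notna()]
        counts = np.zeros((2, 2), dtype=int)
        for i, level in enumerate(levels):
            for j, s in enumerate(strata):
                counts[i, j] = int(((known[cov] == level) & (known[stratifier] == s)).sum())
        res = contingency_test(counts.T)  # strata as rows, levels as columns
        col_totals = counts.sum(axis=0)
        for i, level in enumerate(levels):
            row = {"covariate": cov, "level": level, "p": res.p, "p_formatted": format_p(res.p)}
            for j, s in enumerate(strata):
                row[f"n_{s}"] = counts[i, j]
                row[f"pct_{s}"] = round(100.0 * counts[i, j] / col_totals[j], 1) if col_totals[j] else 0.0
            rows.append(row)
        unknown = int(strat[cov].isna().sum())
        if unknown:
            rows.append({"covariate": cov, "level": "Unknown", "p": math.nan,
                         "p_formatted": "", **{f"n_{s}": int(((strat[cov].isna()) & (strat[stratifier] == s)).sum()) for s in strata}})
    return pd.DataFrame(rows)


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "survival": self.survival, "group": self.group})


def km_estimate(times, events, groups) -> dict[str, KMCurve]:
    """Product-limit survival estimate per group."""
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative survival times")
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        tbl = kmf.event_table
        out[str(g)] = KMCurve(
            group=str(g),
            times=tbl.index.to_numpy(float),
            at_risk=tbl["at_risk"].to_numpy(float),
            survival=kmf.survival_function_["KM_estimate"].to_numpy(float),
        )
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(levels)}")
    res = multivariate_logrank_test(np.asarray(times, float), groups,
                                    np.asarray(events, bool))
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Estimates for one covariate (or one joint model)."""

    estimates: pd.DataFrame  # per covariate: hazard_ratio, ci_low, ci_high, p, coef
    log_likelihood: float
    converged: bool
    n: int
    n_events: int

    def validate(self) -> None:
        e = self.estimates
        if not ((e["ci_low"] < e["hazard_ratio"]) & (e["hazard_ratio"] < e["ci_high"])).all():
            raise ValueError("confidence bounds do not bracket the hazard ratio")
        if not np.allclose(e["hazard_ratio"], np.exp(e["coef"])):
            raise ValueError("hazard ratio is not exp(coef)")


def _design_column(cohort: pd.DataFrame, cov: str) -> pd.Series:
    col = cohort[cov]
    if col.dtype == bool:
        return col.astype(float)
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.dropna().unique().tolist())
        if len(levels) != 2:
            raise ValueError(f"covariate {cov} is not binary: {levels}")
        return (col == levels[1]).astype(float)
    return col.astype(float)


def cox_fit(
    cohort: pd.DataFrame,
    covariates,
    outcome: str = "bcss",
    multivariate: bool = False,
    subgroup: pd.Series | None = None,
    min_events: int = 10,
) -> dict[str, CoxResult] | CoxResult:
    """Cox proportional-hazards regression with Efron tie handling.

    Univariate mode (default) fits one model per covariate and returns a
    mapping; multivariate mode fits them jointly.  ``subgroup`` is a boolean
    row filter implementing stratified subgroup analyses.
    """
    if outcome not in ("os", "bcss"):
        raise ValueError("outcome must be 'os' or 'bcss'")
    df = cohort if subgroup is None else cohort[np.asarray(subgroup, bool)]
    time_col, event_col = f"{outcome}_time", f"{outcome}_event"
    covariates = list(covariates)

    def fit_one(cols) -> CoxResult:
        data = pd.DataFrame({time_col: df[time_col].astype(float),
                             event_col: df[event_col].astype(bool)})
        for c in cols:
            x = _design_column(df, c)
            if x.nunique(dropna=True) < 2:
                raise ValueError(f"covariate {c} is constant")
            data[c] = x
        data = data.dropna()
        n_events = int(data[event_col].sum())
        if n_events < min_events:
            raise ValueError(f"only {n_events} events; need >= {min_events}")
        cph = CoxPHFitter()
        converged = True
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except Exception:
            converged = False
            cph.fit(data, duration_col=time_col, event_col=event_col,
                    fit_options={"step_size": 0.25})
        summ = cph.summary
        est = pd.DataFrame({
            "covariate": summ.index,
            "coef": summ["coef"].to_numpy(),
            "hazard_ratio": summ["exp(coef)"].to_numpy(),
            "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
            "p": summ["p"].to_numpy(),
        }).reset_index(drop=True)
        res = CoxResult(estimates=est, log_likelihood=float(cph.log_likelihood_),
                        converged=converged, n=len(data), n_events=n_events)
        res.validate()
        return res

    if multivariate:
        return fit_one(covariates)
    return {c: fit_one([c]) for c in covariates}


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    defined: bool = True


def spearman_rho(x, y, min_pairs: int = 5) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < min_pairs:
        raise ValueError(f"only {len(x)} complete pairs; need >= {min_pairs}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=math.nan, p=math.nan, n=len(x), defined=False)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(x))
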