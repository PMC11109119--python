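"""Survival analysis: Kaplan-Meier, log-rank, Cox PH and explained variation.

Relapse-free survival is analysed with a 5-year horizon: event-free
follow-up beyond 60 months is administratively censored at 60. Cox
proportional-hazards models use the Efron tie correction (follow-up is
recorded at month resolution, so ties are common) and every fitted term
is checked against the proportional-hazards assumption via scaled
Schoenfeld residuals on Kaplan-Meier-transformed time.

The per-variable explained variation of a multivariable model uses the
likelihood-ratio pseudo-R^2, R^2 = 1 - exp(-LR / n); each term's
contribution is the drop in R^2 when the term is removed from the full
model, floored at zero and rescaled so the contributions sum to 100% of
the full model's R^2. Uncertainty comes from a nonparametric bootstrap
over patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

logger = logging.getLogger(__name__)


def censor_at(records: pd.DataFrame, horizon_months: float = 60.0,
              time_col: str = "time_months", event_col: str = "event") -> pd.DataFrame:
    """Administrative censoring at a horizon (default 5 years)."""
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    out = records.copy()
    over = out[time_col] > horizon_months
    out.loc[over, time_col] = horizon_months
    out.loc[over, event_col] = False
    out[event_col] = out[event_col].astype(bool)
    return out


def km_estimate(records: pd.DataFrame, time_col: str = "time_months",
                event_col: str = "event") -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood standard errors.

    Returns one row per event time: at_risk, events, survival and
    greenwood_se.
    """
    if len(records) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records[time_col], records[event_col])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "events": ev["observed"].to_numpy(dtype=int),
        }
    )
    out["survival"] = [float(surv.loc[t]) for t in out["time"]]
    # Greenwood: Var(S(t)) = S(t)^2 * cumsum d / (n (n - d))
    terms = out["events"] / (out["at_risk"] * (out["at_risk"] - out["events"]))
    terms = terms.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    out["greenwood_se"] = out["survival"] * np.sqrt(np.cumsum(terms))
    return out


def logrank_test(records: pd.DataFrame, group_col: str,
                 time_col: str = "time_months", event_col: str = "event"):
    """Multi-group log-rank test; returns (chi_sq, df, p)."""
    counts = records[group_col].value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError("need >= 2 non-empty groups")
    res = multivariate_logrank_test(
        records[time_col], records[group_col], records[event_col]
    )
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


@dataclass
class CoxFit:
    coefficients: pd.DataFrame  # beta, se, hr, ci_low, ci_high, wald_p per term
    loglik_null: float
    loglik_full: float
    converged: bool
    ph_check: Dict[str, float]
    fitter: CoxPHFitter

    @property
    def likelihood_ratio(self) -> float:
        return 2.0 * (self.loglik_full - self.loglik_null)


def _encode_terms(records: pd.DataFrame, terms: Sequence[str]) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Dummy-encode categorical terms; returns (design, term -> columns)."""
    cols: Dict[str, List[str]] = {}
    pieces = []
    for term in terms:
        col = records[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col.astype(str), prefix=term, drop_first=True).astype(float)
            pieces.append(dummies)
            cols[term] = list(dummies.columns)
        else:
            pieces.append(col.astype(float).to_frame(term))
            cols[term] = [term]
    design = pd.concat(pieces, axis=1)
    return design, cols


def cox_fit(records: pd.DataFrame, terms: Sequence[str],
            time_col: str = "time_months", event_col: str = "event",
            check_ph: bool = True) -> CoxFit:
    """Multivariable Cox PH fit (Efron ties) with a PH-assumption check."""
    n_events = int(records[event_col].sum())
    if n_events < len(terms):
        raise ValueError("fewer events than model terms")
    design, term_cols = _encode_terms(records, terms)
    df = design.copy()
    df["_time"] = records[time_col].to_numpy(dtype=float)
    df["_event"] = records[event_col].to_numpy(dtype=bool)
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-9})
    except Exception as err:  # convergence trouble: refit with a ridge whisper
        logger.warning("Cox fit failed (%s); retrying with small penalizer", err)
        cph = CoxPHFitter(penalizer=1e-6)
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception:
            raise
        converged = False
    summ = cph.summary
    coef = pd.DataFrame(
        {
            "beta": summ["coef"],
            "se": summ["se(coef)"],
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "wald_p": summ["p"],
        }
    )
    ph_p = {}
    if check_ph:
        try:
            ph = proportional_hazard_test(cph, df, time_transform="km")
            ph_p = {row: float(ph.summary.loc[row, "p"]) for row in ph.summary.index}
        except Exception as err:
            logger.warning("PH check failed: %s", err)
    # collapse column-level PH p-values to term level (min over dummies)
    ph_by_term = {}
    for term, cls in term_cols.items():
        ps = [ph_p[c] for c in cls if c in ph_p]
        if ps:
            ph_by_term[term] = min(ps)
    return CoxFit(
        coefficients=coef,
        loglik_null=float(cph._ll_null_),
        loglik_full=float(cph.log_likelihood_),
        converged=converged,
        ph_check=ph_by_term,
        fitter=cph,
    )


def _lr_rsq(records: pd.DataFrame, terms: Sequence[str],
            time_col: str, event_col: str) -> float:
    """Likelihood-ratio pseudo-R^2 = 1 - exp(-LR / n); 0 for no terms."""
    if not terms:
        return 0.0
    fit = cox_fit(records, terms, time_col=time_col, event_col=event_col, check_ph=False)
    n = len(records)
    return float(1.0 - np.exp(-fit.likelihood_ratio / n))


def _partition_once(records, terms, time_col, event_col) -> pd.Series:
    r2_full = _lr_rsq(records, terms, time_col, event_col)
    contribs = {}
    for term in terms:
        rest = [t for t in terms if t != term]
        r2_rest = _lr_rsq(records, rest, time_col, event_col)
        contribs[term] = max(r2_full - r2_rest, 0.0)
    total = sum(contribs.values())
    if total <= 0:
        return pd.Series({t: 0.0 for t in terms})
    return pd.Series({t: 100.0 * (v / total) for t, v in contribs.items()})


def explained_variation(
    records: pd.DataFrame,
    terms: Sequence[str],
    n_boot: int = 5000,
    seed: int = 0,
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Per-term percentage of the full Cox model's explained variation.

    Leave-one-term-out partition of R^2 = 1 - exp(-LR/n); negative raw
    contributions are floored at 0 (logged) before rescaling to 100%.
    Percentile bootstrap intervals over patients when ``n_boot > 0``.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("no terms")
    point = _partition_once(records, terms, time_col, event_col)
    out = pd.DataFrame({"percent": point})
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        failures = 0
        for _ in range(n_boot):
            idx = rng.integers(0, len(records), size=len(records))
            sample = records.iloc[idx].reset_index(drop=True)
            try:
                boots.append(_partition_once(sample, terms, time_col, event_col))
            except Exception:
                failures += 1
        if failures:
            logger.warning("%d bootstrap replicate(s) failed and were skipped", failures)
        bdf = pd.DataFrame(boots)
        out["boot_mean"] = bdf.mean()
        out["ci_low"] = bdf.quantile(0.025)
        out["ci_high"] = bdf.quantile(0.975)
    return out


def survival_filter(
    sheet: pd.DataFrame,
    stages: Sequence[str] = ("I", "II", "III"),
    stage_col: str = "stage",
) -> pd.DataFrame:
    """Restrict a sample sheet to the survival-eligible population
    (locoregional stage; additional exclusion flags are applied by the
    caller as boolean columns)."""
    return sheet[sheet[stage_col].isin(stages)].copy()
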