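"""Per-gene intra-tumor heterogeneity (ITH) scoring.

For each gene, a one-way random-intercept model is fitted across all
samples from all tumors, with tumor as the grouping factor::

    x_ts = mu + u_t + e_ts,   u_t ~ N(0, sigma_tumor_sq),
                              e_ts ~ N(0, sigma_resid_sq)

The intraclass correlation ICC = sigma_tumor_sq / (sigma_tumor_sq +
sigma_resid_sq) measures how much of a gene's variation lies between
tumors; the ITH score is 1 - ICC, so genes that vary mostly *within*
tumors score high. Genes with a flat expression profile (10-90th
percentile range <= 1 on log2 scale) are non-informative and excluded
before scoring, and retained genes are split into low / intermediate /
high ITH categories at configurable score thresholds.

Estimation is REML via a profiled likelihood in the single variance-ratio
parameter gamma = sigma_tumor_sq / sigma_resid_sq: for fixed gamma both
the GLS mean and the residual variance have closed forms, leaving a 1-D
minimisation that is robust for arbitrary unbalanced group sizes. For a
balanced design the estimate coincides with the ANOVA method-of-moments
solution whenever that solution is non-negative. Negative variance
estimates are truncated at zero (boundary REML).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import ExpressionMatrix

DEFAULT_THRESHOLDS = (0.5, 0.8)


@dataclass(frozen=True)
class VarianceComponents:
    sigma_tumor_sq: float
    sigma_resid_sq: float
    converged: bool = True

    def __post_init__(self):
        if not (np.isfinite(self.sigma_tumor_sq) and np.isfinite(self.sigma_resid_sq)):
            raise ValueError("variance components must be finite")
        if self.sigma_tumor_sq < 0 or self.sigma_resid_sq < 0:
            raise ValueError("variance components must be non-negative")


def percentile_range(values: np.ndarray, lo: float = 10.0, hi: float = 90.0) -> float:
    """10-90th percentile spread using linear interpolation between order
    statistics (rank 1 + (n-1)p convention)."""
    return float(
        np.percentile(values, hi, method="linear")
        - np.percentile(values, lo, method="linear")
    )


def percentile_range_filter(
    expr: ExpressionMatrix, threshold: float = 1.0
) -> pd.DataFrame:
    """Per-gene (range, passed) at ``passed <=> p90 - p10 > threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples for a percentile range")
    p10, p90 = np.percentile(expr.values, [10, 90], axis=1, method="linear")
    rng = p90 - p10
    return pd.DataFrame(
        {"gene_id": list(expr.gene_ids), "range": rng, "passed_filter": rng > threshold}
    ).set_index("gene_id")


def _group_stats(groups: Sequence[np.ndarray]):
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([float(np.mean(g)) for g in groups])
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    return ns, means, ssw


def _anova_estimate(ns, means, ssw) -> Tuple[float, float]:
    """Method-of-moments (ANOVA) estimator, unbalanced-capable."""
    N = ns.sum()
    m = len(ns)
    grand = float(np.sum(ns * means) / N)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    msw = ssw / (N - m) if N > m else 0.0
    msb = ssb / (m - 1)
    n0 = (N - np.sum(ns**2) / N) / (m - 1)
    sa = max((msb - msw) / n0, 0.0)
    return sa, msw


def _profiled_reml_criterion(gamma: float, ns, means, ssw) -> Tuple[float, float]:
    """-2 REML log-likelihood profiled over mu and sigma_resid_sq.

    Returns (criterion, sigma_resid_sq_hat(gamma)).
    """
    N = ns.sum()
    w = ns / (1.0 + ns * gamma)
    mu = float(np.sum(w * means) / np.sum(w))
    q = ssw + float(np.sum(w * (means - mu) ** 2))
    se2 = q / (N - 1)
    crit = (N - 1) * np.log(q) + float(np.sum(np.log1p(ns * gamma))) + np.log(np.sum(w))
    return crit, se2


def fit_variance_components(values_by_tumor: Dict[str, np.ndarray]) -> VarianceComponents:
    """REML fit of the one-way random-intercept model.

    ``values_by_tumor`` maps tumor id to the vector of that tumor's
    sample-level expression values for one gene.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_tumor.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 tumors")
    if all(len(g) < 2 for g in groups):
        raise ValueError(
            "all tumors are singletons; residual variance is unidentifiable"
        )
    ns, means, ssw = _group_stats(groups)

    sa0, se0 = _anova_estimate(ns, means, ssw)
    if se0 <= 0:
        # perfect within-tumor replication: all variance is between tumors
        N, m = ns.sum(), len(ns)
        grand = float(np.sum(ns * means) / N)
        sa = float(np.sum(ns * (means - grand) ** 2) / (N - np.sum(ns**2) / N)) if m > 1 else 0.0
        return VarianceComponents(max(sa, 0.0), 0.0, True)

    def crit_log(t: float) -> float:
        return _profiled_reml_criterion(np.exp(t), ns, means, ssw)[0]

    # search on log(gamma); bracket around the ANOVA start
    start = np.log(max(sa0 / se0, 1e-6))
    res = minimize_scalar(
        crit_log,
        bracket=None,
        bounds=(start - 16.0, start + 16.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    gamma = float(np.exp(res.x))
    c_gamma, se2 = _profiled_reml_criterion(gamma, ns, means, ssw)
    c_zero, se2_zero = _profiled_reml_criterion(0.0, ns, means, ssw)
    if c_zero <= c_gamma:  # boundary solution sigma_tumor_sq = 0
        return VarianceComponents(0.0, se2_zero, True)
    return VarianceComponents(gamma * se2, se2, bool(res.success))


def icc(components: VarianceComponents) -> float:
    """Between-tumor variance over total variance; 0 for the 0/0 case."""
    total = components.sigma_tumor_sq + components.sigma_resid_sq
    if total == 0:
        return 0.0
    return components.sigma_tumor_sq / total


def ith_table(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    thresholds: Tuple[float, float] = DEFAULT_THRESHOLDS,
    range_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene ITH table: variance components, ICC, ITH score, category.

    ``thresholds = (t_low, t_high)``: ITH score < t_low is low, >= t_high
    is high, otherwise intermediate. Genes failing the expression-range
    filter (or failing to fit) are reported ``not_scored``.
    """
    t_low, t_high = thresholds
    if not (0.0 <= t_low < t_high <= 1.0):
        raise ValueError("need 0 <= t_low < t_high <= 1")

    sheet = sheet.set_index("sample_id").loc[list(expr.sample_ids)]
    tumor_codes, tumor_ids = pd.factorize(sheet["tumor_id"])
    filt = percentile_range_filter(expr, range_threshold)

    order = np.argsort(tumor_codes, kind="stable")
    sorted_codes = tumor_codes[order]
    boundaries = np.searchsorted(sorted_codes, np.arange(len(tumor_ids) + 1))

    records = []
    n_failed = 0
    for i, gid in enumerate(expr.gene_ids):
        row = filt.loc[gid]
        if not row["passed_filter"]:
            records.append(
                dict(
                    gene_id=gid, range=row["range"], passed_filter=False,
                    sigma_tumor_sq=np.nan, sigma_resid_sq=np.nan,
                    icc=np.nan, ith_score=np.nan, category="not_scored",
                )
            )
            continue
        vals = expr.values[i, order]
        groups = {
            str(tumor_ids[t]): vals[boundaries[t]:boundaries[t + 1]]
            for t in range(len(tumor_ids))
        }
        try:
            comp = fit_variance_components(groups)
        except ValueError:
            n_failed += 1
            records.append(
                dict(
                    gene_id=gid, range=row["range"], passed_filter=True,
                    sigma_tumor_sq=np.nan, sigma_resid_sq=np.nan,
                    icc=np.nan, ith_score=np.nan, category="not_scored",
                )
            )
            continue
        r = icc(comp)
        score = 1.0 - r
        if score < t_low:
            cat = "low"
        elif score >= t_high:
            cat = "high"
        else:
            cat = "intermediate"
        records.append(
            dict(
                gene_id=gid, range=row["range"], passed_filter=True,
                sigma_tumor_sq=comp.sigma_tumor_sq,
                sigma_resid_sq=comp.sigma_resid_sq,
                icc=r, ith_score=score, category=cat,
            )
        )
    table = pd.DataFrame(records).set_index("gene_id")
    table.attrs["n_fit_failures"] = n_failed
    return table
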