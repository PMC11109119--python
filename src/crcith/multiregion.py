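"""Tumor-level heterogeneity summaries and framework agreement statistics.

Given per-sample subtype labels for tumors with multiple spatially
distinct samples, a tumor is heterogeneous when two samples carry
different classified labels, homogeneous when all classified labels agree
and nothing is unclassified, and undetermined when unclassified samples
leave the verdict open (heterogeneity can be proven by two discordant
labels; homogeneity cannot be proven while calls are missing). General
transcriptomic heterogeneity is summarised as the maximum Euclidean
distance between any two of a tumor's samples in PC1-PC3 space.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


def pca_scores(expr: ExpressionMatrix, n_top: int = 1000, n_components: int = 3) -> pd.DataFrame:
    """Sample scores on the first PCs of the top-variance genes.

    Covariance PCA (gene centering only) via SVD on the ``n_top`` genes
    with highest cross-sample variance. Component signs are fixed so that
    each loading vector has a non-negative sum.
    """
    if expr.n_samples < 3:
        raise ValueError("need >= 3 samples for PCA")
    v = expr.values
    var = v.var(axis=1, ddof=1)
    top = np.argsort(var)[::-1][: min(n_top, expr.n_genes)]
    x = v[top, :]
    xc = x - x.mean(axis=1, keepdims=True)  # center genes
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    nonzero = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if nonzero < n_components:
        raise ValueError(
            f"only {nonzero} non-degenerate components available, need {n_components}"
        )
    # samples x components scores; loadings are columns of u
    flip = np.where(u.sum(axis=0) < 0, -1.0, 1.0)
    scores = (vt.T * s) * flip
    cols = [f"PC{i + 1}" for i in range(n_components)]
    out = pd.DataFrame(scores[:, :n_components], index=list(expr.sample_ids), columns=cols)
    out.attrs["loadings"] = u * flip  # genes x components (full set)
    out.attrs["scores_full"] = scores
    out.attrs["gene_subset"] = [expr.gene_ids[i] for i in top]
    out.attrs["explained_variance"] = (s**2) / (expr.n_samples - 1)
    return out


def max_pairwise_pc_distance(coords: pd.DataFrame, tumor_of: pd.Series) -> pd.Series:
    """Per-tumor max Euclidean distance over all sample pairs in PC space.

    Singleton tumors score 0.
    """
    out = {}
    for tumor, idx in tumor_of.groupby(tumor_of).groups.items():
        pts = coords.loc[list(idx)].to_numpy()
        if len(pts) < 2:
            out[tumor] = 0.0
            continue
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        out[tumor] = float(d.max())
    return pd.Series(out, name="max_pc_distance")


def summarize_tumor(
    labels: Sequence[Optional[str]],
    scores: Optional[Sequence[float]] = None,
) -> Tuple[str, Optional[str]]:
    """Tumor heterogeneity verdict and major class from per-sample labels.

    ``None`` / ``"unclassified"`` entries are unclassified samples. Two
    distinct classified labels prove heterogeneity regardless of missing
    calls; any unclassified sample otherwise makes the tumor
    undetermined. The major class is the label covering >= 50% of
    classified samples (ties: higher mean enrichment ``scores`` when
    given, else lexicographic, with a log note).
    """
    labels = [None if (l is None or l == UNCLASSIFIED) else l for l in labels]
    classified = [l for l in labels if l is not None]
    any_unclassified = len(classified) < len(labels)
    distinct = sorted(set(classified))

    if len(distinct) >= 2:
        status = "heterogeneous"
    elif any_unclassified:
        if not classified:
            logger.warning("all samples unclassified; tumor undetermined")
        status = "undetermined"
    elif len(labels) < 2:
        status = "undetermined"  # single sample: no het/hom verdict possible
    else:
        status = "homogeneous"

    major = None
    if classified:
        counts = pd.Series(classified).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) == 1:
            cand = top[0]
        elif scores is not None:
            by_score = {}
            for lab in top:
                vals = [s for l, s in zip(labels, scores) if l == lab and s is not None]
                by_score[lab] = float(np.mean(vals)) if vals else -np.inf
            cand = max(sorted(top), key=lambda lab: by_score[lab])
        else:
            logger.info("major-class tie among %s broken lexicographically", top)
            cand = sorted(top)[0]
        # the >=50% rule: the winner must cover at least half the samples
        if counts[cand] * 2 >= len(classified):
            major = cand
    return status, major


def summarize_cohort(
    calls: pd.DataFrame,
    sheet: pd.DataFrame,
    label_col: str = "cls",
    score_cols: Optional[dict] = None,
) -> pd.DataFrame:
    """Apply :func:`summarize_tumor` per tumor of a multiregional cohort."""
    merged = calls.join(sheet.set_index("sample_id")["tumor_id"], how="inner")
    rows = []
    for tumor, grp in merged.groupby("tumor_id"):
        labels = list(grp[label_col])
        scores = None
        if score_cols is not None:
            scores = [
                score_cols.get(l) and grp.iloc[i][score_cols[l]]
                for i, l in enumerate(labels)
            ]
        status, major = summarize_tumor(labels, scores)
        rows.append(
            dict(tumor_id=tumor, n_samples=len(grp), het_status=status, major_class=major)
        )
    return pd.DataFrame(rows).set_index("tumor_id")


def agreement(labels_a: Sequence[str], labels_b: Sequence[str]):
    """Accuracy, Cohen's kappa and the confusion table for paired labels."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors must be paired")
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no overlapping labelled pairs")
    universe = sorted(set(a) | set(b))
    table = pd.DataFrame(
        confusion_matrix(a, b, labels=universe), index=universe, columns=universe
    )
    acc = float(np.trace(table.to_numpy()) / table.to_numpy().sum())
    kappa = float(cohen_kappa_score(a, b, labels=universe))
    return acc, kappa, table


def enrichment_odds(a: int, b: int, c: int, d: int):
    """Conditional-MLE odds ratio with exact 95% CI and exact p.

    Inputs are the 2x2 counts [[a, b], [c, d]].
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: empty margins")
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    p = float(sp_stats.fisher_exact(table, alternative="two-sided")[1])
    return float(res.statistic), (float(ci.low), float(ci.high)), p
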