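"""Template derivation and single-sample subtype scoring.

This module carries the single-sample machinery of the pipeline:

* a moderated t-test (empirical-Bayes variance shrinkage) for one-vs-rest
  differential expression, used to derive per-class up/down template gene
  sets at adj. p < 0.001 and |log2FC| > 1;
* a rank-based single-sample enrichment score in [0, 1] for a directed
  template, with a sample-specific permutation null for significance;
* the heterogeneity caller: a sample with significant enrichment (p <
  alpha) for more than one class is heterogeneous, with none it is
  unclassified, and the top-scoring significant class is the major
  subtype;
* nearest-template prediction (NTP): cosine distance of the z-scored
  sample profile to a signed template vector, permutation p-value, BH-FDR
  across samples;
* marker-mean microenvironment scores and a simplified competitive
  gene-set comparison test (rank-sum of gene-level moderated t statistics
  with an inter-gene-correlation variance-inflation factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def _fit_f_prior(s2: np.ndarray, d: float) -> Tuple[float, float]:
    """Moment-match gene-wise variances to a scaled F distribution.

    Under the hierarchical model s2 | sigma2 ~ sigma2 * chi2_d / d with a
    scaled inverse-chi-square prior (s0^2, d0) on sigma2, the marginal of
    s2 / s0^2 is F(d, d0). The prior pair (s0^2, d0) is recovered from the
    sample mean and variance of the observed s2. Returns (s0_sq, d0);
    d0 = inf when the observed spread is at (or below) the no-prior limit.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    m1 = float(np.mean(s2))
    v = float(np.var(s2, ddof=1))
    if m1 <= 0 or v <= 0:
        return m1, np.inf

    # CV^2 of F(d, d0) as a function of d0 (for d0 > 4)
    def cv2(d0: float) -> float:
        return 2.0 * (d + d0 - 2.0) / (d * (d0 - 4.0))

    target = v / m1**2
    lo, hi = 4.0 + 1e-6, 1e8
    if target <= cv2(hi):  # variances barely overdispersed: infinite prior df
        return m1, np.inf
    if target >= cv2(lo):
        d0 = lo
    else:
        d0 = brentq(lambda x: cv2(x) - target, lo, hi)
    s0_sq = m1 * (d0 - 2.0) / d0
    return s0_sq, float(d0)


def moderated_ttest(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Two-group moderated t-test per gene with BH adjustment.

    log2fc = mean(A) - mean(B). The squared pooled standard error is
    shrunk towards an empirical-Bayes prior variance with prior df
    estimated by moment matching (pass ``prior_df=0`` to recover the
    ordinary two-sample t-test exactly).
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    a = expr.values[:, [idx[s] for s in group_a]]
    b = expr.values[:, [idx[s] for s in group_b]]
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2
    lfc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if prior_df is None:
        s0_sq, d0 = _fit_f_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.mean(s2[s2 > 0])) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_tilde = s2
        df_total = d
    else:
        s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0),
                     np.sign(lfc) * np.inf)
        t = np.where((se == 0) & (lfc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene_id": list(expr.gene_ids), "log2fc": lfc, "t": t, "p": p, "adj_p": adj}
    ).set_index("gene_id")


@dataclass
class TemplateCollection:
    """Per-class up/down template gene sets with derivation statistics."""

    classes: List[str]
    up: Dict[str, GeneSet]
    down: Dict[str, GeneSet]
    stats: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def union_genes(self, cls: str) -> List[str]:
        up = self.up.get(cls)
        dn = self.down.get(cls)
        return sorted(
            (up.genes if up else frozenset()) | (dn.genes if dn else frozenset())
        )


def derive_templates(
    expr: ExpressionMatrix,
    class_labels: pd.Series,
    adj_p_max: float = 0.001,
    lfc_min: float = 1.0,
    prior_df: Optional[float] = None,
) -> TemplateCollection:
    """One-vs-rest template derivation.

    ``class_labels`` is indexed by sample id; samples with missing labels
    are excluded from the rest group. Genes enter a class's up (down) set
    when adj_p < adj_p_max and log2fc > lfc_min (< -lfc_min).
    """
    labels = class_labels.dropna()
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    small = [c for c in classes if counts[c] < 3]
    if small:
        raise ValueError(f"class(es) with < 3 samples: {small}")
    up, down, stats_by_class = {}, {}, {}
    for c in classes:
        in_c = list(labels.index[labels == c])
        rest = list(labels.index[labels != c])
        de = moderated_ttest(expr, in_c, rest, prior_df=prior_df)
        sig = de[de["adj_p"] < adj_p_max]
        up_genes = frozenset(sig.index[sig["log2fc"] > lfc_min])
        dn_genes = frozenset(sig.index[sig["log2fc"] < -lfc_min])
        if not up_genes and not dn_genes:
            raise ValueError(f"no template genes pass thresholds for class {c!r}")
        up[c] = GeneSet(f"{c}_UP", up_genes, "up") if up_genes else None
        down[c] = GeneSet(f"{c}_DN", dn_genes, "down") if dn_genes else None
        stats_by_class[c] = de
    return TemplateCollection(classes=classes, up=up, down=down, stats=stats_by_class)


# ---------------------------------------------------------------------------
# rank-based single-sample score + permutation null
# ---------------------------------------------------------------------------

def _rank_component(ranks: np.ndarray, members: np.ndarray, n_total: int) -> float:
    n = members.size
    if n == 0 or n >= n_total:
        raise ValueError("template must be non-empty and smaller than the universe")
    mean_rank = float(ranks[members].mean())
    return (mean_rank - (n + 1) / 2.0) / (n_total - n)


def rank_score(
    sample_expression: pd.Series,
    up: Optional[GeneSet],
    down: Optional[GeneSet] = None,
) -> float:
    """Normalized mean-rank enrichment of a directed template in [0, 1].

    Genes are ranked ascending (average ties). The up component rescales
    the mean rank of the up set; the down component does the same on
    reversed ranks. With both sets present the score is their mean, which
    is an order-preserving rescaling of the summed components.
    """
    genes = np.asarray(sample_expression.index)
    ranks = stats.rankdata(sample_expression.to_numpy(), method="average")
    n_total = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    up_idx = (
        np.array([pos[g] for g in up.genes if g in pos], dtype=int)
        if up is not None
        else np.array([], dtype=int)
    )
    dn_idx = (
        np.array([pos[g] for g in down.genes if g in pos], dtype=int)
        if down is not None
        else np.array([], dtype=int)
    )
    comps = []
    if up_idx.size:
        comps.append(_rank_component(ranks, up_idx, n_total))
    if dn_idx.size:
        comps.append(_rank_component(n_total + 1.0 - ranks, dn_idx, n_total))
    if not comps:
        raise ValueError("no template gene measured in the sample")
    return float(np.mean(comps))


@dataclass(frozen=True)
class EnrichmentResult:
    sample_id: str
    cls: str
    score: float
    pvalue: float
    n_null: int


def _null_scores(
    ranks: np.ndarray, n_up: int, n_down: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """B null scores from random same-size gene sets within one sample."""
    n_total = ranks.size
    k = n_up + n_down
    if k == 0:
        raise ValueError("no template gene measured in the sample")
    keys = rng.random((B, n_total))
    subset = np.argpartition(keys, k, axis=1)[:, :k]
    comps = []
    if n_up:
        up_sets = subset[:, :n_up]
        comps.append((ranks[up_sets].mean(axis=1) - (n_up + 1) / 2.0) / (n_total - n_up))
    if n_down:
        dn_sets = subset[:, n_up:]
        rev = n_total + 1.0 - ranks
        comps.append((rev[dn_sets].mean(axis=1) - (n_down + 1) / 2.0) / (n_total - n_down))
    return np.mean(comps, axis=0)


def permutation_pvalue(
    sample_expression: pd.Series,
    up: Optional[GeneSet],
    down: Optional[GeneSet] = None,
    B: int = 1000,
    seed: int = 0,
    sample_id: str = "",
    cls: str = "",
) -> EnrichmentResult:
    """Permutation p-value for :func:`rank_score`.

    Null scores come from random gene sets of matching sizes drawn without
    replacement from the measured genes of the same sample, keeping the
    null sample-specific; p = (1 + #{null >= observed}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    n_total = len(sample_expression)
    n_up = (
        len([g for g in up.genes if g in sample_expression.index]) if up else 0
    )
    n_dn = (
        len([g for g in down.genes if g in sample_expression.index]) if down else 0
    )
    if n_up + n_dn > n_total / 2:
        logger.warning("template covers more than half the universe; null poorly defined")
    obs = rank_score(sample_expression, up, down)
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(sample_expression.to_numpy(), method="average")
    null = _null_scores(ranks, n_up, n_dn, B, rng)
    p = (1.0 + float(np.sum(null >= obs))) / (B + 1.0)
    return EnrichmentResult(sample_id=sample_id, cls=cls, score=obs, pvalue=p, n_null=B)


@dataclass(frozen=True)
class HeterogeneityCall:
    sample_id: str
    status: str  # unclassified | homogeneous | heterogeneous
    major_class: Optional[str]
    significant_classes: frozenset


def call_heterogeneity(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> HeterogeneityCall:
    """Single-sample subtype-heterogeneity decision rule.

    Significant classes are those with p < alpha. None significant ->
    unclassified; more than one -> heterogeneous; the top-scoring
    significant class is the major subtype.
    """
    classes = [r.cls for r in results]
    if len(set(classes)) != len(classes):
        raise ValueError("duplicate class in results")
    sig = [r for r in results if r.pvalue < alpha]
    sample_id = results[0].sample_id if results else ""
    if not sig:
        return HeterogeneityCall(sample_id, "unclassified", None, frozenset())
    major = max(sig, key=lambda r: r.score).cls
    status = "heterogeneous" if len(sig) > 1 else "homogeneous"
    return HeterogeneityCall(sample_id, status, major, frozenset(r.cls for r in sig))


def score_cohort(
    expr: ExpressionMatrix,
    templates: TemplateCollection,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every sample against every class template and call
    heterogeneity; returns one row per sample with scores, p-values,
    status and major class."""
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(expr.n_samples * len(templates.classes))
    k = 0
    gene_index = pd.Index(expr.gene_ids)
    for j, sid in enumerate(expr.sample_ids):
        sample = pd.Series(expr.values[:, j], index=gene_index)
        results = []
        for c in templates.classes:
            res = permutation_pvalue(
                sample,
                templates.up[c],
                templates.down.get(c),
                B=B,
                seed=int(child_seeds[k] % (2**31)),
                sample_id=sid,
                cls=c,
            )
            results.append(res)
            k += 1
        call = call_heterogeneity(results, alpha=alpha)
        row = dict(sample_id=sid, status=call.status, major_class=call.major_class)
        for r in results:
            row[f"score_{r.cls}"] = r.score
            row[f"p_{r.cls}"] = r.pvalue
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# nearest-template prediction
# ---------------------------------------------------------------------------

def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise z-normalisation across samples (zero-variance genes -> 0)."""
    v = expr.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, (v - mu) / sd)


def _cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - float(np.dot(a, b) / (na * nb))


def classify_ntp(
    expr: ExpressionMatrix,
    templates: TemplateCollection,
    fdr_max: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Nearest-template prediction with permutation significance.

    The expression matrix is gene-wise z-scored; each class is a signed
    vector (+1 up genes, -1 down genes) over its template genes, and a
    sample is assigned to the class at minimum cosine distance. The
    p-value compares the observed distance with distances of the same
    signed pattern applied to random gene subsets of the sample; FDR is BH
    across samples, and a sample is classified when fdr < fdr_max.
    """
    z = zscore_genes(expr)
    gene_pos = {g: i for i, g in enumerate(z.gene_ids)}
    class_vectors = {}
    for c in templates.classes:
        up_set = templates.up.get(c)
        up = [g for g in up_set.genes if g in gene_pos] if up_set else []
        dn_set = templates.down.get(c)
        dn = [g for g in dn_set.genes if g in gene_pos] if dn_set else []
        idx = np.array([gene_pos[g] for g in up + dn], dtype=int)
        signs = np.concatenate([np.ones(len(up)), -np.ones(len(dn))])
        class_vectors[c] = (idx, signs)

    rng = np.random.default_rng(seed)
    n_genes = z.n_genes
    rows = []
    for j, sid in enumerate(z.sample_ids):
        x = z.values[:, j]
        dists = {}
        for c, (idx, signs) in class_vectors.items():
            if idx.size == 0:
                dists[c] = np.inf
                continue
            dists[c] = _cosine_distance(x[idx], signs)
        best = min(dists, key=dists.get)
        d_obs = dists[best]
        if not np.isfinite(d_obs):
            logger.warning("sample %s has no measured template genes", sid)
            rows.append(dict(sample_id=sid, cls=None, distance=np.nan, p=np.nan))
            continue
        idx, signs = class_vectors[best]
        null = np.empty(B)
        for b in range(B):
            rnd = rng.choice(n_genes, size=idx.size, replace=False)
            null[b] = _cosine_distance(x[rnd], signs)
        p = (1.0 + float(np.sum(null <= d_obs))) / (B + 1.0)
        rows.append(dict(sample_id=sid, cls=best, distance=d_obs, p=p))
    out = pd.DataFrame(rows).set_index("sample_id")
    ok = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["classified"] = out["fdr"] < fdr_max
    return out


# ---------------------------------------------------------------------------
# marker scores and competitive gene-set comparison
# ---------------------------------------------------------------------------

def marker_score(expr: ExpressionMatrix, markers: GeneSet) -> pd.Series:
    """Arithmetic mean of the measured marker genes' log2 expression per
    sample (used for microenvironment populations such as CAFs and CTLs)."""
    present = [g for g in markers.genes if g in set(expr.gene_ids)]
    if not present:
        raise ValueError(f"no marker of {markers.name!r} measured")
    sub = expr.subset_genes(present)
    return pd.Series(sub.values.mean(axis=0), index=list(expr.sample_ids), name=markers.name)


def geneset_comparison(
    expr: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    sets: Iterable[GeneSet],
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Competitive gene-set test between two sample groups.

    Per set, a two-sided rank-sum z of gene-level moderated t statistics
    (in-set vs out-of-set), deflated by a variance-inflation factor
    1 + (n_set - 1) * rho_bar, where rho_bar is the mean inter-gene
    correlation of within-group residuals over the set (floored at 0).
    This is an explicitly simplified competitive test; BH across sets.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs >= 3 samples")
    de = moderated_ttest(expr, group_a, group_b, prior_df=prior_df)
    tstats = de["t"]
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    resid = np.column_stack(
        [
            expr.values[:, [idx[s] for s in group_a]]
            - expr.values[:, [idx[s] for s in group_a]].mean(axis=1, keepdims=True),
            expr.values[:, [idx[s] for s in group_b]]
            - expr.values[:, [idx[s] for s in group_b]].mean(axis=1, keepdims=True),
        ]
    )
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for gs in sets:
        members = [g for g in gs.genes if g in gene_pos]
        if len(members) < 2:
            logger.warning("set %s has < 2 measured genes; skipped", gs.name)
            continue
        in_mask = np.zeros(len(tstats), dtype=bool)
        in_mask[[gene_pos[g] for g in members]] = True
        z0 = _ranksum_z(tstats.to_numpy()[in_mask], tstats.to_numpy()[~in_mask])
        sub = resid[[gene_pos[g] for g in members], :]
        cors = np.corrcoef(sub)
        n = len(members)
        rho = float((cors.sum() - n) / (n * (n - 1)))
        rho = max(rho, 0.0)
        vif = 1.0 + (n - 1) * rho
        z = z0 / np.sqrt(vif)
        p = 2.0 * stats.norm.sf(abs(z))
        direction = "up in A" if np.mean(tstats.to_numpy()[in_mask]) > 0 else "up in B"
        rows.append(dict(set=gs.name, n_genes=n, z=z, rho_bar=rho, direction=direction, p=p))
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum statistic (normal approx, ties ok)."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((r1 - mu) / np.sqrt(var))
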