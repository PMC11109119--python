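"""Consensus non-negative matrix factorization subtyping on ITH-low genes.

Subtype discovery runs KL-divergence NMF (multiplicative updates, random
non-negative initialisation) on anti-logged expression (2^x of the
log2-scale matrix, the only reading that yields the non-negative input
NMF requires). For each factorisation rank k the factorisation is
repeated over ``n_runs`` random starts; per run, samples are
hard-assigned to the argmax row of H, and the run-averaged connectivity
matrix is the consensus. Final labels cut an average-linkage dendrogram
of (1 - consensus) at k; stability diagnostics are the cophenetic
correlation of that dendrogram and the mean silhouette width on
(1 - consensus) distances. The selected rank is the one preceding the
first large drop (default 0.05) in either diagnostic.

Discovered clusters are mapped one-to-one onto a reference framework
(e.g. CMS) by maximising agreement over the confusion matrix (Hungarian
assignment); surplus clusters beyond the reference classes get
``NMFx.5``-style names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix
from .multiregion import agreement

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


def antilog(expr: ExpressionMatrix) -> np.ndarray:
    """Elementwise 2^x of a log2-scale matrix (strictly positive)."""
    if not np.all(np.isfinite(expr.values)):
        raise ValueError("expression values must be finite")
    return np.exp2(expr.values)


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum(V log(V/WH) - V + WH).

    Terms with V = 0 contribute WH (the x log x -> 0 limit convention);
    WH is floored at machine epsilon.
    """
    WH = np.maximum(W @ H, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(V > 0, V * np.log(np.maximum(V, _EPS) / WH), 0.0)
    return float(np.sum(lg - V + WH))


def nmf_run(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One KL-NMF fit by multiplicative updates; returns (W, H, trace).

    The objective trace (one entry per iteration, including the initial
    point) is non-increasing up to floating-point round-off.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    n, m = V.shape
    if k >= min(n, m):
        raise ValueError(f"rank k={k} must be < min(matrix dims) = {min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

    trace = [kl_divergence(V, W, H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        obj = kl_divergence(V, W, H)
        prev = trace[-1]
        trace.append(obj)
        if abs(prev - obj) < tol * max(abs(prev), _EPS):
            break
    return W, H, np.asarray(trace)


@dataclass
class NmfModel:
    k: int
    W: np.ndarray
    H: np.ndarray
    n_runs: int
    consensus: np.ndarray
    cophenetic: float
    mean_silhouette: float
    labels: pd.Series
    objective_traces: List[np.ndarray] = field(default_factory=list)


def _hard_labels(H: np.ndarray) -> np.ndarray:
    """Cluster assignment by argmax row of H (ties -> lowest index)."""
    return np.argmax(H, axis=0)


def consensus_cluster(
    V: np.ndarray,
    k: int,
    sample_ids: Sequence[str],
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> NmfModel:
    """Consensus NMF at a single rank over repeated random starts."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    m = V.shape[1]
    consensus = np.zeros((m, m))
    best = None
    traces = []
    seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    for r in range(n_runs):
        W, H, trace = nmf_run(V, k, seed=int(seeds[r] % (2**31)), max_iter=max_iter, tol=tol)
        traces.append(trace)
        lab = _hard_labels(H)
        if len(np.unique(lab)) < k:
            logger.info("run %d produced an empty cluster (kept)", r)
        consensus += (lab[:, None] == lab[None, :]).astype(float)
        if best is None or trace[-1] < best[2]:
            best = (W, H, trace[-1])
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    coph_corr, _ = cophenet(Z, condensed)
    if np.isnan(coph_corr):  # constant distances (e.g. perfect consensus)
        coph_corr = 1.0
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = 0.0
    return NmfModel(
        k=k,
        W=best[0],
        H=best[1],
        n_runs=n_runs,
        consensus=consensus,
        cophenetic=float(coph_corr),
        mean_silhouette=sil,
        labels=pd.Series(labels, index=list(sample_ids), name=f"nmf_k{k}"),
        objective_traces=traces,
    )


def consensus_scan(
    V: np.ndarray,
    ranks: Sequence[int],
    sample_ids: Sequence[str],
    n_runs: int = 100,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Dict[int, NmfModel]:
    models = {}
    for i, k in enumerate(ranks):
        models[k] = consensus_cluster(
            V, k, sample_ids, n_runs=n_runs, seed=seed + 1000 * i, max_iter=max_iter, tol=tol
        )
    return models


def select_rank(models: Dict[int, NmfModel], drop_threshold: float = 0.05) -> int:
    """Rank preceding the first large drop in cophenetic or silhouette.

    k* is the smallest k with cophenetic(k+1) < cophenetic(k) -
    drop_threshold or the same for the silhouette; with no such drop the
    largest evaluated rank is returned with a warning.
    """
    ks = sorted(models)
    if len(ks) < 2:
        raise ValueError("need models for at least 2 consecutive ranks")
    for k, k_next in zip(ks[:-1], ks[1:]):
        c0, c1 = models[k].cophenetic, models[k_next].cophenetic
        s0, s1 = models[k].mean_silhouette, models[k_next].mean_silhouette
        if c1 < c0 - drop_threshold or s1 < s0 - drop_threshold:
            return k
    logger.warning("no drop > %.3f found; returning largest rank %d", drop_threshold, ks[-1])
    return ks[-1]


def map_clusters(
    labels: pd.Series, reference_labels: pd.Series
) -> Tuple[pd.Series, Dict, float, float]:
    """Optimal one-to-one renaming of clusters onto reference classes.

    Hungarian assignment on the confusion matrix maximises agreement.
    Surplus clusters (more clusters than reference classes) get
    ``<ref>.5``-style names and are excluded from the agreement
    statistics. Returns (renamed labels, mapping, accuracy, kappa).
    """
    common = labels.index.intersection(reference_labels.index)
    lab = labels.loc[common]
    ref = reference_labels.loc[common].dropna()
    lab = lab.loc[ref.index]
    clusters = sorted(lab.unique())
    classes = sorted(ref.unique())
    conf = np.zeros((len(clusters), len(classes)))
    for i, cl in enumerate(clusters):
        for j, cf in enumerate(classes):
            conf[i, j] = int(((lab == cl) & (ref == cf)).sum())
    row, col = linear_sum_assignment(-conf)
    mapping = {clusters[i]: classes[j] for i, j in zip(row, col)}
    surplus = [cl for cl in clusters if cl not in mapping]
    # surplus clusters are named after the reference class they overlap most
    for cl in surplus:
        j = int(np.argmax(conf[clusters.index(cl)]))
        mapping[cl] = f"{classes[j]}.5"
    renamed = labels.map(mapping)
    mask = renamed.loc[ref.index].isin(classes)
    acc, kappa, _ = agreement(renamed.loc[ref.index][mask], ref[mask])
    return renamed, mapping, acc, kappa


def external_gene_filter(
    expr: ExpressionMatrix, median_min: float = 4.0, var_min: float = 0.1
) -> List[str]:
    """Genes suitable for classifying an external series: median log2
    expression >= median_min and variance >= var_min across tumors."""
    med = np.median(expr.values, axis=1)
    var = expr.values.var(axis=1, ddof=1)
    keep = (med >= median_min) & (var >= var_min)
    return [g for g, k in zip(expr.gene_ids, keep) if k]
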