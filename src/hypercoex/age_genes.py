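"""Selection and clustering of age-associated genes.

Genes are filtered by relative variance (per-gene sd divided by the maximum
per-gene sd, s/s_max), with the threshold chosen by a projection score: the
fraction of variance captured by the top-k principal components of the
filtered submatrix, minus the mean of the same quantity over gene-wise
permuted copies.  Selected genes are grouped by hierarchical clustering on
correlation distance between mean per-age profiles, and per-gene age
association is quantified by one-way ANOVA across age groups and by rank
regression of expression on age, both with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "AgeGeneSet",
    "variance_filter",
    "projection_score",
    "projection_score_select",
    "cluster_age_genes",
    "anova_age_association",
    "rank_regression_age",
]


@dataclasses.dataclass
class AgeGeneSet:
    """Selected age-associated genes with cluster labels and age windows."""

    genes: list[str]
    cluster_of: dict[str, int]
    cluster_age: dict[int, tuple[int, int]]  # cluster -> (first, last) dpf
    tau_star: float | None = None
    mps: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            c = self.cluster_of[g]
            lo, hi = self.cluster_age[c]
            rows.append({"gene": g, "cluster": c, "age_lo": lo, "age_hi": hi})
        return pd.DataFrame(rows)


def variance_filter(X: ExpressionMatrix, tau: float) -> list[str]:
    """Genes whose relative sd (s / s_max) is at least ``tau``."""
    if not (0 <= tau <= 1):
        raise ValueError("tau must be in [0, 1]")
    sds = X.values.std(axis=1, ddof=1)
    s_max = sds.max()
    if s_max == 0:
        raise ValueError("no variance: all genes are constant")
    rel = sds / s_max
    if tau == 0:
        keep = rel.index[sds > 0]
    else:
        keep = rel.index[rel >= tau]
    return list(keep)


def _topk_variance_fraction(values: np.ndarray, k: int) -> float:
    """Fraction of total variance on the top-k principal components.

    Rows (genes) are the variables, columns (samples) the observations;
    rows are centered before the SVD.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    total = float(np.sum(sv**2))
    if total == 0:
        return 0.0
    return float(np.sum(sv[:k] ** 2) / total)


def projection_score(
    values: np.ndarray, k: int, B: int, rng: np.random.Generator
) -> float:
    """Top-k PC variance fraction minus its mean under gene-wise permutation."""
    observed = _topk_variance_fraction(values, k)
    null = np.empty(B)
    for b in range(B):
        permuted = rng.permuted(values, axis=1)
        null[b] = _topk_variance_fraction(permuted, k)
    return observed - float(null.mean())


def projection_score_select(
    X: ExpressionMatrix,
    taus: Sequence[float],
    k: int = 2,
    B: int = 20,
    seed: int | None = None,
) -> tuple[float, float, list[str]]:
    """Choose the variance threshold maximizing the projection score.

    Thresholds leaving fewer than ``k + 1`` genes are skipped; if every
    threshold is skipped an error is raised.  Returns ``(tau_star, score,
    selected genes)``.
    """
    if k < 1 or B < 1:
        raise ValueError("k and B must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[float, float, list[str]] | None = None
    for tau in sorted(taus):
        genes = variance_filter(X, tau)
        if len(genes) < k + 1:
            continue
        score = projection_score(X.values.loc[genes].to_numpy(), k, B, rng)
        if best is None or score > best[1]:
            best = (tau, score, genes)
    if best is None:
        raise ValueError("every threshold left fewer than k + 1 genes")
    return best


def _mean_age_profiles(X: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    ages = X.meta["age_dpf"].astype(int)
    prof = X.values.loc[list(genes)].T.groupby(ages.to_numpy()).mean().T
    return prof[sorted(prof.columns)]


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(profiles)
    corr = np.nan_to_num(corr, nan=0.0)  # constant profiles: treat r as 0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def _cut_with_auto_k(dist: np.ndarray, Z: np.ndarray, k: int | str) -> np.ndarray:
    n = dist.shape[0]
    if k == "auto":
        best_k, best_sil = 2, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            sil = silhouette_score(dist, labels, metric="precomputed")
            if sil > best_sil:
                best_k, best_sil = kk, sil
        k = best_k
    return fcluster(Z, t=int(k), criterion="maxclust")


def cluster_age_genes(
    X: ExpressionMatrix, genes: Sequence[str], k: int | str = "auto"
) -> AgeGeneSet:
    """Hierarchically cluster gene age-profiles and label clusters by peak age.

    Average linkage on correlation distance (1 - r) between mean per-age
    profiles; ``k="auto"`` picks k in 2..6 by mean silhouette.  Each cluster
    is labelled with the age window over which its mean profile is elevated
    (ages above the midpoint between the profile's min and max).
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    missing = set(genes) - set(X.gene_ids)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    profiles = _mean_age_profiles(X, genes)
    age_cols = list(profiles.columns)
    if k == 1:
        labels = np.ones(len(genes), dtype=int)
    else:
        dist = _correlation_distance(profiles.to_numpy())
        Z = linkage(squareform(dist, checks=False), method="average")
        labels = _cut_with_auto_k(dist, Z, k)
    cluster_of = {g: int(c) for g, c in zip(genes, labels)}
    cluster_age: dict[int, tuple[int, int]] = {}
    for c in sorted(set(labels)):
        member_mean = profiles.to_numpy()[labels == c].mean(axis=0)
        lo, hi = member_mean.min(), member_mean.max()
        if hi > lo:
            elevated = [a for a, v in zip(age_cols, member_mean) if v > (lo + hi) / 2]
        else:
            elevated = age_cols
        cluster_age[int(c)] = (int(min(elevated)), int(max(elevated)))
    return AgeGeneSet(genes, cluster_of, cluster_age)


def anova_age_association(X: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene one-way ANOVA of expression on age group, BH adjusted.

    Genes that are constant across all samples get (F=0, p=1).
    """
    ages = X.meta["age_dpf"].astype(int).to_numpy()
    groups = sorted(set(ages))
    if len(groups) < 2:
        raise ValueError("need >= 2 age groups")
    masks = [ages == a for a in groups]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each age group needs >= 2 samples")
    V = X.values.to_numpy()
    F = np.zeros(V.shape[0])
    p = np.ones(V.shape[0])
    for i in range(V.shape[0]):
        cells = [V[i, m] for m in masks]
        if np.ptp(V[i]) == 0:
            continue  # constant gene: F=0, p=1
        with np.errstate(divide="ignore", invalid="ignore"):
            f, pv = stats.f_oneway(*cells)
        if np.isnan(f):  # zero residual variance with distinct means
            f, pv = np.inf, 0.0
        F[i], p[i] = f, pv
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": X.gene_ids, "F": F, "p": p, "q": q})


def rank_regression_age(
    X: ExpressionMatrix, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Least-squares fit of rank(expression) on rank(age), per gene.

    The signed correlation of the fit equals the Spearman correlation of
    expression with age.  Constant genes get (R=0, p=1).  Returns a frame
    with columns gene, R, p, q (BH across genes).
    """
    if genes is None:
        genes = X.gene_ids
    genes = list(genes)
    n = len(X.sample_ids)
    if n < 3:
        raise ValueError("need >= 3 samples")
    age_rank = stats.rankdata(X.meta["age_dpf"].astype(int).to_numpy())
    V = X.values.loc[genes].to_numpy()
    R = np.zeros(len(genes))
    p = np.ones(len(genes))
    za = (age_rank - age_rank.mean()) / age_rank.std(ddof=1)
    for i in range(len(genes)):
        if np.ptp(V[i]) == 0:
            continue
        er = stats.rankdata(V[i])
        ze = (er - er.mean()) / er.std(ddof=1)
        r = float(np.dot(za, ze) / (n - 1))
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0:
            pv = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            pv = 2 * stats.t.sf(abs(t), df=n - 2)
        R[i], p[i] = r, pv
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "R": R, "p": p, "q": q})
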