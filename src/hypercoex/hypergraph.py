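"""Binarized-correlation hypergraphs and their topology statistics.

A hypergraph is built from a list of target genes ``g`` (typically the
age-associated set) and the background transcriptome ``gc``: Pearson
correlations between every target and every background gene are binarized at
one pooled standard deviation from the pooled mean, giving the binary
incidence matrix ``M`` (targets x background transcripts; background genes
act as hyperedges).  ``A = M . M^t`` is the reduced adjacency matrix, whose
(i, j) entry counts background transcripts correlated with both targets i
and j - the higher-order interactions.  Connectivity is a row sum of ``M``
or ``A``; entropy is the Shannon entropy of the normalized connectivity
distribution as a fraction of its maximum (log of the node count).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix

__all__ = [
    "Hypergraph",
    "PermutationNull",
    "correlation_matrix",
    "binarize_incidence",
    "reduced_adjacency",
    "build_hypergraph",
    "connectivity",
    "hypergraph_entropy",
    "detect_clusters",
    "peripheral_genes",
    "permute_incidence",
    "compare_topology",
]


@dataclasses.dataclass
class Hypergraph:
    """Binary incidence ``M`` (|g| x |gc|) and reduced adjacency ``A = M.M^t``."""

    g: list[str]
    gc: list[str]
    M: np.ndarray
    A: np.ndarray
    r_mean: float
    r_sd: float

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        self.A = np.asarray(self.A)
        if set(self.g) & set(self.gc):
            raise ValueError("target and background gene lists overlap")
        if self.M.shape != (len(self.g), len(self.gc)):
            raise ValueError("incidence shape does not match gene lists")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")


def _zscore_rows(V: np.ndarray) -> np.ndarray:
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (V - mu) / sd


def correlation_matrix(
    X: ExpressionMatrix,
    targets: Sequence[str],
    background: Sequence[str] | str = "rest",
) -> pd.DataFrame:
    """Pearson r between each target and each background gene.

    ``background="rest"`` expands to every gene not in ``targets``.
    Zero-variance background genes are excluded; a zero-variance target is
    an error (it cannot carry a correlation).
    """
    targets = list(targets)
    missing = set(targets) - set(X.gene_ids)
    if missing:
        raise ValueError(f"targets absent from matrix: {sorted(missing)[:5]}")
    if isinstance(background, str):
        if background != "rest":
            raise ValueError("background must be a gene list or 'rest'")
        background = [g for g in X.gene_ids if g not in set(targets)]
    else:
        background = list(background)
    n = len(X.sample_ids)
    if n < 3:
        raise ValueError("need >= 3 samples to correlate")
    Vt = X.values.loc[targets].to_numpy(dtype=float)
    sd_t = Vt.std(axis=1, ddof=1)
    if (sd_t == 0).any():
        bad = [g for g, s in zip(targets, sd_t) if s == 0]
        raise ValueError(f"zero-variance target gene(s): {bad[:5]}")
    Vb = X.values.loc[background].to_numpy(dtype=float)
    keep = Vb.std(axis=1, ddof=1) > 0
    background = [g for g, k in zip(background, keep) if k]
    Zt = _zscore_rows(Vt)
    Zb = _zscore_rows(Vb[keep])
    R = (Zt @ Zb.T) / (n - 1)
    return pd.DataFrame(np.clip(R, -1.0, 1.0), index=targets, columns=background)


def binarize_incidence(R: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Threshold correlations at +/- one pooled sd from the pooled mean.

    The mean and (sample, n-1) sd are pooled over every entry of ``R``; an
    entry maps to 1 iff it lies strictly more than one sd from the mean.
    A zero-sd matrix yields an all-zero incidence with a warning.
    """
    arr = np.asarray(R, dtype=float)
    if arr.size == 0:
        raise ValueError("empty correlation matrix")
    if not np.isfinite(arr).all():
        raise ValueError("correlation matrix has non-finite entries")
    r_mean = float(arr.mean())
    r_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if r_sd <= 1e-12 * max(1.0, abs(r_mean)):
        r_sd = 0.0
    if r_sd == 0:
        warnings.warn("zero pooled sd: incidence matrix is all zeros")
        return np.zeros(arr.shape, dtype=np.int8), r_mean, r_sd
    M = (np.abs(arr - r_mean) > r_sd).astype(np.int8)
    return M, r_mean, r_sd


def reduced_adjacency(M: np.ndarray) -> np.ndarray:
    """A = M . M^t: shared post-binarization correlations per gene pair."""
    M = np.asarray(M)
    return (M.astype(np.int64) @ M.astype(np.int64).T)


def build_hypergraph(
    X: ExpressionMatrix,
    targets: Sequence[str],
    background: Sequence[str] | str = "rest",
) -> Hypergraph:
    """Correlate, binarize and reduce in one step."""
    R = correlation_matrix(X, targets, background)
    M, r_mean, r_sd = binarize_incidence(R)
    A = reduced_adjacency(M)
    return Hypergraph(list(R.index), list(R.columns), M, A, r_mean, r_sd)


def connectivity(H: Hypergraph, kind: str = "adjacency") -> np.ndarray:
    """Per-gene connections: row sums of ``M`` or of ``A`` (diagonal included)."""
    if kind == "incidence":
        return H.M.sum(axis=1).astype(np.int64)
    if kind == "adjacency":
        return H.A.sum(axis=1)
    raise ValueError("kind must be 'incidence' or 'adjacency'")


def hypergraph_entropy(conn: Sequence[float]) -> float:
    """Normalized Shannon entropy of a connectivity distribution, in [0, 1].

    The vector is normalized to probabilities; entropy is computed with the
    0 log 0 = 0 convention and divided by log(n), so a uniform vector gives
    1 and a single nonzero entry gives 0.
    """
    c = np.asarray(conn, dtype=float)
    if c.ndim != 1 or len(c) < 2:
        raise ValueError("connectivity vector must have length >= 2")
    if (c < 0).any():
        raise ValueError("connectivity must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("empty distribution")
    p = c / total
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    return H / float(np.log(len(c)))


def detect_clusters(
    H: Hypergraph,
    k: int | str = "auto",
    age_labels: dict[str, tuple[int, int]] | None = None,
) -> tuple[dict[str, int], dict[int, tuple[int, int] | None]]:
    """Cluster target genes on shared-correlation distance 1 - A / max(A).

    Average linkage; ``k="auto"`` picks k in 2..6 by silhouette.  When
    per-gene age windows are supplied, each cluster is labelled with the
    majority age window of its members.  Returns ``(gene -> cluster,
    cluster -> age window or None)``.
    """
    n = len(H.g)
    if n < 2:
        raise ValueError("need >= 2 target genes")
    a_max = H.A.max()
    if a_max == 0:
        raise ValueError("disconnected hypergraph: adjacency is all zeros")
    dist = 1.0 - H.A / a_max
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 1.0)
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        if k == "auto":
            best_k, best_sil = 2, -np.inf
            for kk in range(2, min(6, n - 1) + 1):
                lab = fcluster(Z, t=kk, criterion="maxclust")
                if len(set(lab)) < 2:
                    continue
                sil = silhouette_score(dist, lab, metric="precomputed")
                if sil > best_sil:
                    best_k, best_sil = kk, sil
            k = best_k
        labels = fcluster(Z, t=int(k), criterion="maxclust")
    assignment = {g: int(c) for g, c in zip(H.g, labels)}
    cluster_age: dict[int, tuple[int, int] | None] = {}
    for c in sorted(set(labels)):
        members = [g for g in H.g if assignment[g] == c]
        if age_labels:
            votes = pd.Series([age_labels[g] for g in members if g in age_labels])
            cluster_age[int(c)] = votes.mode().iloc[0] if len(votes) else None
        else:
            cluster_age[int(c)] = None
    return assignment, cluster_age


def peripheral_genes(H: Hypergraph, cluster: Sequence[str]) -> list[str]:
    """Background transcripts correlated with *every* gene of ``cluster``.

    These are the all-ones columns of ``M`` restricted to the cluster rows -
    the complete-subgraph criterion; an empty result is allowed.
    """
    cluster = list(cluster)
    if not cluster:
        raise ValueError("cluster must be non-empty")
    index = {g: i for i, g in enumerate(H.g)}
    missing = [g for g in cluster if g not in index]
    if missing:
        raise ValueError(f"cluster genes not in hypergraph: {missing[:5]}")
    rows = H.M[[index[g] for g in cluster]]
    mask = rows.all(axis=0)
    return [g for g, m in zip(H.gc, mask) if m]


@dataclasses.dataclass
class PermutationNull:
    """Null connectivity distributions from incidence-matrix permutation."""

    incidence: np.ndarray  # (n_perm, |g|) row sums of permuted M
    adjacency: np.ndarray  # (n_perm, |g|) row sums of permuted M.M^t
    rank_stability: np.ndarray  # per-permutation Spearman r vs observed adjacency
    mode: str
    seed: int | None


def permute_incidence(
    H: Hypergraph,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "within_row",
) -> PermutationNull:
    """Permutation null for connectivity and higher-order structure.

    ``within_row`` (default) shuffles each row of ``M`` independently,
    conserving every gene's degree while destroying which hyperedges are
    shared; ``global`` shuffles the whole matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("within_row", "global"):
        raise ValueError("mode must be 'within_row' or 'global'")
    rng = np.random.default_rng(seed)
    obs_adj = connectivity(H, "adjacency").astype(float)
    inc = np.empty((n_perm, len(H.g)), dtype=np.int64)
    adj = np.empty((n_perm, len(H.g)), dtype=np.int64)
    stab = np.empty(n_perm)
    for b in range(n_perm):
        if mode == "within_row":
            Mp = rng.permuted(H.M, axis=1)
        else:
            Mp = rng.permutation(H.M.ravel()).reshape(H.M.shape)
        inc[b] = Mp.sum(axis=1)
        colsum = Mp.sum(axis=0)
        adj[b] = Mp.astype(np.int64) @ colsum.astype(np.int64)
        if np.ptp(adj[b]) == 0 or np.ptp(obs_adj) == 0:
            stab[b] = np.nan
        else:
            stab[b] = stats.spearmanr(obs_adj, adj[b]).statistic
    return PermutationNull(inc, adj, stab, mode, seed)


def compare_topology(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and fold change of means, mean(a)/mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both vectors must be non-empty")
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
    mb = b.mean()
    fold = float(a.mean() / mb) if mb != 0 else float("nan")
    return p, fold
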