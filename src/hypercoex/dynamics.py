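"""Hypergraph dynamics: entropy over moving age windows and random walks.

The time series splits samples into moving windows of two sequential ages
(5-10 dpf, 10-15 dpf, ...), repeatedly draws random target-gene sets, builds
the correlation hypergraph within the window, and records normalized entropy.
The random walk treats background transcripts as hyperedges: from a node,
pick an incident hyperedge uniformly, then a member node of that hyperedge
uniformly (self-transitions allowed), giving the row-stochastic transition
matrix P = D_v^-1 M D_e^-1 M^t.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .hypergraph import Hypergraph, binarize_incidence, hypergraph_entropy
from .io import ExpressionMatrix

__all__ = [
    "EntropySamples",
    "TransitionMatrix",
    "moving_windows",
    "entropy_timeseries",
    "compare_timeseries",
    "random_walk_transition",
    "transition_adjacency_correlation",
]


@dataclasses.dataclass
class EntropySamples:
    """Iterated normalized-entropy values for one condition/window/gene set."""

    condition: str
    window: tuple[int, int] | None
    values: np.ndarray
    n_targets: int
    seed: int | None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("entropy values must lie in [0, 1]")


@dataclasses.dataclass
class TransitionMatrix:
    """Row-stochastic random-walk transition matrix over hypergraph nodes."""

    genes: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if (self.P < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")


def moving_windows(ages: Sequence[int]) -> list[tuple[int, int]]:
    """Consecutive pairs of distinct ages, in sorted order."""
    uniq = sorted(set(int(a) for a in ages))
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct ages")
    return list(zip(uniq[:-1], uniq[1:]))


def _iterated_entropy(
    V: np.ndarray,
    n_targets: int,
    n_iter: int,
    rng: np.random.Generator,
    max_retries: int = 10,
) -> np.ndarray:
    """Entropy of random-target hypergraphs built from sample matrix ``V``.

    ``V`` is genes x samples for one window.  Per iteration: draw
    ``n_targets`` genes without replacement, correlate against every other
    non-constant gene, binarize at the pooled +/-1 sd threshold and take the
    entropy of the adjacency connectivity (row sums of M.M^t, computed as
    M @ colsums(M) without materializing A).
    """
    n_genes, n = V.shape
    if n < 3:
        raise ValueError("window has fewer than 3 samples")
    if n_targets >= n_genes:
        raise ValueError("n_targets must be smaller than the gene count")
    sd = V.std(axis=1, ddof=1)
    valid = sd > 0
    mu = V.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (V - mu) / sd[:, None]
    values = np.empty(n_iter)
    for it in range(n_iter):
        for attempt in range(max_retries):
            idx = rng.choice(n_genes, size=n_targets, replace=False)
            if not valid[idx].all():
                continue
            bg_mask = valid.copy()
            bg_mask[idx] = False
            R = (Z[idx] @ Z[bg_mask].T) / (n - 1)
            M, _, _ = binarize_incidence(R)
            conn = M.astype(np.int64) @ M.sum(axis=0).astype(np.int64)
            if conn.sum() > 0:  # else: no supra-threshold correlation, redraw
                values[it] = hypergraph_entropy(conn)
                break
        else:
            raise RuntimeError("could not draw a usable target set")
    return values


def entropy_timeseries(
    X: ExpressionMatrix,
    n_targets: int = 100,
    n_iter: int = 1000,
    seed: int | None = None,
) -> list[EntropySamples]:
    """Iterated hypergraph entropy in each moving two-age window.

    Returns one :class:`EntropySamples` per window, in age order; all
    randomness is driven by ``seed`` (one independent stream per window).
    """
    windows = moving_windows(X.ages)
    condition = X.condition_label()
    streams = np.random.SeedSequence(seed).spawn(len(windows))
    out = []
    for (lo, hi), ss in zip(windows, streams):
        sub = X.subset_ages([lo, hi])
        V = sub.values.to_numpy(dtype=float)
        vals = _iterated_entropy(V, n_targets, n_iter, np.random.default_rng(ss))
        out.append(EntropySamples(condition, (lo, hi), vals, n_targets, seed))
    return out


def compare_timeseries(samples: Sequence[EntropySamples]) -> pd.DataFrame:
    """ANOVA plus Tukey HSD contrasts of SC vs KD entropy per window.

    Expects samples covering both conditions over a shared set of windows.
    Returns one row per window with the global one-way F over all
    condition-by-window cells, the Tukey-adjusted p for the SC-KD contrast
    in that window, a BH-adjusted q across windows, and the fold change of
    mean entropy (KD / SC).
    """
    cells: dict[tuple[str, tuple[int, int]], np.ndarray] = {}
    for s in samples:
        if s.window is None:
            raise ValueError("samples must carry a window")
        cells[(s.condition, s.window)] = s.values
    if len(cells) < 2:
        raise ValueError("need >= 2 condition/window cells")
    for key, vals in cells.items():
        if len(vals) < 2:
            raise ValueError(f"cell {key} has fewer than 2 values")
    windows = sorted({w for (_, w) in cells})
    F, _ = stats.f_oneway(*cells.values())
    labels = np.concatenate(
        [[f"{c}|{w[0]}-{w[1]}"] * len(v) for (c, w), v in cells.items()]
    )
    values = np.concatenate(list(cells.values()))
    tukey = pairwise_tukeyhsd(values, labels)
    tk = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    rows = []
    for w in windows:
        sc_lab, kd_lab = f"SC|{w[0]}-{w[1]}", f"KD|{w[0]}-{w[1]}"
        pair = tk[
            ((tk["group1"] == sc_lab) & (tk["group2"] == kd_lab))
            | ((tk["group1"] == kd_lab) & (tk["group2"] == sc_lab))
        ]
        p_tukey = float(pair["p-adj"].iloc[0]) if len(pair) else np.nan
        sc_vals = cells.get(("SC", w))
        kd_vals = cells.get(("KD", w))
        fold = (
            float(kd_vals.mean() / sc_vals.mean())
            if sc_vals is not None and kd_vals is not None and sc_vals.mean() != 0
            else np.nan
        )
        rows.append(
            {"window": f"{w[0]}-{w[1]}", "F": float(F), "p_tukey": p_tukey, "fold_kd_vs_sc": fold}
        )
    out = pd.DataFrame(rows)
    mask = out["p_tukey"].notna()
    q = np.full(len(out), np.nan)
    if mask.any():
        q[mask.to_numpy()] = multipletests(out.loc[mask, "p_tukey"], method="fdr_bh")[1]
    out["q"] = q
    return out


def random_walk_transition(H: Hypergraph, cluster: Sequence[str]) -> TransitionMatrix:
    """Node -> hyperedge -> node random walk restricted to a cluster.

    With ``M_c`` the cluster-restricted incidence (all-zero hyperedge columns
    dropped), ``D_v`` node degrees and ``D_e`` hyperedge sizes:
    ``P = D_v^-1 . M_c . D_e^-1 . M_c^t``.  Isolated genes make the walk
    undefined and raise.
    """
    cluster = list(cluster)
    index = {g: i for i, g in enumerate(H.g)}
    missing = [g for g in cluster if g not in index]
    if missing:
        raise ValueError(f"cluster genes not in hypergraph: {missing[:5]}")
    Mc = H.M[[index[g] for g in cluster]].astype(float)
    keep = Mc.sum(axis=0) > 0
    Mc = Mc[:, keep]
    row_deg = Mc.sum(axis=1)
    if (row_deg == 0).any():
        isolated = [g for g, d in zip(cluster, row_deg) if d == 0]
        raise ValueError(f"disconnected: isolated genes {isolated[:5]}")
    if Mc.shape[1] == 0:
        raise ValueError("disconnected: no incident hyperedges")
    col_deg = Mc.sum(axis=0)
    P = (Mc / row_deg[:, None]) @ (Mc / col_deg[None, :]).T
    return TransitionMatrix(cluster, P)


def transition_adjacency_correlation(P: TransitionMatrix, A: np.ndarray) -> float:
    """Pearson r between off-diagonal transition probabilities and adjacency.

    Diagonals are excluded (both are structurally inflated).  Returns NaN
    when either flattened vector is constant.
    """
    A = np.asarray(A, dtype=float)
    n = len(P.genes)
    if A.shape != (n, n):
        raise ValueError("adjacency shape does not match transition matrix")
    mask = ~np.eye(n, dtype=bool)
    x, y = P.P[mask], A[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
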