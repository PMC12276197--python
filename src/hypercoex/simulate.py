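"""Synthetic two-condition longitudinal expression data with planted structure.

The generator emulates a morpholino knockdown study design: two conditions
(standard control, SC; knockdown, KD) sampled at a fixed set of developmental
ages with a small number of replicates.  Age-associated structure is planted
as gene clusters whose expression is elevated (a boxcar shift on the log2
scale) at their assigned age window, each cluster surrounded by
background-linked genes that are noisy affine copies of a cluster parent at a
target correlation.  The KD-like condition differs in two ways: a fraction of
the earliest cluster's genes have their peak age reassigned (developmental
mistiming), and a common latent factor is mixed into all cluster genes to
raise cross-cluster correlation (loss of modular coordination).  Linked
background genes are copied from their *realized* parents and therefore
inherit both perturbations, which is what couples the perturbations to the
hypergraph's incidence structure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SyntheticConfig", "generate_longitudinal"]


@dataclasses.dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated design: 2000 genes, ages 5/10/15/20/30 dpf
    with 3 replicates each, four planted clusters of 40 genes with 100 linked
    background genes apiece, a 2.0 log2-unit age-specific up-shift, linked-gene
    correlation 0.8, residual noise sd 0.5, and a KD condition that reassigns
    the peak age of 70% of earliest-cluster genes and adds 0.3 cross-cluster
    correlation.
    """

    n_genes: int = 2000
    ages: Sequence[int] = (5, 10, 15, 20, 30)
    n_reps: int = 3
    n_clusters: int = 4
    genes_per_cluster: int = 40
    n_background_linked: int = 100  # per cluster
    effect_size: float = 2.0  # log2 units
    background_corr: float = 0.8
    noise_sd: float = 0.5  # log2 units
    kd_disruption: float = 0.7
    kd_crosstalk: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_clusters * (self.genes_per_cluster + self.n_background_linked)
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0 < self.background_corr <= 1):
            raise ValueError("background_corr must be in (0, 1]")
        for name in ("kd_disruption", "kd_crosstalk"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.ages) < 2:
            raise ValueError("need at least two ages")
        if self.n_clusters > len(self.ages):
            raise ValueError("more clusters than ages to assign them to")


def _cluster_age_windows(cfg: SyntheticConfig) -> list[list[int]]:
    """Assign each cluster an age window: one age each, the last cluster
    absorbing any trailing ages (e.g. 4 clusters over 5 ages -> the last
    cluster spans the final two ages)."""
    ages = sorted(int(a) for a in cfg.ages)
    windows = [[a] for a in ages[: cfg.n_clusters - 1]]
    windows.append(ages[cfg.n_clusters - 1 :])
    return windows


def _sample_layout(cfg: SyntheticConfig, condition: str) -> pd.DataFrame:
    rows = []
    for age in sorted(int(a) for a in cfg.ages):
        for rep in range(1, cfg.n_reps + 1):
            rows.append(
                {
                    "sample": f"{condition}_{age}dpf_r{rep}",
                    "age_dpf": age,
                    "condition": condition,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def _build_condition(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    baselines: np.ndarray,
    peak_ages: list[list[int]],
    parents: np.ndarray,
    crosstalk: float,
    meta: pd.DataFrame,
) -> np.ndarray:
    """Assemble one condition's (n_genes x n_samples) matrix.

    ``peak_ages`` gives, per cluster gene, the list of ages at which that
    gene is elevated (already reassigned for disrupted KD genes).
    """
    n_samples = len(meta)
    sample_ages = meta["age_dpf"].to_numpy(dtype=int)
    n_cluster = cfg.n_clusters * cfg.genes_per_cluster
    n_linked = cfg.n_clusters * cfg.n_background_linked
    X = np.empty((cfg.n_genes, n_samples))

    # planted cluster genes: baseline + boxcar + noise
    cluster_block = np.empty((n_cluster, n_samples))
    for i in range(n_cluster):
        boxcar = np.isin(sample_ages, peak_ages[i]).astype(float) * cfg.effect_size
        cluster_block[i] = baselines[i] + boxcar + rng.normal(0, cfg.noise_sd, n_samples)

    if crosstalk > 0:
        # Cross-cluster mixing: every cluster gene trades a crosstalk fraction
        # of its centered profile for a random unit combination of the age
        # *programs* (orthonormalized boxcar directions).  Genes bleed into
        # each other's age programs rather than following one global factor,
        # so coordination becomes diffuse: within-cluster coherence weakens,
        # cross-cluster correlation rises, and no single direction dominates.
        windows = _cluster_age_windows(cfg)
        progs = []
        for w in windows:
            b = np.isin(sample_ages, w).astype(float)
            b -= b.mean()
            progs.append(b / b.std(ddof=1))
        Q, _ = np.linalg.qr(np.array(progs).T)
        F = Q.T * np.sqrt(n_samples - 1)  # orthonormal centered directions
        u = rng.normal(size=(n_cluster, F.shape[0]))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        means = cluster_block.mean(axis=1, keepdims=True)
        centered = cluster_block - means
        sds = centered.std(axis=1, ddof=1, keepdims=True)
        cluster_block = (
            means
            + np.sqrt(1.0 - crosstalk) * centered
            + np.sqrt(crosstalk) * sds * (u @ F)
        )
    X[:n_cluster] = cluster_block

    # background-linked genes: affine copies of realized parents
    rho = cfg.background_corr
    for j in range(n_linked):
        p = X[parents[j]]
        centered = p - p.mean()
        sd = centered.std(ddof=1)
        X[n_cluster + j] = (
            baselines[n_cluster + j]
            + rho * centered
            + np.sqrt(1.0 - rho * rho) * sd * rng.normal(0, 1.0, n_samples)
        )

    # unstructured background
    n_rest = cfg.n_genes - n_cluster - n_linked
    X[n_cluster + n_linked :] = baselines[n_cluster + n_linked :, None] + rng.normal(
        0, cfg.noise_sd, (n_rest, n_samples)
    )
    return X


def generate_longitudinal(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Generate (SC-like, KD-like) expression matrices plus ground truth.

    Returns
    -------
    sc, kd : ExpressionMatrix
        One matrix per condition, each ``n_genes`` x ``len(ages) * n_reps``.
    truth : DataFrame
        Per-gene ground truth with columns ``gene``, ``role`` (``cluster`` /
        ``linked`` / ``noise``), ``cluster`` (label or -1), ``parent`` (gene id
        or empty), ``disrupted`` (bool), ``sc_peak_ages``, ``kd_peak_ages``
        (comma-separated dpf, empty for unstructured genes).
    """
    ss = np.random.SeedSequence(cfg.seed)
    shared_rng, sc_rng, kd_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    n_cluster = cfg.n_clusters * cfg.genes_per_cluster
    n_linked = cfg.n_clusters * cfg.n_background_linked
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]

    # gene-level properties shared between conditions
    baselines = shared_rng.normal(8.0, 1.0, cfg.n_genes)
    windows = _cluster_age_windows(cfg)
    cluster_of = np.repeat(np.arange(cfg.n_clusters), cfg.genes_per_cluster)
    sc_peaks = [list(windows[cluster_of[i]]) for i in range(n_cluster)]

    # each linked gene copies a parent drawn from its cluster
    parent_cluster = np.repeat(np.arange(cfg.n_clusters), cfg.n_background_linked)
    parents = np.array(
        [
            c * cfg.genes_per_cluster + shared_rng.integers(cfg.genes_per_cluster)
            for c in parent_cluster
        ]
    )

    # KD disruption: reassign peak ages of a fraction of the earliest cluster
    ages_sorted = sorted(int(a) for a in cfg.ages)
    earliest = [i for i in range(n_cluster) if cluster_of[i] == 0]
    n_disrupt = int(round(cfg.kd_disruption * len(earliest)))
    disrupted_idx = shared_rng.choice(earliest, size=n_disrupt, replace=False)
    disrupted = np.zeros(cfg.n_genes, dtype=bool)
    disrupted[disrupted_idx] = True
    kd_peaks = [list(p) for p in sc_peaks]
    for i in disrupted_idx:
        choices = [a for a in ages_sorted if a not in sc_peaks[i]]
        kd_peaks[i] = [int(shared_rng.choice(choices))]

    meta_sc = _sample_layout(cfg, "SC")
    meta_kd = _sample_layout(cfg, "KD")
    X_sc = _build_condition(cfg, sc_rng, baselines, sc_peaks, parents, 0.0, meta_sc)
    X_kd = _build_condition(
        cfg, kd_rng, baselines, kd_peaks, parents, cfg.kd_crosstalk, meta_kd
    )

    roles = ["cluster"] * n_cluster + ["linked"] * n_linked + ["noise"] * (
        cfg.n_genes - n_cluster - n_linked
    )
    cluster_labels = np.full(cfg.n_genes, -1)
    cluster_labels[:n_cluster] = cluster_of
    cluster_labels[n_cluster : n_cluster + n_linked] = parent_cluster
    parent_col = [""] * cfg.n_genes
    sc_peak_col = [""] * cfg.n_genes
    kd_peak_col = [""] * cfg.n_genes
    for j in range(n_linked):
        parent_col[n_cluster + j] = gene_ids[parents[j]]
    for i in range(n_cluster):
        sc_peak_col[i] = ",".join(str(a) for a in sc_peaks[i])
        kd_peak_col[i] = ",".join(str(a) for a in kd_peaks[i])

    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "role": roles,
            "cluster": cluster_labels,
            "parent": parent_col,
            "disrupted": disrupted,
            "sc_peak_ages": sc_peak_col,
            "kd_peak_ages": kd_peak_col,
        }
    )

    sc = ExpressionMatrix(pd.DataFrame(X_sc, index=gene_ids, columns=meta_sc.index), meta_sc)
    kd = ExpressionMatrix(pd.DataFrame(X_kd, index=gene_ids, columns=meta_kd.index), meta_kd)
    return sc, kd, truth
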