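"""Per-pathway hypergraph entropy and Bayesian two-group comparison.

For each pathway (after homolog mapping and a minimum-size filter), random
subsets of its genes are repeatedly used as hypergraph targets against the
rest of the transcriptome and the normalized entropy recorded, separately
per condition.  The SC and KD entropy distributions are then compared with
a Bayesian Gaussian linear model, entropy ~ alpha + beta * I(condition=KD),
with weakly informative normal priors (location 0, scale 2.5 x outcome sd).
The reported beta is sign-flipped so that positive values mean higher
entropy in SC; a pathway is called significant when the equal-tailed 89%
credible interval of beta excludes 0.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import EntropySamples
from .hypergraph import binarize_incidence, hypergraph_entropy
from .io import ExpressionMatrix, PathwayCollection

__all__ = [
    "PathwayBeta",
    "filter_pathways",
    "pathway_entropy_distributions",
    "bayesian_entropy_difference",
    "pathway_entropy_analysis",
]


@dataclasses.dataclass
class PathwayBeta:
    """Posterior summary of the SC-KD entropy difference for one pathway."""

    pathway: str
    beta_mean: float
    ci89: tuple[float, float]
    significant: bool
    n_draws: int
    seed: int | None


def filter_pathways(
    coll: PathwayCollection,
    X: ExpressionMatrix,
    homolog_map: Mapping[str, str] | None = None,
    min_genes: int = 15,
) -> PathwayCollection:
    """Map pathway genes through a homolog table and drop small pathways.

    Genes are first mapped (identity if no map is given), then intersected
    with the genes present in ``X``; pathways retaining fewer than
    ``min_genes`` genes are removed.
    """
    if homolog_map is not None and len(homolog_map) == 0:
        warnings.warn("empty homolog map: no genes will translate")
    present = set(X.gene_ids)
    kept: dict[str, list[str]] = {}
    for name, genes in coll:
        if homolog_map is not None:
            genes = [homolog_map[g] for g in genes if g in homolog_map]
        surviving = [g for g in dict.fromkeys(genes) if g in present]
        if len(surviving) >= min_genes:
            kept[name] = surviving
    if coll.pathways and not kept:
        raise ValueError("all pathways dropped by the size filter")
    return PathwayCollection(kept, source=coll.source)


def pathway_entropy_distributions(
    X: ExpressionMatrix,
    pathway_genes: Sequence[str],
    n_genes: int = 10,
    n_iter: int = 1000,
    seed: int | None = None,
    pathway: str = "",
) -> EntropySamples:
    """Iterated hypergraph entropy of random ``n_genes`` pathway subsets.

    Each iteration samples ``n_genes`` of the pathway's genes (those present
    in ``X``) without replacement as targets and builds the binarized
    correlation hypergraph against the rest of the transcriptome.  Entropy is
    taken over the hyperedge-usage distribution (column sums of the incidence
    matrix): it asks how the pathway's shared correlations are spread across
    the background transcriptome.  A functionally coordinated pathway
    concentrates its correlations on specific background partners (low
    entropy); an arbitrary gene set spreads them diffusely (high entropy).
    """
    usable = [g for g in pathway_genes if g in set(X.gene_ids)]
    if len(usable) < n_genes:
        raise ValueError(
            f"pathway {pathway or '<unnamed>'}: only {len(usable)} genes in the "
            f"matrix, need {n_genes}"
        )
    rng = np.random.default_rng(seed)
    V = X.values.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(X.gene_ids)}
    usable_idx = np.array([gene_pos[g] for g in usable])
    n = V.shape[1]
    sd = V.std(axis=1, ddof=1)
    valid = sd > 0
    mu = V.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (V - mu) / sd[:, None]
    values = np.empty(n_iter)
    for it in range(n_iter):
        for attempt in range(10):
            pick = rng.choice(len(usable_idx), size=n_genes, replace=False)
            idx = usable_idx[pick]
            if not valid[idx].all():
                continue
            bg_mask = valid.copy()
            bg_mask[idx] = False
            R = (Z[idx] @ Z[bg_mask].T) / (n - 1)
            M, _, _ = binarize_incidence(R)
            usage = M.sum(axis=0).astype(np.int64)
            if usage.sum() > 0:
                values[it] = hypergraph_entropy(usage)
                break
        else:
            raise RuntimeError(
                f"pathway {pathway or '<unnamed>'}: could not draw a usable target set"
            )
    return EntropySamples(X.condition_label(), None, values, n_genes, seed)


def _gibbs_two_group(
    y: np.ndarray,
    x: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
    burn_in: int = 500,
) -> np.ndarray:
    """Gibbs sampler for y = alpha + beta x + N(0, sigma^2).

    Priors: alpha, beta ~ N(0, (2.5 sd(y))^2); sigma^2 ~ Inv-Gamma(1e-3, 1e-3).
    Returns the retained draws of beta.
    """
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    Xty = X.T @ y
    sd_y = y.std(ddof=1)
    tau2 = (2.5 * sd_y) ** 2
    prior_prec = np.eye(2) / tau2
    a0 = b0 = 1e-3
    sigma2 = max(sd_y**2, 1e-12)
    theta = np.zeros(2)
    draws = np.empty(n_draws)
    total = burn_in + n_draws
    for t in range(total):
        V = np.linalg.inv(XtX / sigma2 + prior_prec)
        m = V @ (Xty / sigma2)
        theta = rng.multivariate_normal(m, V, method="cholesky")
        resid = y - X @ theta
        shape = a0 + n / 2
        scale = b0 + 0.5 * float(resid @ resid)
        sigma2 = scale / rng.gamma(shape)
        if t >= burn_in:
            draws[t - burn_in] = theta[1]
    return draws


def bayesian_entropy_difference(
    sc: EntropySamples,
    kd: EntropySamples,
    n_draws: int = 4000,
    seed: int | None = None,
    pathway: str = "",
) -> PathwayBeta:
    """Posterior for the SC-KD entropy difference of one pathway.

    Fits the two-group Gaussian linear model by Gibbs sampling and reports
    the sign-flipped beta (positive = higher entropy in SC), its equal-tailed
    89% credible interval (quantiles 0.055 and 0.945), and whether the
    interval excludes zero.
    """
    y = np.concatenate([np.asarray(sc.values), np.asarray(kd.values)])
    if len(sc.values) == 0 or len(kd.values) == 0:
        raise ValueError("both sample sets must be non-empty")
    x = np.concatenate([np.zeros(len(sc.values)), np.ones(len(kd.values))])
    if y.std(ddof=1) == 0:
        return PathwayBeta(pathway, 0.0, (0.0, 0.0), False, n_draws, seed)
    rng = np.random.default_rng(seed)
    beta_draws = -_gibbs_two_group(y, x, n_draws, rng)  # flip: positive = SC higher
    lo, hi = np.quantile(beta_draws, [0.055, 0.945])
    return PathwayBeta(
        pathway,
        float(beta_draws.mean()),
        (float(lo), float(hi)),
        bool(lo > 0 or hi < 0),
        n_draws,
        seed,
    )


def pathway_entropy_analysis(
    X_sc: ExpressionMatrix,
    X_kd: ExpressionMatrix,
    coll: PathwayCollection,
    n_genes: int = 10,
    n_iter: int = 1000,
    n_draws: int = 4000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Entropy distributions plus Bayesian comparison for every pathway."""
    streams = np.random.SeedSequence(seed).spawn(len(coll))
    rows = []
    for (name, genes), ss in zip(coll, streams):
        s_sc, s_kd, s_fit = ss.spawn(3)
        sc = pathway_entropy_distributions(
            X_sc, genes, n_genes, n_iter, seed=s_sc.entropy % (2**31), pathway=name
        )
        kd = pathway_entropy_distributions(
            X_kd, genes, n_genes, n_iter, seed=s_kd.entropy % (2**31), pathway=name
        )
        beta = bayesian_entropy_difference(
            sc, kd, n_draws, seed=s_fit.entropy % (2**31), pathway=name
        )
        rows.append(
            {
                "pathway": name,
                "beta_mean": beta.beta_mean,
                "ci_low": beta.ci89[0],
                "ci_high": beta.ci89[1],
                "significant": beta.significant,
                "mean_entropy_sc": float(np.mean(sc.values)),
                "mean_entropy_kd": float(np.mean(kd.values)),
            }
        )
    return pd.DataFrame(rows)
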