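"""Gene importance ranks from hypergraph row sums, and enrichment testing.

A gene's importance in a hypergraph is its row sum in the incidence matrix
(connectivity) or in the reduced adjacency matrix (higher-order
interactions).  Row sums are converted to normalized ranks in [0, 1]
(1 = most connected, ties averaged) so that ranks are comparable between the
SC and KD hypergraphs, and annotated gene sets (e.g. cardiometabolic GWAS
hits) are tested for enrichment with a two-tailed Fisher exact test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hypergraph import Hypergraph, connectivity

__all__ = [
    "EnrichmentResult",
    "normalized_rank",
    "rank_table",
    "rank_shift",
    "gwas_enrichment_test",
]


def normalized_rank(row_sums: Sequence[float]) -> np.ndarray:
    """Descending tie-averaged ranks, rescaled to [0, 1] (1 = largest).

    With ranks r in 1..n (1 = largest row sum), the normalized rank is
    (n - r) / (n - 1), so the most connected gene maps to 1 and the least
    to 0; all-equal input maps everywhere to 0.5.
    """
    x = np.asarray(row_sums, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 row sums to rank")
    ranks = stats.rankdata(-x, method="average")
    return (n - ranks) / (n - 1)


def rank_table(H: Hypergraph) -> pd.DataFrame:
    """Row sums and normalized ranks for both matrix kinds of one hypergraph."""
    rows = []
    for kind in ("incidence", "adjacency"):
        sums = connectivity(H, kind).astype(float)
        norm = normalized_rank(sums)
        for g, s, r in zip(H.g, sums, norm):
            rows.append({"gene": g, "kind": kind, "row_sum": s, "norm_rank": r})
    return pd.DataFrame(rows)


def rank_shift(
    genes: Sequence[str],
    sc: pd.DataFrame,
    kd: pd.DataFrame,
    kind: str = "incidence",
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene normalized-rank difference between conditions.

    ``sc`` and ``kd`` are :func:`rank_table` outputs.  Genes missing from
    either table (for the requested kind) are reported in the skipped list,
    never silently dropped.  ``delta = norm_rank_kd - norm_rank_sc``.
    """
    sc_k = sc[sc["kind"] == kind].set_index("gene")["norm_rank"]
    kd_k = kd[kd["kind"] == kind].set_index("gene")["norm_rank"]
    rows, skipped = [], []
    for g in genes:
        if g not in sc_k.index or g not in kd_k.index:
            skipped.append(g)
            continue
        rows.append(
            {
                "gene": g,
                "norm_rank_sc": float(sc_k[g]),
                "norm_rank_kd": float(kd_k[g]),
                "delta": float(kd_k[g] - sc_k[g]),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "norm_rank_sc", "norm_rank_kd", "delta"]), skipped


@dataclasses.dataclass
class EnrichmentResult:
    """2x2 enrichment: sample odds ratio and two-tailed Fisher exact p."""

    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    continuity_corrected: bool = False
    conditional_odds_ratio: float | None = None


def gwas_enrichment_test(
    hits_in_query: int,
    query_size: int,
    background_hits: int,
    background_size: int,
) -> EnrichmentResult:
    """Fisher exact enrichment of annotated genes in a query set.

    Builds [[hits, query - hits], [background hits, background - hits]] and
    reports the sample odds ratio (ad/bc; Haldane 0.5 correction when an
    off-diagonal cell is zero, flagged) alongside the two-tailed exact p.
    The conditional-MLE odds ratio is also carried for reference.
    """
    if hits_in_query > query_size or background_hits > background_size:
        raise ValueError("hits cannot exceed their set size")
    if min(hits_in_query, query_size, background_hits, background_size) < 0:
        raise ValueError("counts must be non-negative")
    a, b = hits_in_query, query_size - hits_in_query
    c, d = background_hits, background_size - background_hits
    corrected = False
    if b == 0 or c == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        odds = (a * d) / (b * c)
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    cond = stats.contingency.odds_ratio([[a, b], [c, d]]).statistic
    return EnrichmentResult(
        float(odds), float(res.pvalue), ((a, b), (c, d)), corrected, float(cond)
    )
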