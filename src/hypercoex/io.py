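"""Readers, writers and core containers.

Every downstream module consumes :class:`ExpressionMatrix` and
:class:`PathwayCollection`; nothing else in the package parses files.  The
canonical on-disk dialect is tab-separated text: an expression matrix with
gene ids in the first column and sample ids in the header, a sample metadata
table with columns ``sample``, ``age_dpf``, ``condition``, ``replicate``,
GMT for gene-set collections, and two-column TSV for homolog maps.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

VALID_CONDITIONS = ("SC", "KD")

__all__ = [
    "ExpressionMatrix",
    "PathwayCollection",
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_two_column_map",
    "read_gene_list",
]


@dataclasses.dataclass
class ExpressionMatrix:
    """Normalized log2 expression (genes x samples) with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids, entries = log2 normalized intensity.
    meta
        DataFrame indexed by sample id with columns ``age_dpf`` (int),
        ``condition`` (one of ``SC``/``KD``) and ``replicate`` (int >= 1).
        Rows are re-aligned to the column order of ``values``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        matrix_samples = set(self.values.columns)
        meta_samples = set(self.meta.index)
        if matrix_samples != meta_samples:
            only_matrix = sorted(matrix_samples - meta_samples)
            only_meta = sorted(meta_samples - matrix_samples)
            raise ValueError(
                "sample sets differ between matrix and metadata: "
                f"matrix-only={only_matrix[:5]}, meta-only={only_meta[:5]}"
            )
        for col in ("age_dpf", "condition", "replicate"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata missing column {col!r}")
        bad = set(self.meta["condition"]) - set(VALID_CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        # align metadata rows to the matrix column order; canonical axis names
        self.meta = self.meta.loc[list(self.values.columns)]
        self.values.index.name = None
        self.values.columns.name = None
        self.meta.index.name = None
        if np.isnan(self.values.to_numpy(dtype=float)).any():
            raise ValueError("expression matrix contains missing values")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ages(self) -> list[int]:
        return sorted(set(int(a) for a in self.meta["age_dpf"]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def condition_label(self) -> str:
        """Condition of the samples, or ``mixed`` if more than one."""
        conds = set(self.meta["condition"])
        return conds.pop() if len(conds) == 1 else "mixed"

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.meta.loc[sample_ids].copy())

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        keep = self.meta.index[self.meta["condition"] == condition]
        if len(keep) == 0:
            raise ValueError(f"no samples with condition {condition!r}")
        return self.subset_samples(keep)

    def subset_ages(self, ages: Sequence[int]) -> "ExpressionMatrix":
        ages = set(int(a) for a in ages)
        keep = self.meta.index[self.meta["age_dpf"].astype(int).isin(ages)]
        if len(keep) == 0:
            raise ValueError(f"no samples at ages {sorted(ages)}")
        return self.subset_samples(keep)


@dataclasses.dataclass
class PathwayCollection:
    """Named gene sets (pathway name -> gene-id list), order preserving."""

    pathways: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} has an empty gene list")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())


@dataclasses.dataclass
class RunConfig:
    """Run-level configuration: the seed and every iteration count.

    The seed recorded here is propagated to every stochastic stage and
    written into each output manifest so that 1000-iteration procedures are
    exactly reproducible.
    """

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    missing_policy: str = "drop_gene"  # or "fail"
    n_permutations: int = 1000
    timeseries_targets: int = 100
    timeseries_iterations: int = 1000
    pathway_targets: int = 10
    pathway_iterations: int = 1000
    posterior_draws: int = 4000
    min_pathway_genes: int = 15
    pca_components: int = 2
    pca_permutations: int = 20

    def __post_init__(self) -> None:
        for field in (
            "n_permutations",
            "timeseries_targets",
            "timeseries_iterations",
            "pathway_targets",
            "pathway_iterations",
            "posterior_draws",
        ):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        if self.missing_policy not in ("drop_gene", "fail"):
            raise ValueError("missing_policy must be 'drop_gene' or 'fail'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def write_manifest(self, path: str | Path, **extra) -> None:
        payload = dataclasses.asdict(self)
        payload.update(extra)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    matrix_path: str | Path,
    meta_path: str | Path,
    missing_policy: str = "drop_gene",
) -> ExpressionMatrix:
    """Load an expression TSV plus metadata TSV into an :class:`ExpressionMatrix`.

    ``missing_policy`` controls incomplete rows: ``drop_gene`` silently drops
    genes with any missing cell, ``fail`` raises naming the first offender.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    for col in values.columns:
        coerced = pd.to_numeric(values[col], errors="coerce")
        bad = coerced.isna() & values[col].notna()
        if bad.any():
            gene = values.index[bad.argmax()]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
        values[col] = coerced
    incomplete = values.isna().any(axis=1)
    if incomplete.any():
        if missing_policy == "fail":
            raise ValueError(
                f"missing values in genes {values.index[incomplete].tolist()[:5]}"
            )
        values = values.loc[~incomplete]
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample": str})
    required = {"sample", "age_dpf", "condition", "replicate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns {sorted(missing_cols)}")
    meta = meta.set_index("sample")
    return ExpressionMatrix(values, meta)


def write_expression(
    X: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path
) -> None:
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    X.values.to_csv(matrix_path, sep="\t", index_label="gene")
    meta = X.meta.reset_index()
    meta = meta.rename(columns={meta.columns[0]: "sample"})
    meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets and gene lists


def read_gene_sets(gmt_path: str | Path) -> PathwayCollection:
    """Parse a GMT file (name, description, then tab-separated gene ids)."""
    pathways: dict[str, list[str]] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{gmt_path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in pathways:
                raise ValueError(f"{gmt_path}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = [g for g in fields[2:] if g]
    return PathwayCollection(pathways, source=str(gmt_path))


def write_gene_sets(coll: PathwayCollection, gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for name, genes in coll:
            fh.write("\t".join([name, coll.source or "na", *genes]) + "\n")


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (e.g. human symbol -> zebrafish homolog); no header."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected exactly 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
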