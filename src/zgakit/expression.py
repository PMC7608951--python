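"""Count-matrix I/O and normalization for single-embryo RNA-seq.

Values live in a pandas DataFrame (genes x samples) tagged with a
processing ``stage`` (``counts`` -> ``log2cpm`` -> ``row_scaled``) so
operations can refuse double normalization, plus a sample-metadata table
(condition, cycle label, minutes after mitosis 11, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

STAGES = ("counts", "log2cpm", "row_scaled")
META_COLUMNS = ("sample_id", "condition", "cycle_label", "minutes", "replicate")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values at a tagged processing stage."""

    values: pd.DataFrame
    stage: str = "counts"
    meta: pd.DataFrame | None = None
    constant_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape[1] < 1:
            raise ValueError("matrix must have at least one sample")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in matrix")
        if self.stage == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in counts-stage matrix")
        if self.meta is not None:
            missing = set(META_COLUMNS) - set(self.meta.columns)
            if missing:
                raise ValueError(f"metadata missing columns: {sorted(missing)}")
            if not set(self.values.columns) <= set(self.meta["sample_id"]):
                raise ValueError("metadata does not cover all samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def _require_stage(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise ValueError(f"{op} requires a {stage}-stage matrix, got {self.stage}")

    def with_meta(self, meta: pd.DataFrame) -> "ExpressionMatrix":
        return replace(self, meta=meta)

    def drop_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Explicit sample exclusion (e.g. an outlier embryo)."""
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return replace(self, values=self.values[keep])

    def condition_key(self) -> pd.Series:
        """Per-sample '<condition>:<cycle_label>' key (replicate grouping)."""
        if self.meta is None:
            raise ValueError("matrix has no sample metadata")
        m = self.meta.set_index("sample_id").loc[list(self.values.columns)]
        return m["condition"].astype(str) + ":" + m["cycle_label"].astype(str)

    def condition_means(self) -> pd.DataFrame:
        """Genes x conditions, replicate embryos averaged within condition."""
        keys = self.condition_key()
        return self.values.T.groupby(keys.values).mean().T


def read_counts(path: str | Path, meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV of raw counts (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(values=values, stage="counts", meta=meta)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return meta


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def log2_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample counts-per-million, then log2(CPM + 1).

    The pseudocount avoids log2(0); library size is the column total of
    the counts assigned to genes in the matrix.
    """
    matrix._require_stage("counts", "log2_cpm")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    cpm = matrix.values / totals * 1e6
    return replace(matrix, values=np.log2(cpm + 1.0), stage="log2cpm")


def scale_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, sd 1 (sample sd, ddof=1),
    as for heatmap display. Constant rows become all-zero and are flagged
    in ``constant_genes``."""
    matrix._require_stage("log2cpm", "scale_rows")
    vals = matrix.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    scaled = vals.sub(mean, axis=0).div(safe_sd, axis=0)
    return replace(
        matrix,
        values=scaled,
        stage="row_scaled",
        constant_genes=tuple(vals.index[constant]),
    )


def pca_trajectory(matrix: ExpressionMatrix, n_components: int = 2):
    """Centered (not variance-scaled) PCA with genes as features.

    Returns ``(coordinates, explained_variance_ratio)``: coordinates is a
    samples x components DataFrame (columns PC1, PC2, ...). Signs of
    components are arbitrary.
    """
    matrix._require_stage("log2cpm", "pca_trajectory")
    X = matrix.values.T.to_numpy(dtype=float)  # samples x genes
    if matrix.values.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, genes)={min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=matrix.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def mean_foldchange_profile(
    matrix: ExpressionMatrix,
    gene_set: list[str],
    baseline_condition: str,
) -> pd.Series:
    """Per-condition mean Log2 fold change of a gene set vs a baseline.

    Replicates are averaged within condition first; each gene's profile is
    its condition mean minus its baseline mean (Log2 CPM+1 units); the
    profile is then averaged over the gene set.
    """
    matrix._require_stage("log2cpm", "mean_foldchange_profile")
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    means = matrix.condition_means()
    if baseline_condition not in means.columns:
        raise KeyError(f"baseline condition {baseline_condition!r} not present")
    missing = set(gene_set) - set(means.index)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    sub = means.loc[list(gene_set)]
    fc = sub.sub(sub[baseline_condition], axis=0)
    return fc.mean(axis=0)
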