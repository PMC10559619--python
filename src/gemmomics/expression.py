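"""Gene-by-sample expression container.

The :class:`ExpressionMatrix` is the backbone of the integration,
enrichment, and classification stages: a real-valued genes x samples
matrix with per-sample metadata (biological group, e.g. histological
subtype or intrinsic subtype, and technical batch).

Values are assumed to live on a log-like scale (microarray log2
intensities or similar), which is what mean differences being
interpreted as log-fold changes requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample group/batch metadata.

    Parameters
    ----------
    values
        DataFrame with gene symbols as index and sample IDs as columns.
    meta
        DataFrame indexed by sample ID with columns ``group`` and
        ``batch``. Missing metadata defaults to a single group/batch.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"group": "all", "batch": "b0"}, index=self.values.columns
            )
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.meta = self.meta.loc[self.values.columns]
        self.values.index.name = "gene"
        self.values.columns.name = None
        self.meta.index.name = "sample"

    # -- basic accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def groups(self) -> pd.Series:
        return self.meta["group"]

    def batches(self) -> pd.Series:
        return self.meta["batch"]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes].copy(), self.meta.copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(
            self.values[samples].copy(), self.meta.loc[samples].copy()
        )

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.meta.index[self.meta["group"] == group])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (genes in rows); metadata alongside."""
        p = Path(path)
        self.values.to_csv(p, sep="\t", index_label="gene")
        if meta_path is None:
            meta_path = p.with_suffix(p.suffix + ".meta")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(
        cls, path: str | Path, meta_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        p = Path(path)
        values = pd.read_csv(p, sep="\t", index_col=0, float_precision="round_trip")
        values.index.name = "gene"
        meta = None
        if meta_path is None:
            candidate = p.with_suffix(p.suffix + ".meta")
            meta_path = candidate if candidate.exists() else None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, meta)

    def to_gct(self, path: str | Path) -> None:
        """Write GCT 1.2 (versioned header, NAME/Description columns)."""
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{self.shape[0]}\t{self.shape[1]}\n")
            fh.write("NAME\tDescription\t" + "\t".join(self.samples) + "\n")
            for gene, row in self.values.iterrows():
                vals = "\t".join(format(v, ".6g") for v in row.to_numpy())
                fh.write(f"{gene}\tna\t{vals}\n")

    @classmethod
    def from_gct(
        cls, path: str | Path, meta: pd.DataFrame | None = None
    ) -> "ExpressionMatrix":
        with open(path) as fh:
            version = fh.readline().strip()
            if version not in ("#1.2",):
                raise ValueError(f"unsupported GCT version line: {version!r}")
            n_genes, n_samples = map(int, fh.readline().split())
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"])
        df.index.name = "gene"
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"GCT header says {(n_genes, n_samples)}, body is {df.shape}"
            )
        return cls(df.astype(float), meta)


def concat_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-wise concatenation on the shared gene set (inner join).

    Used to pool cohorts (e.g. human training data plus mouse samples)
    before joint batch adjustment.
    """
    shared = [g for g in a.genes if g in set(b.genes)]
    if not shared:
        raise ValueError("no shared genes between matrices")
    values = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample IDs across matrices")
    meta = pd.concat([a.meta, b.meta], axis=0)
    return ExpressionMatrix(values, meta)


def map_homologs(
    expr: ExpressionMatrix, homologs: Mapping[str, str]
) -> ExpressionMatrix:
    """Rename genes through a homolog map, dropping unmapped genes.

    When two source genes map to the same target symbol the first
    (in row order) is kept.
    """
    mapped = {g: homologs[g] for g in expr.genes if g in homologs}
    values = expr.values.loc[list(mapped)].rename(index=mapped)
    values = values[~values.index.duplicated(keep="first")]
    return ExpressionMatrix(values, expr.meta.copy())
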