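"""Shared containers and on-disk formats.

The expression container is deliberately small: a genes x spots count table
plus an optional normalized layer, both as labelled pandas frames. Counts are
exchanged as Matrix Market (MTX) with side-car gene/barcode TSVs; the
normalized layer as a plain TSV. Everything round-trips exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """Genes x spots expression with an optional normalized layer.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer counts, index = gene ids, columns = spot barcodes.
    normalized : pandas.DataFrame, optional
        Same shape/labels as ``counts``; typically depth-scaled log1p.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        # axis labels carry no information here; normalize so IO round-trips compare equal
        for df in (self.counts, self.normalized):
            if df is not None:
                # rename (not in-place name assignment): the Index object may be shared
                df.index = df.index.rename(None)
                df.columns = df.columns.rename(None)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate spot ids in counts")
        if self.normalized is not None:
            if not self.normalized.index.equals(self.counts.index) or not self.normalized.columns.equals(
                self.counts.columns
            ):
                raise ValueError("normalized layer labels do not match counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def spot_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def layer(self, name: str = "normalized") -> pd.DataFrame:
        """Return a layer by name ('counts' or 'normalized')."""
        if name == "counts":
            return self.counts
        if name == "normalized":
            if self.normalized is None:
                raise ValueError("no normalized layer present")
            return self.normalized
        raise KeyError(name)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.counts.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        norm = self.normalized.loc[genes] if self.normalized is not None else None
        return ExpressionMatrix(self.counts.loc[genes], norm)

    # -- IO -----------------------------------------------------------------

    def write(self, directory: str | os.PathLike) -> None:
        """Write counts.mtx + genes.tsv + barcodes.tsv (+ normalized.tsv)."""
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        mat = scipy.sparse.csc_matrix(self.counts.to_numpy())
        scipy.io.mmwrite(os.path.join(directory, "counts.mtx"), mat, field="integer")
        pd.Series(self.gene_ids).to_csv(
            os.path.join(directory, "genes.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(self.spot_ids).to_csv(
            os.path.join(directory, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        if self.normalized is not None:
            self.normalized.to_csv(os.path.join(directory, "normalized.tsv"), sep="\t")

    @classmethod
    def read(cls, directory: str | os.PathLike) -> "ExpressionMatrix":
        directory = os.fspath(directory)
        mat = scipy.io.mmread(os.path.join(directory, "counts.mtx")).toarray().astype(np.int64)
        genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(os.path.join(directory, "barcodes.tsv"), sep="\t", header=None)[0].astype(str)
        counts = pd.DataFrame(mat, index=genes.tolist(), columns=barcodes.tolist())
        norm_path = os.path.join(directory, "normalized.tsv")
        normalized = None
        if os.path.exists(norm_path):
            normalized = pd.read_csv(norm_path, sep="\t", index_col=0)
            normalized.index = normalized.index.astype(str)
            normalized.columns = normalized.columns.astype(str)
        return cls(counts, normalized)
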