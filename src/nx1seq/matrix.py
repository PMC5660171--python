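"""Digital expression matrix container and on-disk formats (MTX, TSV).

Counts are *read* counts ("tags"): the bead chemistry has no UMIs, so a tag
is one sequenced cDNA fragment, and after per-cell normalization values
become fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

_REL_TOL = 1e-6


class NormalizedMatrixError(ValueError):
    """Raised when an operation requiring raw counts gets a normalized matrix."""


@dataclass
class DigitalExpressionMatrix:
    """Cell-barcode x gene count matrix.

    ``data`` is a pandas DataFrame with barcodes as the index and gene ids as
    columns.  ``normalized_total`` is None for raw read counts; once set,
    every row sums to that value (within 1e-6 relative tolerance).
    """

    data: pd.DataFrame
    sample_label: str = ""
    normalized_total: float | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate barcodes in matrix index")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate gene ids in matrix columns")
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.normalized_total is not None and len(self.data):
            sums = self.data.sum(axis=1).to_numpy(dtype=float)
            if not np.allclose(sums, self.normalized_total, rtol=_REL_TOL, atol=0):
                raise ValueError("row sums inconsistent with normalized_total")

    # -- basic accessors -------------------------------------------------

    @property
    def barcodes(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_cells(self) -> int:
        return len(self.data.index)

    @property
    def n_genes(self) -> int:
        return len(self.data.columns)

    def reads_per_cell(self) -> pd.Series:
        return self.data.sum(axis=1)

    def genes_per_cell(self) -> pd.Series:
        """Number of genes with a nonzero count, per barcode."""
        return (self.data > 0).sum(axis=1)

    def subset_barcodes(self, barcodes) -> "DigitalExpressionMatrix":
        return DigitalExpressionMatrix(
            data=self.data.loc[list(barcodes)].copy(),
            sample_label=self.sample_label,
            normalized_total=self.normalized_total,
        )

    # -- I/O -------------------------------------------------------------

    def to_mtx(self, outdir: str | Path) -> None:
        """Write matrix.mtx + barcodes.tsv + genes.tsv (genes x cells layout)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mat = sparse.csc_matrix(self.data.to_numpy().T)
        sio.mmwrite(str(outdir / "matrix.mtx"), mat)
        (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in self.barcodes))
        (outdir / "genes.tsv").write_text("".join(g + "\n" for g in self.genes))

    @classmethod
    def from_mtx(cls, indir: str | Path, sample_label: str = "",
                 normalized_total: float | None = None) -> "DigitalExpressionMatrix":
        indir = Path(indir)
        mat = sio.mmread(str(indir / "matrix.mtx")).toarray().T
        barcodes = (indir / "barcodes.tsv").read_text().split()
        genes = (indir / "genes.tsv").read_text().split()
        df = pd.DataFrame(mat, index=barcodes, columns=genes)
        if normalized_total is None and (df.to_numpy() % 1 == 0).all():
            df = df.astype(np.int64)
        return cls(df, sample_label=sample_label, normalized_total=normalized_total)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="barcode")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_label: str = "",
                 normalized_total: float | None = None) -> "DigitalExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="barcode")
        return cls(df, sample_label=sample_label, normalized_total=normalized_total)
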