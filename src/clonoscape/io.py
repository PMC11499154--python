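"""Plain-text readers/writers for pipeline artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .expression import GexMatrix
from .molecules import MOLECULE_COLUMNS, validate_molecule_table

__all__ = [
    "read_molecule_table",
    "write_molecule_table",
    "write_gex_csv",
    "read_gex_csv",
    "write_gex_mtx",
    "read_gex_mtx",
]


def write_molecule_table(molecules: pd.DataFrame, path: str | Path) -> None:
    validate_molecule_table(molecules)
    molecules[MOLECULE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_molecule_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_label": str, "umi": str, "feature": str})
    validate_molecule_table(df)
    return df


def write_gex_csv(m: GexMatrix, path: str | Path) -> None:
    m.to_csv(path)


def read_gex_csv(path: str | Path, sample_id: str, stage: str = "counts") -> GexMatrix:
    df = pd.read_csv(path, index_col="cell_id")
    return GexMatrix(
        values=df.to_numpy(),
        cell_ids=[str(c) for c in df.index],
        gene_names=[str(g) for g in df.columns],
        sample_ids=[sample_id] * len(df),
        stage=stage,
    )


def write_gex_mtx(m: GexMatrix, prefix: str | Path) -> None:
    """MatrixMarket triple: ``<prefix>.mtx`` plus cell/gene name sidecars."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(m.values))
    prefix.with_suffix(".cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    prefix.with_suffix(".genes.txt").write_text("\n".join(m.gene_names) + "\n")


def read_gex_mtx(prefix: str | Path, sample_id: str, stage: str = "counts") -> GexMatrix:
    from scipy.io import mmread

    prefix = Path(prefix)
    values = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    cells = prefix.with_suffix(".cells.txt").read_text().splitlines()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    return GexMatrix(
        values=values,
        cell_ids=cells,
        gene_names=genes,
        sample_ids=[sample_id] * len(cells),
        stage=stage,
    )
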