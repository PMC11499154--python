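"""Expression-side processing: merge, CPM, log2 transform, gating, PCA, UMAP."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GexMatrix",
    "EmbeddingResult",
    "merge_gex",
    "cpm_normalize",
    "log2_zero_to_one",
    "gate_cd8",
    "pca_scree",
    "umap_embed",
]

_STAGES = ("counts", "cpm", "log2cpm")

MARKERS = ("CD8", "CD4", "FOXP3")


@dataclass
class GexMatrix:
    """Cells x genes matrix with per-cell sample annotation and a stage tag."""

    values: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    sample_ids: list[str]
    stage: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        if len(self.sample_ids) != len(self.cell_ids):
            raise ValueError("sample_ids must have one entry per cell")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene(self, name: str) -> np.ndarray:
        if name not in self.gene_names:
            raise KeyError(f"gene {name!r} not in matrix")
        return self.values[:, self.gene_names.index(name)]

    def subset_cells(self, cells: list[str]) -> "GexMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in cells]
        return GexMatrix(
            values=self.values[idx],
            cell_ids=list(cells),
            gene_names=list(self.gene_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            stage=self.stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_names)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="cell_id")


@dataclass
class EmbeddingResult:
    """PCA scores / explained variance, optionally with UMAP coordinates."""

    pc_scores: np.ndarray
    explained_variance_ratio: np.ndarray
    n_pcs_used: int
    seed: int
    cell_ids: list[str] = field(default_factory=list)
    umap_coords: np.ndarray | None = None

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.explained_variance_ratio) + 1),
                "explained_variance_ratio": self.explained_variance_ratio,
            }
        )


def merge_gex(matrices: list[GexMatrix]) -> GexMatrix:
    """Row-concatenate per-sample matrices sharing an identical gene panel."""
    if not matrices:
        raise ValueError("no matrices to merge")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.gene_names != ref.gene_names:
            diff = sorted(set(m.gene_names) ^ set(ref.gene_names))
            raise ValueError(f"gene_names mismatch between matrices: {diff}")
        if m.stage != ref.stage:
            raise ValueError("cannot merge matrices at different stages")
    cells = [c for m in matrices for c in m.cell_ids]
    if len(set(cells)) != len(cells):
        dupes = sorted({c for c in cells if cells.count(c) > 1})
        raise ValueError(f"duplicate cell ids across matrices: {dupes[:5]}")
    return GexMatrix(
        values=np.vstack([m.values for m in matrices]),
        cell_ids=cells,
        gene_names=list(ref.gene_names),
        sample_ids=[s for m in matrices for s in m.sample_ids],
        stage=ref.stage,
    )


def cpm_normalize(m: GexMatrix) -> GexMatrix:
    """Scale every cell row to one million total counts.

    All-zero rows are left all-zero and reported with a warning.
    """
    if m.stage != "counts":
        raise ValueError(f"cpm_normalize expects stage 'counts', got {m.stage!r}")
    totals = m.values.sum(axis=1, dtype=float)
    zero_rows = totals == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero cell rows left unnormalized",
            stacklevel=2,
        )
    scale = np.divide(1e6, totals, out=np.zeros_like(totals), where=~zero_rows)
    return replace(m, values=m.values * scale[:, None], stage="cpm")


def log2_zero_to_one(m: GexMatrix) -> GexMatrix:
    """log2 with zeros (and sub-one values) clamped to one beforehand.

    Maps v to ``log2(max(v, 1))`` so zeros land exactly at 0.
    """
    if m.stage != "cpm":
        raise ValueError(f"log2_zero_to_one expects stage 'cpm', got {m.stage!r}")
    return replace(m, values=np.log2(np.maximum(m.values, 1.0)), stage="log2cpm")


def gate_cd8(
    m: GexMatrix,
    cd8_min: float = 0.0,
    cd4_max: float = 0.0,
    foxp3_max: float = 0.0,
) -> tuple[set[str], dict]:
    """Select effector cells: CD8 > cd8_min, CD4 <= cd4_max, FOXP3 <= foxp3_max.

    Returns the retained cell-id set and a report including the CD8+ fraction.
    """
    if m.stage != "log2cpm":
        raise ValueError(f"gate_cd8 expects stage 'log2cpm', got {m.stage!r}")
    for g in MARKERS:
        if g not in m.gene_names:
            raise ValueError(f"marker gene {g!r} absent from matrix")
    keep = (
        (m.gene("CD8") > cd8_min)
        & (m.gene("CD4") <= cd4_max)
        & (m.gene("FOXP3") <= foxp3_max)
    )
    gated = {c for c, k in zip(m.cell_ids, keep) if k}
    report = {
        "n_cells": m.n_cells,
        "n_gated": int(keep.sum()),
        "cd8_fraction": float(keep.mean()) if m.n_cells else float("nan"),
        "thresholds": {"cd8_min": cd8_min, "cd4_max": cd4_max, "foxp3_max": foxp3_max},
    }
    return gated, report


def pca_scree(m: GexMatrix, n_components: int) -> EmbeddingResult:
    """Mean-centered PCA; scores and explained-variance ratios in decreasing order."""
    from sklearn.decomposition import PCA

    if m.stage != "log2cpm":
        raise ValueError(f"pca_scree expects stage 'log2cpm', got {m.stage!r}")
    limit = min(m.values.shape)
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={limit}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(np.asarray(m.values, dtype=float))
    return EmbeddingResult(
        pc_scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_pcs_used=n_components,
        seed=0,
        cell_ids=list(m.cell_ids),
    )


def umap_embed(
    pcs: EmbeddingResult,
    n_pcs: int = 4,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> EmbeddingResult:
    """2-D UMAP of the first ``n_pcs`` principal components (seeded)."""
    import umap

    if n_pcs > pcs.pc_scores.shape[1]:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds available components {pcs.pc_scores.shape[1]}"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # umap-learn warns that a fixed random_state disables parallelism
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(pcs.pc_scores[:, :n_pcs])
    return EmbeddingResult(
        pc_scores=pcs.pc_scores,
        explained_variance_ratio=pcs.explained_variance_ratio,
        n_pcs_used=n_pcs,
        seed=seed,
        cell_ids=list(pcs.cell_ids),
        umap_coords=np.asarray(coords),
    )
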