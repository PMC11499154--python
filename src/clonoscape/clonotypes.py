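"""Paired-chain clonotype construction, counting, and dominant selection.

AIRR rearrangement rows (one receptor chain per row) are paired per cell
into full-length alpha/beta clonotypes; clonotypes are counted by member
cells and the dominant one is selected by cell count first and mean
predicted binding score second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AIRR_COLUMNS",
    "read_airr",
    "write_airr",
    "build_clonotypes",
    "annotate_clonotypes",
    "clonotype_abundance",
    "select_dominant",
    "DominantSelection",
]

AIRR_COLUMNS = [
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction_aa",
    "sequence_aa",
    "duplicate_count",
    "productive",
]

#: Clonotype identity: V/J calls plus full-length amino-acid chain sequences.
CLONOTYPE_KEY_FIELDS = [
    "tra_v_call", "tra_j_call", "tra_sequence_aa",
    "trb_v_call", "trb_j_call", "trb_sequence_aa",
]


def read_airr(path: str | Path) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV restricted to the columns used here.

    Non-productive rows are retained (flagged by the ``productive`` column).
    """
    df = pd.read_csv(path, sep="\t", dtype={"duplicate_count": "Int64"})
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR file missing required column(s): {missing}")
    if len(df) == 0:
        return df[AIRR_COLUMNS].assign(
            duplicate_count=pd.Series(dtype=np.int64),
            productive=pd.Series(dtype=bool),
        )[AIRR_COLUMNS]
    bad = ~df["locus"].isin(["TRA", "TRB"])
    if bad.any():
        raise ValueError(
            f"locus must be TRA or TRB (offending values: {sorted(df.loc[bad, 'locus'].unique())})"
        )
    if isinstance(df["productive"].iloc[0], str):
        df["productive"] = df["productive"].map({"T": True, "F": False})
    df["duplicate_count"] = df["duplicate_count"].astype(np.int64)
    empty_junc = df["productive"] & (df["junction_aa"].fillna("") == "")
    if empty_junc.any():
        raise ValueError("productive rows must have a non-empty junction_aa")
    return df[AIRR_COLUMNS]


def write_airr(airr: pd.DataFrame, path: str | Path) -> None:
    """Write the AIRR subset as TSV (``productive`` encoded T/F)."""
    out = airr[AIRR_COLUMNS].copy()
    out["productive"] = out["productive"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ClonotypeBuildReport:
    n_cells_in: int = 0
    n_cells_paired: int = 0
    excluded_cells: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_cells)


def _empty_clonotype_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=CLONOTYPE_KEY_FIELDS + ["cdr3a", "cdr3b", "member_cells", "n_cells"]
    )


def build_clonotypes(
    airr: pd.DataFrame, cells: set[str]
) -> tuple[pd.DataFrame, ClonotypeBuildReport]:
    """Pair one productive TRA and one productive TRB chain per cell.

    Per cell and locus the productive row with the highest
    ``duplicate_count`` wins (ties to the lexicographically smallest
    ``sequence_aa``).  Cells lacking either chain are excluded and listed
    in the report.  Returns a clonotype table with one row per distinct
    paired key, its member cells and ``n_cells``, sorted by descending
    ``n_cells`` then key.
    """
    report = ClonotypeBuildReport(n_cells_in=len(cells))
    if not cells:
        return _empty_clonotype_table(), report
    sub = airr[airr["cell_id"].isin(cells) & airr["productive"].astype(bool)]
    best = (
        sub.sort_values(
            ["cell_id", "locus", "duplicate_count", "sequence_aa"],
            ascending=[True, True, False, True],
            kind="mergesort",
        )
        .drop_duplicates(["cell_id", "locus"])
    )
    tra = best[best["locus"] == "TRA"].set_index("cell_id")
    trb = best[best["locus"] == "TRB"].set_index("cell_id")
    paired_ids = tra.index.intersection(trb.index)
    report.excluded_cells = sorted(cells - set(paired_ids))
    report.n_cells_paired = len(paired_ids)
    if len(paired_ids) == 0:
        return _empty_clonotype_table(), report
    a, b = tra.loc[paired_ids], trb.loc[paired_ids]
    cells_df = pd.DataFrame(
        {
            "cell_id": paired_ids,
            "tra_v_call": a["v_call"].to_numpy(),
            "tra_j_call": a["j_call"].to_numpy(),
            "tra_sequence_aa": a["sequence_aa"].to_numpy(),
            "trb_v_call": b["v_call"].to_numpy(),
            "trb_j_call": b["j_call"].to_numpy(),
            "trb_sequence_aa": b["sequence_aa"].to_numpy(),
            "cdr3a": a["junction_aa"].to_numpy(),
            "cdr3b": b["junction_aa"].to_numpy(),
        }
    )
    grouped = cells_df.groupby(CLONOTYPE_KEY_FIELDS + ["cdr3a", "cdr3b"], sort=False)[
        "cell_id"
    ]
    table = grouped.agg(lambda s: sorted(s)).rename("member_cells").reset_index()
    table["n_cells"] = table["member_cells"].map(len)
    table = table.sort_values(
        ["n_cells"] + CLONOTYPE_KEY_FIELDS, ascending=[False] + [True] * 6,
        kind="mergesort",
    ).reset_index(drop=True)
    return table, report


def annotate_clonotypes(
    table: pd.DataFrame,
    binding_score_of_cell: dict[str, float] | None = None,
    effector_cells: set[str] | None = None,
) -> pd.DataFrame:
    """Attach mean binding score and effector (CD8+CD4-FOXP3-) fraction.

    ``binding_score_of_cell`` maps cell id to its predicted binding score;
    ``effector_cells`` is the gated cell-id set.  Missing inputs leave the
    corresponding column absent.
    """
    out = table.copy()
    if binding_score_of_cell is not None:
        out["mean_binding_score"] = out["member_cells"].map(
            lambda cs: float(
                np.mean([binding_score_of_cell[c] for c in cs if c in binding_score_of_cell])
            )
            if any(c in binding_score_of_cell for c in cs)
            else np.nan
        )
    if effector_cells is not None:
        out["frac_cd8_cd4neg_foxp3neg"] = out["member_cells"].map(
            lambda cs: sum(c in effector_cells for c in cs) / len(cs)
        )
    return out


def clonotype_abundance(table: pd.DataFrame, min_cells: int = 2) -> pd.DataFrame:
    """Clonotypes with ``n_cells >= min_cells``, by descending size then key."""
    if min_cells < 1:
        raise ValueError(f"min_cells must be >= 1 (got {min_cells})")
    out = table[table["n_cells"] >= min_cells]
    out = out.sort_values(
        ["n_cells"] + CLONOTYPE_KEY_FIELDS, ascending=[False] + [True] * 6,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


@dataclass
class DominantSelection:
    key: tuple
    n_cells: int
    mean_binding_score: float
    cdr3a: str
    cdr3b: str
    member_cells: list[str]
    top10: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "key": list(self.key),
            "n_cells": self.n_cells,
            "mean_binding_score": self.mean_binding_score,
            "cdr3a": self.cdr3a,
            "cdr3b": self.cdr3b,
            "member_cells": self.member_cells,
            "top10": self.top10.to_dict(orient="records"),
        }


def select_dominant(
    table: pd.DataFrame, min_effector_frac: float = 0.5
) -> DominantSelection:
    """Dominant clonotype by (cell count, mean binding score), lexicographically.

    Candidates are clonotypes whose CD8+CD4-FOXP3- member fraction is at
    least ``min_effector_frac``; candidates must carry a binding score.
    """
    if len(table) == 0:
        raise ValueError("no dominant clonotype: table is empty")
    cand = table
    if "frac_cd8_cd4neg_foxp3neg" in table.columns:
        cand = table[table["frac_cd8_cd4neg_foxp3neg"] >= min_effector_frac]
    if len(cand) == 0:
        raise ValueError(
            "no dominant clonotype: no candidate passes the effector-fraction filter"
        )
    if "mean_binding_score" not in cand.columns or cand["mean_binding_score"].isna().any():
        raise ValueError("candidates must carry a mean_binding_score")
    ranked = cand.sort_values(
        ["n_cells", "mean_binding_score"] + CLONOTYPE_KEY_FIELDS,
        ascending=[False, False] + [True] * 6,
        kind="mergesort",
    ).reset_index(drop=True)
    top = ranked.iloc[0]
    cols = ["n_cells", "mean_binding_score", "cdr3a", "cdr3b"]
    if "frac_cd8_cd4neg_foxp3neg" in ranked.columns:
        cols.append("frac_cd8_cd4neg_foxp3neg")
    return DominantSelection(
        key=tuple(top[f] for f in CLONOTYPE_KEY_FIELDS),
        n_cells=int(top["n_cells"]),
        mean_binding_score=float(top["mean_binding_score"]),
        cdr3a=top["cdr3a"],
        cdr3b=top["cdr3b"],
        member_cells=list(top["member_cells"]),
        top10=ranked.head(10)[cols].copy(),
    )
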