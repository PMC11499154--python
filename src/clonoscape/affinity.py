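"""Binding-score file dialect and a deterministic surrogate scorer.

The external TCR-peptide binding predictor is driven through CSV files:
an input file carrying CDR3 alpha/beta, peptide, MHC class, V/J genes,
T-cell type and a cell index, and an output file adding a score in
[0, 1].  The surrogate scorer stands in for the network so the pipeline
is testable offline: given a planted affinity it returns it (plus
clamped Gaussian noise), otherwise a deterministic hash-based
pseudo-score of (CDR3 beta, peptide).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BindingRecord",
    "ERGO_INPUT_COLUMNS",
    "write_ergo_input",
    "read_ergo_output",
    "surrogate_score",
]

#: Input column order of the predictor dialect; the trailing column carries
#: the single-cell index for later data-frame merging.
ERGO_INPUT_COLUMNS = [
    "TRA", "TRB", "Peptide", "MHC", "TRAV", "TRAJ", "TRBV", "TRBJ",
    "T-Cell-Type", "cell_index",
]

SCORE_COLUMN = "Score"


@dataclass(frozen=True)
class BindingRecord:
    cell_index: str
    cdr3a: str
    cdr3b: str
    peptide: str
    mhc_class: str = "MHC-I"
    va: str = ""
    ja: str = ""
    vb: str = ""
    jb: str = ""
    t_cell_type: str = "CD8"
    score: float | None = None

    def validate(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        if not self.cdr3b:
            raise ValueError("CDR3 beta is mandatory")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1] (got {self.score})")


def write_ergo_input(records: list[BindingRecord], path: str | Path) -> None:
    """Write the predictor input CSV (one row per record, fixed column order)."""
    for i, r in enumerate(records):
        if not r.cdr3b:
            raise ValueError(f"record {i}: CDR3 beta is mandatory")
        if not r.peptide:
            raise ValueError(f"record {i}: peptide must be non-empty")
    rows = [
        {
            "TRA": r.cdr3a, "TRB": r.cdr3b, "Peptide": r.peptide,
            "MHC": r.mhc_class, "TRAV": r.va, "TRAJ": r.ja,
            "TRBV": r.vb, "TRBJ": r.jb, "T-Cell-Type": r.t_cell_type,
            "cell_index": r.cell_index,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ERGO_INPUT_COLUMNS).to_csv(path, index=False)


def read_ergo_output(path: str | Path) -> list[BindingRecord]:
    """Read a scored predictor CSV back into records.

    The file must contain the input columns plus a ``Score`` column with
    numeric values in [0, 1] (boundaries inclusive).
    """
    df = pd.read_csv(path, dtype={"cell_index": str}, keep_default_na=False)
    missing = [c for c in ERGO_INPUT_COLUMNS + [SCORE_COLUMN] if c not in df.columns]
    if missing:
        raise ValueError(f"predictor output missing column(s): {missing}")
    scores = pd.to_numeric(df[SCORE_COLUMN], errors="coerce")
    if scores.isna().any():
        row = int(scores.index[scores.isna()][0])
        raise ValueError(f"non-numeric score at row {row}")
    bad = (scores < 0) | (scores > 1)
    if bad.any():
        row = int(scores.index[bad][0])
        raise ValueError(
            f"score outside [0, 1] at row {row}: {float(scores.iloc[row])}"
        )
    return [
        BindingRecord(
            cell_index=str(r["cell_index"]),
            cdr3a=r["TRA"], cdr3b=r["TRB"], peptide=r["Peptide"],
            mhc_class=r["MHC"], va=r["TRAV"], ja=r["TRAJ"],
            vb=r["TRBV"], jb=r["TRBJ"], t_cell_type=r["T-Cell-Type"],
            score=float(s),
        )
        for (_, r), s in zip(df.iterrows(), scores)
    ]


def surrogate_score(
    record: BindingRecord,
    truth: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> float:
    """Deterministic stand-in for the binding predictor; always in [0, 1].

    With a planted ``truth`` affinity the score is truth plus clamped
    Gaussian noise (noise seeded by ``seed`` and the record identity).
    Without one, a hash-based pseudo-score of (CDR3 beta, peptide).
    """
    digest = hashlib.sha256(
        f"{record.cdr3b}|{record.peptide}|{seed}".encode()
    ).digest()
    if truth is None:
        return int.from_bytes(digest[:8], "big") / float(2**64)
    if noise_sd == 0.0:
        return float(np.clip(truth, 0.0, 1.0))
    rng = np.random.default_rng(int.from_bytes(digest[:8], "big"))
    return float(np.clip(truth + rng.normal(0.0, noise_sd), 0.0, 1.0))


def score_records(
    records: list[BindingRecord],
    truth_of_cell: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BindingRecord]:
    """Score a batch with :func:`surrogate_score` (truth looked up per cell)."""
    out = []
    for r in records:
        truth = None if truth_of_cell is None else truth_of_cell.get(r.cell_index)
        out.append(replace(r, score=surrogate_score(r, truth, noise_sd, seed)))
    return out
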