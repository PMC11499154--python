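"""Molecule-level processing: UMI error correction, cell calling, demultiplexing.

Operates on a molecule table — a :class:`pandas.DataFrame` with columns
``cell_label``, ``umi``, ``feature``, ``reads`` and unique
``(cell_label, umi, feature)`` keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellCallResult",
    "DemuxResult",
    "DbecResult",
    "validate_molecule_table",
    "rsec_correct",
    "dbec_filter",
    "call_cells",
    "demultiplex",
]

MOLECULE_COLUMNS = ["cell_label", "umi", "feature", "reads"]


@dataclass
class CellCallResult:
    """Outcome of barcode-rank cell calling."""

    valid_labels: list[str]            # prefix of labels sorted by descending reads
    rank_curve: pd.Series              # total reads per label, descending
    inflection_rank: int | None        # == len(valid_labels) when a knee was found

    @property
    def n_valid(self) -> int:
        return len(self.valid_labels)


@dataclass
class DemuxResult:
    """Per-cell sample assignment and the per-tag noise thresholds used."""

    assignment: dict[str, str]         # cell -> sample id | "multiplet" | "undetermined"
    per_tag_noise: dict[str, float]

    def cells_of(self, sample: str) -> list[str]:
        return sorted(c for c, s in self.assignment.items() if s == sample)

    @property
    def n_multiplets(self) -> int:
        return sum(1 for s in self.assignment.values() if s == "multiplet")


@dataclass
class DbecResult:
    """Kept and removed molecules plus the per-feature decision."""

    kept: pd.DataFrame
    removed: pd.DataFrame
    status: dict[str, str] = field(default_factory=dict)  # feature -> "corrected"|"pass"

    def __iter__(self):
        # allows ``kept, removed = dbec_filter(...)``
        return iter((self.kept, self.removed))


def validate_molecule_table(molecules: pd.DataFrame) -> None:
    missing = [c for c in MOLECULE_COLUMNS if c not in molecules.columns]
    if missing:
        raise ValueError(f"molecule table missing columns: {missing}")
    if len(molecules) == 0:
        return
    if (molecules["reads"] < 1).any():
        raise ValueError("molecule table has reads < 1")
    lens = molecules["umi"].str.len()
    if lens.nunique() > 1:
        raise ValueError("UMIs of unequal length")
    if molecules.duplicated(["cell_label", "umi", "feature"]).any():
        raise ValueError("duplicate (cell_label, umi, feature) keys")


def _hamming1(a: str, b: str) -> bool:
    return sum(x != y for x, y in zip(a, b)) == 1


def _collapse_group(counts: dict[str, int]) -> dict[str, int]:
    """Recursive substitution-error collapse of one (cell, feature) group.

    A UMI ``u`` merges into a Hamming-distance-1 neighbour ``v`` when
    ``reads(v) >= 2 * reads(u) - 1``; among eligible parents the one with
    the most reads wins, ties broken by lexicographically smallest UMI.
    Equal-read pairs only merge toward the smaller UMI, which keeps the
    relation acyclic.  Applied until fixpoint; reads are conserved.
    """
    counts = dict(counts)
    changed = True
    while changed:
        changed = False
        for u in sorted(counts, key=lambda x: (counts[x], x)):
            if u not in counts:
                continue
            ru = counts[u]
            parents = [
                v
                for v, rv in counts.items()
                if v != u
                and rv >= 2 * ru - 1
                and (rv > ru or (rv == ru and v < u))
                and _hamming1(u, v)
            ]
            if parents:
                best = min(parents, key=lambda v: (-counts[v], v))
                counts[best] += ru
                del counts[u]
                changed = True
                break  # re-sort: the merge may enable new merges
    return counts


def _groups_with_h1_pairs(molecules: pd.DataFrame) -> np.ndarray:
    """Group codes of (cell_label, feature) groups containing at least one
    Hamming-distance-1 UMI pair.  Vectorized pre-filter: two UMIs at
    distance 1 share exactly one single-position-wildcarded key.
    """
    gid = pd.factorize(
        molecules["cell_label"].astype(str) + "\x00" + molecules["feature"].astype(str)
    )[0]
    L = len(molecules["umi"].iloc[0])
    u = molecules["umi"].to_numpy().astype(f"S{L}").view("S1").reshape(len(molecules), L)
    flagged: set[int] = set()
    for p in range(L):
        masked = u.copy()
        masked[:, p] = b"*"
        keys = pd.DataFrame({"g": gid, "m": masked.view(f"S{L}").ravel()})
        dup = keys.duplicated(keep=False).to_numpy()
        if dup.any():
            flagged.update(np.unique(gid[dup]).tolist())
    return np.isin(gid, sorted(flagged))


def rsec_correct(molecules: pd.DataFrame) -> pd.DataFrame:
    """Recursive substitution error correction over every (cell, feature) group.

    Total reads are conserved within each group; the number of distinct
    UMIs can only decrease.
    """
    validate_molecule_table(molecules)
    if len(molecules) == 0:
        return molecules.copy()
    needs_work = _groups_with_h1_pairs(molecules)
    passthrough = molecules.loc[~needs_work]
    todo = molecules.loc[needs_work]
    out_parts = [passthrough]
    if len(todo):
        merged_rows = []
        for (cell, feat), grp in todo.groupby(["cell_label", "feature"], sort=False):
            counts = _collapse_group(dict(zip(grp["umi"], grp["reads"])))
            for umi, reads in counts.items():
                merged_rows.append((cell, umi, feat, reads))
        out_parts.append(pd.DataFrame(merged_rows, columns=MOLECULE_COLUMNS))
    out = pd.concat(out_parts, ignore_index=True)
    out["reads"] = out["reads"].astype(np.int64)
    return out.sort_values(MOLECULE_COLUMNS[:3], kind="mergesort").reset_index(drop=True)


def _best_split(x: np.ndarray) -> tuple[float, float, float] | None:
    """Two-class split of values minimizing total within-class variance.

    Returns ``(low_mean, high_mean, threshold)`` of the best split, where
    ``threshold`` is the midpoint between the two boundary values, or
    ``None`` when no split exists (fewer than 2 values or all equal).
    The split index is found by exhaustive scan (Otsu-style on raw values).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return None
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    best = None
    best_sse = np.inf
    for i in range(1, n):  # low class = x[:i]
        if x[i - 1] == x[i]:
            continue  # threshold must separate distinct values
        nl, nh = i, n - i
        sl, sh = csum[i - 1], csum[-1] - csum[i - 1]
        ql, qh = csq[i - 1], csq[-1] - csq[i - 1]
        sse = (ql - sl * sl / nl) + (qh - sh * sh / nh)
        if sse < best_sse - 1e-12:
            best_sse = sse
            best = (sl / nl, sh / nh, (x[i - 1] + x[i]) / 2.0)
    return best


def dbec_filter(molecules: pd.DataFrame, margin: float = 1.0) -> DbecResult:
    """Distribution-based error correction on read depth per molecule.

    Per feature, log2 read depths are split into two classes by the
    exhaustive minimum within-class-variance threshold; when the class
    means are at least ``margin`` log2 units apart, the low class is
    removed as error molecules.  The feature's top molecule is never
    removed (it always sits in the high class).
    """
    validate_molecule_table(molecules)
    if len(molecules) == 0:
        empty = molecules.copy()
        return DbecResult(kept=empty, removed=empty.copy(), status={})
    status: dict[str, str] = {}
    keep_mask = np.ones(len(molecules), dtype=bool)
    logr = np.log2(molecules["reads"].to_numpy(dtype=float))
    for feat, idx in molecules.groupby("feature", sort=False).indices.items():
        split = _best_split(logr[idx])
        if split is None:
            status[feat] = "pass"
            continue
        low_mean, high_mean, cut = split
        if high_mean - low_mean >= margin:
            keep_mask[idx] = logr[idx] > cut
            status[feat] = "corrected"
        else:
            status[feat] = "pass"
    kept = molecules.loc[keep_mask].reset_index(drop=True)
    removed = molecules.loc[~keep_mask].reset_index(drop=True)
    return DbecResult(kept=kept, removed=removed, status=status)


def call_cells(
    molecules: pd.DataFrame,
    window: int = 5,
    tol: float = 0.01,
) -> CellCallResult:
    """Second-derivative cell calling on the barcode-rank curve.

    Labels are ranked by descending total reads.  The curve of
    (log10 rank, log10 cumulative read fraction) is resampled onto a
    uniform log-rank grid, smoothed by a centered moving average of
    ``window`` grid points, and the knee located at the grid point
    minimizing the discrete second derivative; the knee rank is then
    refined to the largest adjacent drop in log total reads within the
    matching rank window.  Labels ranked at or before the knee are valid.
    When the minimum second derivative exceeds ``-tol`` (no knee), every
    label is returned and ``inflection_rank`` is ``None``.
    """
    validate_molecule_table(molecules)
    totals = (
        molecules.groupby("cell_label")["reads"]
        .sum()
        .sort_values(ascending=False, kind="mergesort")
    )
    # deterministic tie handling: equal totals ordered by label
    totals = totals.iloc[
        np.lexsort((totals.index.to_numpy(), -totals.to_numpy()))
    ]
    n = len(totals)
    if n < 3:
        raise ValueError(f"cell calling needs >= 3 distinct cell labels (got {n})")
    t = totals.to_numpy(dtype=float)
    x = np.log10(np.arange(1, n + 1, dtype=float))
    y = np.log10(np.cumsum(t) / t.sum())
    xg = np.linspace(x[0], x[-1], n)
    dx = xg[1] - xg[0]
    yg = np.interp(xg, x, y)
    ys = pd.Series(yg).rolling(window, center=True, min_periods=1).mean().to_numpy()
    d2 = np.zeros(n)
    d2[1:-1] = (ys[2:] - 2.0 * ys[1:-1] + ys[:-2]) / (dx * dx)
    # exclude grid points whose smoothing window or difference stencil is
    # truncated at the curve ends (edge artifacts)
    w2 = max(1, window // 2)
    lo_g, hi_g = w2 + 1, n - 2 - w2
    if lo_g > hi_g or d2[lo_g : hi_g + 1].min() > -tol:
        return CellCallResult(
            valid_labels=list(totals.index), rank_curve=totals, inflection_rank=None
        )
    knee_x = xg[lo_g + int(np.argmin(d2[lo_g : hi_g + 1]))]
    # refine: largest log drop between adjacent ranks near the knee
    lo_r = max(0, int(np.floor(10 ** (knee_x - (w2 + 1) * dx))) - 1)
    hi_r = min(n - 2, int(np.ceil(10 ** (knee_x + (w2 + 1) * dx))) - 1)
    drops = np.log10(t[lo_r : hi_r + 1]) - np.log10(t[lo_r + 1 : hi_r + 2])
    knee = lo_r + int(np.argmax(drops))  # boundary between knee and knee+1
    valid = list(totals.index[: knee + 1])
    return CellCallResult(
        valid_labels=valid, rank_curve=totals, inflection_rank=knee + 1
    )


def demultiplex(
    tag_molecules: pd.DataFrame,
    valid_labels: set[str],
    thresholds: dict[str, float] | None = None,
) -> DemuxResult:
    """Assign each called cell to a sample tag, a multiplet, or undetermined.

    Per-tag noise threshold = mean + 3*SD of that tag's read counts over
    the cells where it is not the maximal tag.  A cell is assigned to the
    unique tag strictly exceeding its threshold; two or more such tags
    make a multiplet, zero make the cell undetermined.  Valid labels
    absent from ``tag_molecules`` are undetermined.
    """
    validate_molecule_table(tag_molecules)
    if not valid_labels:
        raise ValueError("valid_labels must be non-empty")
    tags = sorted(tag_molecules["feature"].unique())
    sample_of_tag = {t: _tag_to_sample(t) for t in tags}
    present = tag_molecules[tag_molecules["cell_label"].isin(valid_labels)]
    counts = (
        present.pivot_table(
            index="cell_label", columns="feature", values="reads",
            aggfunc="sum", fill_value=0,
        )
        .reindex(columns=tags, fill_value=0)
    )
    assignment: dict[str, str] = {
        c: "undetermined" for c in valid_labels if c not in counts.index
    }
    if len(counts) == 0:
        return DemuxResult(assignment=assignment, per_tag_noise={t: 0.0 for t in tags})
    mat = counts.to_numpy(dtype=float)
    argmax = mat.argmax(axis=1)
    if thresholds is None:
        thresholds = {}
        for j, tag in enumerate(tags):
            noise = mat[argmax != j, j]
            if len(noise) == 0:
                thresholds[tag] = 0.0
            elif len(noise) == 1:
                thresholds[tag] = float(noise[0])
            else:
                thresholds[tag] = float(noise.mean() + 3.0 * noise.std(ddof=1))
    thr = np.array([thresholds[t] for t in tags])
    above = mat > thr[None, :]
    n_above = above.sum(axis=1)
    for i, cell in enumerate(counts.index):
        if n_above[i] == 0:
            assignment[cell] = "undetermined"
        elif n_above[i] == 1:
            tag = tags[int(np.argmax(above[i]))]
            assignment[cell] = sample_of_tag[tag]
        else:
            assignment[cell] = "multiplet"
    return DemuxResult(assignment=assignment, per_tag_noise=thresholds)


def _tag_to_sample(tag: str) -> str:
    """Map ``SampleTagNN`` to sample id ``SN``; other names pass through."""
    if tag.startswith("SampleTag"):
        suffix = tag[len("SampleTag"):]
        if suffix.isdigit():
            return f"S{int(suffix)}"
    return tag
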