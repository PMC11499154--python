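"""LDH cytotoxicity statistics.

Percent cytotoxicity from optical densities, per-group donor summaries,
one-way ANOVA with Tukey HSD (Tukey-Kramer for unbalanced groups), and
the enrichment fold-change summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CytotoxicityPlate

__all__ = [
    "percent_cytotoxicity",
    "summarize_donors",
    "anova_tukey",
    "enrichment_fold_change",
    "AnovaTukeyResult",
]

DONOR_TABLE_COLUMNS = ["donor", "cell_line", "condition", "pct"]


def percent_cytotoxicity(plate: CytotoxicityPlate) -> float:
    """100 * (OD(effector+target) - OD(effector)) / (OD(max) - OD(spontaneous)).

    Replicate wells are averaged per condition before the formula is applied.
    """
    plate.validate()
    et = float(np.mean(plate.od_effector_plus_target))
    e = float(np.mean(plate.od_effector_only))
    mx = float(np.mean(plate.od_max_lysis))
    sp = float(np.mean(plate.od_spontaneous))
    denom = mx - sp
    if denom <= 0:
        raise ValueError(
            f"non-positive denominator: mean max-lysis OD ({mx}) must exceed "
            f"mean spontaneous OD ({sp})"
        )
    return 100.0 * (et - e) / denom


def _validate_donor_table(table: pd.DataFrame) -> None:
    missing = [c for c in DONOR_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"donor table missing column(s): {missing}")
    if table.duplicated(["donor", "cell_line", "condition"]).any():
        raise ValueError("donor table has duplicate (donor, cell_line, condition) rows")


def summarize_donors(table: pd.DataFrame) -> pd.DataFrame:
    """Per (cell_line, condition) group: n, mean and sample SD (ddof=1).

    ``mean`` / ``sd`` are rounded to 2 decimals for reporting; the
    unrounded values are kept as ``mean_raw`` / ``sd_raw``.  Groups with a
    single donor get no SD and are flagged.
    """
    _validate_donor_table(table)
    rows = []
    for (line, cond), grp in table.groupby(["cell_line", "condition"], sort=True):
        vals = grp["pct"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n >= 2 else np.nan
        rows.append(
            {
                "cell_line": line,
                "condition": cond,
                "n": n,
                "mean": round(mean, 2),
                "sd": round(sd, 2) if n >= 2 else np.nan,
                "mean_raw": mean,
                "sd_raw": sd,
                "sd_defined": n >= 2,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    anova_p: float
    comparisons: pd.DataFrame  # group_a, group_b, mean_diff, p_adj

    def p_adj(self, group_a: str, group_b: str) -> float:
        m = self.comparisons
        hit = m[
            ((m["group_a"] == group_a) & (m["group_b"] == group_b))
            | ((m["group_a"] == group_b) & (m["group_b"] == group_a))
        ]
        if len(hit) != 1:
            raise KeyError(f"no comparison {group_a} vs {group_b}")
        return float(hit["p_adj"].iloc[0])


def anova_tukey(table: pd.DataFrame) -> AnovaTukeyResult:
    """One-way ANOVA across (cell_line x condition) groups + Tukey HSD pairs.

    Unbalanced group sizes use the Tukey-Kramer generalization.  Adjusted
    p-values come from the studentized-range distribution.
    """
    _validate_donor_table(table)
    groups: dict[str, np.ndarray] = {}
    for (line, cond), grp in table.groupby(["cell_line", "condition"], sort=True):
        groups[f"{line} {cond}"] = grp["pct"].to_numpy(dtype=float)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    samples = [groups[n] for n in names]
    f_stat, p = stats.f_oneway(*samples)
    tk = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(tk.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        anova_p=float(p),
        comparisons=pd.DataFrame(rows),
    )


def enrichment_fold_change(
    pre_pct: list[float] | np.ndarray, post_pct: list[float] | np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-donor fold change post/pre, plus mean and sample SD of the FCs."""
    pre = np.asarray(pre_pct, dtype=float)
    post = np.asarray(post_pct, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post lists must have equal length")
    if (pre <= 0).any():
        raise ValueError("fold change undefined: pre-values must be strictly positive")
    fc = post / pre
    sd = float(fc.std(ddof=1)) if len(fc) >= 2 else float("nan")
    return fc, float(fc.mean()), sd
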