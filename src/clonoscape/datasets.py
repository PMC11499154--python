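"""Bundled reference datasets.

``reference_donor_cytotoxicity`` returns the published per-donor LDH
percent-cytotoxicity measurements of seven healthy donors whose T-cells
were transduced either with the candidate-TCR lentivirus (``LV``) or a
vehicle lentivirus (``Veh``) and co-cultured with three tumor cell lines
(antigen-high SK-MEL-5, antigen-low HCT-116, antigen-negative
MDA-MB-231).  Decimal commas of the source were normalized to points.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_donor_cytotoxicity"]

_ROWS = {
    ("SK-MEL-5", "LV"): [68.46, 71.02, 65.48, 62.43, 74.02, 85.48, 81.67],
    ("SK-MEL-5", "Veh"): [51.72, 38.04, 18.80, 36.11, 16.05, 29.26, 33.56],
    ("HCT-116", "LV"): [33.75, 44.16, 44.52, 29.52, 29.92, 57.69, 50.50],
    ("HCT-116", "Veh"): [33.75, 44.52, 29.92, 50.50, 18.93, 33.62, 39.55],
    ("MDA-MB-231", "LV"): [42.33, 42.50, 40.06, 15.97, 8.18, 16.93, 28.48],
    ("MDA-MB-231", "Veh"): [36.45, 20.65, 6.16, 15.75, 21.13, 17.29, 17.96],
}


def reference_donor_cytotoxicity() -> pd.DataFrame:
    """Long-format donor table: donor, cell_line, condition, pct."""
    rows = []
    for (line, cond), values in _ROWS.items():
        for donor, pct in enumerate(values, start=1):
            rows.append(
                {"donor": f"D{donor}", "cell_line": line, "condition": cond, "pct": pct}
            )
    return pd.DataFrame(rows)
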