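"""Packaged worked-example count table for the three carrier groups.

Counts (never percentages) for 2,889 African American subjects split into
normal diploids, carriers of shorter upstream hemizygous deletions, and
carriers of the larger hemizygous deletion at the 3p26.1 locus.  Derived
percentages are always recomputed from the counts.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_table2_fixture", "GROUPS"]

GROUPS = ["diploid", "short_deletion", "large_deletion"]

_COUNTS = {
    #                     diploid  short  large
    "n":                  (2772,    40,    77),
    "male":               (1567,    24,    57),
    "female":             (1205,    16,    20),
    "current_smoker":     (2230,    35,    60),
    "ex_smoker":          (542,      5,    17),
    "copd_case":          (2000,    27,    59),
    "copd_control":       (565,      8,    14),
    "copd_unknown":       (207,      5,     4),
}


def load_table2_fixture() -> pd.DataFrame:
    """Grouped count table: rows are characteristics, columns carrier groups."""
    df = pd.DataFrame(_COUNTS, index=GROUPS).T
    df.index.name = "characteristic"
    return df


def percent(df: pd.DataFrame, row: str, group: str) -> float:
    """Percentage of a characteristic within one carrier group."""
    return 100.0 * df.loc[row, group] / df.loc["n", group]


def percent_overall(df: pd.DataFrame, row: str) -> float:
    """Percentage of a characteristic across the whole cohort."""
    return 100.0 * df.loc[row].sum() / df.loc["n"].sum()
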