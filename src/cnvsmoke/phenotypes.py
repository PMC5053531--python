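"""Deterministic phenotype transforms applied before association testing.

Pack-years of smoking are heavily right-skewed, so the scan analyzes
log10(pack-years).  Average cigarettes per day is recoded into seven
ordinal categories of width 10 (right-closed: 1 for <=10 per day, 2 for
(10, 20], ..., 7 for >60) and analyzed as a numeric 1-7 score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["log10_pack_years", "recode_cpd", "transform_phenotypes"]


def log10_pack_years(pack_years):
    """Base-10 logarithm of pack-years; rejects non-positive input."""
    x = np.asarray(pack_years, dtype=float)
    if np.any(x <= 0):
        raise ValueError("pack_years must be positive")
    out = np.log10(x)
    return float(out) if np.isscalar(pack_years) or out.ndim == 0 else out


def recode_cpd(cigs_per_day):
    """Ordinal 1-7 category for average cigarettes smoked per day.

    Category k covers (10(k-1), 10k] for k = 1..6 (boundaries closed on the
    right, so exactly 10 per day is category 1); anything above 60 is
    category 7.
    """
    x = np.asarray(cigs_per_day, dtype=float)
    if np.any(x <= 0):
        raise ValueError("cigs_per_day must be positive")
    cat = np.minimum(np.ceil(x / 10.0), 7).astype(int)
    return int(cat) if np.isscalar(cigs_per_day) or cat.ndim == 0 else cat


def transform_phenotypes(subjects: pd.DataFrame) -> pd.DataFrame:
    """Append transformed phenotype columns to a phenotype table.

    Adds ``log10_pack_years`` (from ``pack_years``) and ``cpd_category``
    (from ``cigs_per_day``); the input frame is not modified.
    """
    out = subjects.copy()
    out["log10_pack_years"] = log10_pack_years(out["pack_years"].to_numpy())
    out["cpd_category"] = recode_cpd(out["cigs_per_day"].to_numpy())
    return out
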