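"""Phenotype encodings and covariate selection.

Bra sizes are coded on an 8-point integer scale (AA=0 ... F=6, with G and
larger cups collapsed to 7).  The five-level word-association menstrual
pain scale is mapped onto the 11-point Numeric Rating Scale (NRS) as
1->0, 2->1, 3->2, 4->5, 5->10, which linearises the relationship between
reported severity and pain-medicine use.  Covariate selection follows the
screening rule used for the association models: principal components are
always included, while Age and BMI enter only when univariately associated
with the phenotype at P < 0.05.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BUST_CODES",
    "PAIN_TO_NRS",
    "encode_bust_size",
    "map_pain_to_nrs",
    "select_covariates",
    "encode_phenotype_table",
]

BUST_CODES = {"AA": 0, "A": 1, "B": 2, "C": 3, "D": 4, "E": 5, "F": 6, "G": 7}
# Cup letters above G collapse into the top code.
_ABOVE_G = tuple("HIJKLMNOPQRSTUVWXYZ")

PAIN_TO_NRS = {1: 0, 2: 1, 3: 2, 4: 5, 5: 10}


def encode_bust_size(label: str) -> int:
    """Integer code 0..7 for a bra cup-size label (>= G collapses to 7)."""
    key = str(label).strip().upper()
    if key in BUST_CODES:
        return BUST_CODES[key]
    if len(key) == 1 and key in _ABOVE_G:
        return 7
    raise ValueError(f"unrecognized bust-size label {label!r}")


def map_pain_to_nrs(level: int) -> int:
    """Map a 5-level pain severity response onto the 0-10 NRS scale."""
    lvl = int(level)
    if lvl != level or lvl not in PAIN_TO_NRS:
        raise ValueError(f"pain level must be an integer in 1..5, got {level!r}")
    return PAIN_TO_NRS[lvl]


def select_covariates(
    phenotype: Sequence[float] | pd.Series,
    candidates: Mapping[str, Sequence[float]],
    always: Sequence[str] = ("PC1", "PC2"),
    alpha: float = 0.05,
) -> list[str]:
    """Screen optional covariates by univariate regression on the phenotype.

    Returns the always-included set plus every candidate whose simple
    regression against the phenotype reaches P < ``alpha``.  Constant
    candidates are excluded with a warning.  The screen is invariant to
    affine rescaling of a candidate.
    """
    y = np.asarray(phenotype, dtype=float)
    chosen = list(always)
    for name, values in candidates.items():
        x = np.asarray(values, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"candidate {name!r} not aligned to phenotype")
        if np.ptp(x) == 0:
            warnings.warn(f"candidate covariate {name!r} is constant; excluded")
            continue
        res = stats.linregress(x, y)
        if res.pvalue < alpha:
            chosen.append(name)
    return chosen


def encode_phenotype_table(
    raw: pd.DataFrame,
    bust_column: str | None = None,
    pain_column: str | None = None,
) -> pd.DataFrame:
    """Apply the standard encodings to a raw phenotype table.

    Adds ``<col>_code`` (bust, 0..7) and ``<col>_nrs`` (pain) columns;
    missing values propagate as NA (complete-case handling is per-trait,
    downstream).
    """
    out = raw.copy()
    if bust_column is not None:
        out[f"{bust_column}_code"] = [
            encode_bust_size(v) if pd.notna(v) else pd.NA for v in raw[bust_column]
        ]
    if pain_column is not None:
        out[f"{pain_column}_nrs"] = [
            map_pain_to_nrs(v) if pd.notna(v) else pd.NA for v in raw[pain_column]
        ]
    return out
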