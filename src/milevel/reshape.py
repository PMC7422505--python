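"""Layout adapters: wide/long pivots and dummy-indicator cluster encoding.

Two pragmatic devices let single- and two-level imputation engines handle
three-level data: arranging the repeated measures in wide format (one row
per child, one column per measure per wave) and representing cluster
membership by I-1 binary dummy indicators (DIs) instead of random effects.
Both transforms are pure, deterministic and lossless, including any
missingness mask.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datagen import EXPOSURE_WAVE_LABELS, OUTCOME_WAVE_LABELS

__all__ = [
    "to_wide",
    "to_long",
    "add_dummy_indicators",
    "add_ses_dummies",
    "WIDE_VALUE_COLUMNS",
]

_CHILD_COLUMNS = ["school_id", "child_id", "age_w1", "sex", "ses_w1", "naplan_z_w1"]

#: Wide-layout repeated-measure columns, in wave order.
WIDE_VALUE_COLUMNS = (
    [f"depression_w{k}" for k in EXPOSURE_WAVE_LABELS]
    + [f"sdq_w{k}" for k in EXPOSURE_WAVE_LABELS]
    + [f"naplan_z_w{k}" for k in OUTCOME_WAVE_LABELS]
)


def to_wide(data: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long cohort table to one row per child.

    Repeated measures become wave-suffixed columns (``depression_w2/4/6``,
    ``sdq_w2/4/6``, ``naplan_z_w3/5/7``, matching the cohort wave labels).
    Missing entries stay missing in their wave-specific column.  Any
    ``r_depression`` indicator is dropped (it is recoverable from the NaN
    pattern).
    """
    counts = data.groupby("child_id")["wave"].agg(["size", "nunique"])
    if (counts["size"] != counts["nunique"]).any():
        bad = counts.index[counts["size"] != counts["nunique"]].tolist()
        raise ValueError(f"duplicated (child, wave) rows for children {bad[:5]}")
    if (counts["size"] != 3).any():
        bad = counts.index[counts["size"] != 3].tolist()
        raise ValueError(
            f"wide layout needs the full 3-occasion structure; children "
            f"{bad[:5]} have fewer rows"
        )

    head = data.drop_duplicates("child_id").set_index("child_id")[
        [c for c in _CHILD_COLUMNS if c != "child_id"]
    ]
    wide = head.copy()
    piv = data.pivot(index="child_id", columns="wave")
    for var, labels in (
        ("depression", EXPOSURE_WAVE_LABELS),
        ("sdq", EXPOSURE_WAVE_LABELS),
        ("naplan_z", OUTCOME_WAVE_LABELS),
    ):
        for occ, lab in enumerate(labels, start=1):
            wide[f"{var}_w{lab}"] = piv[(var, occ)]
    return wide.reset_index()[_CHILD_COLUMNS + WIDE_VALUE_COLUMNS]


def to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_wide`; restores the long layout and, when the
    exposure has missing entries, the ``r_depression`` indicator."""
    frames = []
    for occ, (ke, ko) in enumerate(
        zip(EXPOSURE_WAVE_LABELS, OUTCOME_WAVE_LABELS), start=1
    ):
        f = wide[_CHILD_COLUMNS].copy()
        f["wave"] = occ
        f["depression"] = wide[f"depression_w{ke}"].to_numpy()
        f["sdq"] = wide[f"sdq_w{ke}"].to_numpy()
        f["naplan_z"] = wide[f"naplan_z_w{ko}"].to_numpy()
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    long = long.sort_values(["child_id", "wave"], kind="stable").reset_index(drop=True)
    long = long[
        ["school_id", "child_id", "wave", "age_w1", "sex", "ses_w1",
         "naplan_z_w1", "depression", "sdq", "naplan_z"]
    ]
    if long["depression"].isna().any():
        long["r_depression"] = long["depression"].notna().astype(int)
    return long


def add_dummy_indicators(
    data: pd.DataFrame, cluster_col: str = "school_id"
) -> tuple[pd.DataFrame, list[str]]:
    """Append I-1 binary indicator columns for I clusters.

    The reference cluster is the smallest cluster id and is encoded as all
    zeros.  Returns the augmented table and the indicator column names
    (``<cluster_col>_di_<id>`` in ascending id order).
    """
    ids = np.sort(data[cluster_col].unique())
    if ids.size < 2:
        raise ValueError(
            f"dummy-indicator encoding needs at least 2 clusters; "
            f"{cluster_col} has {ids.size}"
        )
    out = data.copy()
    di_cols = []
    vals = data[cluster_col].to_numpy()
    for cid in ids[1:]:  # ids[0] is the all-zero reference
        col = f"{cluster_col}_di_{cid}"
        out[col] = (vals == cid).astype(float)
        di_cols.append(col)
    return out, di_cols


def add_ses_dummies(data: pd.DataFrame, ses_col: str = "ses_w1"
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Expand the 5-level SES quintile into indicator columns ``ses_2`` ..
    ``ses_5`` (quintile 1 as reference), for use in imputation models."""
    out = data.copy()
    cols = []
    vals = data[ses_col].to_numpy()
    for a in range(2, 6):
        col = f"ses_{a}"
        out[col] = (vals == a).astype(float)
        cols.append(col)
    return out, cols
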