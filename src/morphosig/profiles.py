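"""Profile-table conventions.

A profile table is a pandas DataFrame whose metadata columns carry the
``Metadata_`` prefix (plate, well, clone, resistance status, batch,
incubation time, cell count, ...) and whose remaining columns are named
numeric morphological features. Tables exist at two levels: ``cell``
(one row per segmented cell) and ``well`` (one row per plate well,
median-aggregated).
"""

from __future__ import annotations

import pandas as pd

METADATA_PREFIX = "Metadata_"

#: canonical platemap columns (un-prefixed, as written to platemap CSVs)
PLATEMAP_COLUMNS = [
    "plate_id",
    "well_id",
    "clone_id",
    "resistance_status",
    "treatment",
    "incubation_time_h",
    "batch",
]

WELL_KEY = [METADATA_PREFIX + "plate_id", METADATA_PREFIX + "well_id"]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of the feature (non-metadata) columns, in table order."""
    return [c for c in df.columns if not c.startswith(METADATA_PREFIX)]


def metadata_columns(df: pd.DataFrame) -> list[str]:
    """Names of the metadata columns, in table order."""
    return [c for c in df.columns if c.startswith(METADATA_PREFIX)]


def feature_matrix(df: pd.DataFrame):
    """Feature block as a float ndarray (wells/cells x features)."""
    return df[feature_columns(df)].to_numpy(dtype=float)


def check_feature_columns_numeric(df: pd.DataFrame) -> None:
    bad = [
        c
        for c in feature_columns(df)
        if not pd.api.types.is_numeric_dtype(df[c])
    ]
    if bad:
        raise TypeError(f"non-numeric feature columns: {bad}")


def check_unique_wells(df: pd.DataFrame) -> None:
    dup = df.duplicated(subset=WELL_KEY)
    if dup.any():
        pairs = df.loc[dup, WELL_KEY].to_records(index=False).tolist()
        raise ValueError(f"duplicate (plate_id, well_id) rows: {pairs}")
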