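"""Image-based profiling pipeline: aggregate, annotate, normalize, select.

The four stages mirror the standard well-profile workflow for
high-content screens: median aggregation of single cells into
well-level profiles, platemap annotation, per-plate z-score
normalization, and a five-rule feature selection (blocklist, missing
values, low variance, extreme outliers, high pairwise correlation)
computed jointly across all plates of an analytical dataset.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .profiles import (
    METADATA_PREFIX,
    PLATEMAP_COLUMNS,
    WELL_KEY,
    check_feature_columns_numeric,
    check_unique_wells,
    feature_columns,
)

__all__ = [
    "FeatureSelectionConfig",
    "aggregate_wells",
    "annotate",
    "normalize",
    "select_features",
]

logger = logging.getLogger(__name__)

#: selection rules in the order they are applied / attributed
SELECTION_RULES = ("blocklist", "missing", "low_variance", "outlier", "correlation")


@dataclass
class FeatureSelectionConfig:
    correlation_threshold: float = 0.9
    outlier_sd_threshold: float = 15.0
    low_variance_unique_ratio: float = 0.95
    low_variance_epsilon: float = 1e-12
    blocklist: tuple[str, ...] = ()
    drop_missing: bool = True

    def validate(self) -> None:
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ValueError(
                f"correlation_threshold must be in (0, 1], got "
                f"{self.correlation_threshold}"
            )
        if self.outlier_sd_threshold <= 0:
            raise ValueError("outlier_sd_threshold must be > 0")
        if not 0.0 < self.low_variance_unique_ratio <= 1.0:
            raise ValueError("low_variance_unique_ratio must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSelectionConfig":
        d = dict(d)
        if "blocklist" in d and d["blocklist"] is not None:
            d["blocklist"] = tuple(d["blocklist"])
        return cls(**d)


def aggregate_wells(cells: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregate single cells into one profile per (plate, well).

    Each feature becomes the per-well median over that well's cells
    (missing cell values are ignored; a feature missing in every cell
    of a well stays missing). A ``Metadata_cell_count`` column records
    how many cells were aggregated. Metadata constant within a well is
    carried through; conflicting metadata raises an integrity error.
    Wells with zero cells cannot appear (they have no rows); callers
    tracking expected wells should compare against their platemap.
    """
    if cells.empty:
        raise ValueError("cell table is empty")
    check_feature_columns_numeric(cells)
    feats = feature_columns(cells)
    meta = [c for c in cells.columns if c.startswith(METADATA_PREFIX)]
    carried = [c for c in meta if c not in WELL_KEY]

    grouped = cells.groupby(WELL_KEY, sort=True)
    for col in carried:
        n_distinct = grouped[col].nunique(dropna=False)
        bad = n_distinct[n_distinct > 1]
        if len(bad):
            raise ValueError(
                f"metadata column {col!r} is not constant within wells: "
                f"{bad.index.tolist()}"
            )
    out = grouped[feats].median()
    out[METADATA_PREFIX + "cell_count"] = grouped.size()
    if carried:
        out = grouped[carried].first().join(out)
    out = out.reset_index()
    meta_cols = [c for c in out.columns if c.startswith(METADATA_PREFIX)]
    return out[meta_cols + feats]


def annotate(wells: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    """Join platemap annotations onto well-level profiles.

    Platemap columns gain the ``Metadata_`` prefix; row count and order
    are unchanged. Errors on duplicate platemap entries and on profile
    wells absent from the platemap (listing the offending wells).
    """
    missing_cols = [c for c in ("plate_id", "well_id") if c not in platemap]
    if missing_cols:
        raise ValueError(f"platemap lacks required columns: {missing_cols}")
    dup = platemap.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        pairs = platemap.loc[dup, ["plate_id", "well_id"]]
        raise ValueError(
            "platemap has duplicated (plate_id, well_id) entries: "
            f"{pairs.to_records(index=False).tolist()}"
        )
    pm = platemap.rename(columns=lambda c: METADATA_PREFIX + c)
    # metadata already on the profiles wins only for the join key
    overlap = [
        c for c in pm.columns if c in wells.columns and c not in WELL_KEY
    ]
    merged = wells.drop(columns=overlap).merge(
        pm, on=WELL_KEY, how="left", validate="many_to_one", indicator=True
    )
    absent = merged["_merge"] == "left_only"
    if absent.any():
        pairs = merged.loc[absent, WELL_KEY].to_records(index=False).tolist()
        raise ValueError(f"profile wells absent from platemap: {pairs}")
    merged = merged.drop(columns="_merge")
    feats = feature_columns(merged)
    meta_cols = [c for c in merged.columns if c.startswith(METADATA_PREFIX)]
    return merged[meta_cols + feats]


def normalize(wells: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-plate z-score: (value - plate mean) / plate SD per feature.

    Uses the population SD (``ddof=0``) by default. Features with zero
    SD on a plate are set to missing on that plate so the missing-value
    rule removes them downstream. A plate with a single well has no
    defined spread and raises.
    """
    check_unique_wells(wells)
    check_feature_columns_numeric(wells)
    feats = feature_columns(wells)
    plate_col = METADATA_PREFIX + "plate_id"
    if plate_col not in wells:
        raise ValueError("normalize requires a Metadata_plate_id column")
    out = wells.copy()
    for plate, sub in wells.groupby(plate_col, sort=False):
        if len(sub) < 2:
            raise ValueError(
                f"plate {plate!r} has a single well: plate SD undefined"
            )
        X = sub[feats].to_numpy(dtype=float)
        mu = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=ddof)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - mu) / sd
        Z[:, sd == 0] = np.nan
        out.loc[sub.index, feats] = Z
    return out


def _read_blocklist(patterns) -> tuple[str, ...]:
    return tuple(patterns)


def load_blocklist(path) -> tuple[str, ...]:
    """Plain-text blocklist: one feature-name pattern per line, # comments."""
    with open(path) as fh:
        return tuple(
            line.strip()
            for line in fh
            if line.strip() and not line.lstrip().startswith("#")
        )


def select_features(
    wells: pd.DataFrame, config: FeatureSelectionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the five selection rules jointly across all plates.

    Rules run in a fixed order — blocklist, missing values, low
    variance, outliers, high correlation — and each dropped feature is
    attributed to exactly one rule in the returned report
    (columns: feature, rule, statistic).

    The outlier rule re-standardizes each surviving feature over the
    whole analytical dataset and drops it if any |z| exceeds the
    threshold. The correlation rule repeatedly takes the most
    correlated remaining pair above the threshold and drops the member
    with the larger mean absolute correlation to all other features
    (ties by feature name).
    """
    config = config or FeatureSelectionConfig()
    config.validate()
    check_feature_columns_numeric(wells)
    feats = feature_columns(wells)
    if not feats:
        raise ValueError("no feature columns present")
    report_rows: list[dict] = []
    surviving = list(feats)

    def drop(feature: str, rule: str, statistic: float | str) -> None:
        surviving.remove(feature)
        report_rows.append(
            {"feature": feature, "rule": rule, "statistic": statistic}
        )

    # 1. blocklist
    for f in list(surviving):
        hit = next(
            (p for p in config.blocklist if fnmatch.fnmatch(f, p)), None
        )
        if hit is not None:
            drop(f, "blocklist", hit)

    X = wells[surviving]

    # 2. missing values
    if config.drop_missing:
        n_missing = X.isna().sum()
        for f in list(surviving):
            if n_missing[f] > 0:
                drop(f, "missing", int(n_missing[f]))

    # 3. low variance: near-constant by top-value frequency or absolute variance
    for f in list(surviving):
        col = wells[f]
        top_ratio = col.value_counts(normalize=True).iloc[0]
        var = float(col.var(ddof=0))
        if top_ratio > config.low_variance_unique_ratio:
            drop(f, "low_variance", float(top_ratio))
        elif var < config.low_variance_epsilon:
            drop(f, "low_variance", var)

    # 4. outliers, measured dataset-wide on the (normalized) values
    for f in list(surviving):
        col = wells[f].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            continue
        zmax = float(np.abs((col - col.mean()) / sd).max())
        if zmax > config.outlier_sd_threshold:
            drop(f, "outlier", zmax)

    # 5. pairwise correlation
    if len(surviving) >= 2:
        corr = wells[surviving].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        while True:
            if corr.empty:
                break
            peak = float(corr.to_numpy().max())
            if peak <= config.correlation_threshold:
                break
            # most correlated pair; ties resolved lexicographically
            stacked = corr.stack()
            pairs = stacked[np.isclose(stacked, peak)].index.tolist()
            a, b = sorted(sorted(p) for p in pairs)[0]
            mean_abs = corr.mean()
            if mean_abs[a] > mean_abs[b]:
                victim = a
            elif mean_abs[b] > mean_abs[a]:
                victim = b
            else:
                victim = max(a, b)
            drop(victim, "correlation", peak)
            corr = corr.drop(index=victim, columns=victim)

    if not surviving:
        raise ValueError("feature selection removed every feature")
    logger.info(
        "feature selection: %d -> %d features", len(feats), len(surviving)
    )
    report = pd.DataFrame(report_rows, columns=["feature", "rule", "statistic"])
    meta_cols = [c for c in wells.columns if c.startswith(METADATA_PREFIX)]
    return wells[meta_cols + surviving], report
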