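"""Table readers/writers shared by the CLI and pipeline.

Profiles and platemaps travel as UTF-8 CSV with a header row; columnar
(parquet) copies are written alongside large tables for fast reload.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .profiles import PLATEMAP_COLUMNS


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


def read_platemap(path: str | Path) -> pd.DataFrame:
    pm = read_table(path)
    missing = [c for c in PLATEMAP_COLUMNS if c not in pm.columns]
    if missing:
        raise ValueError(f"platemap {path} lacks columns: {missing}")
    return pm
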