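"""Occurrence-record CSV I/O (columns: species, lon, lat)."""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["species", "lon", "lat"]


def read_occurrences(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns {missing}")
    return df[_COLUMNS].copy()


def write_occurrences(df: pd.DataFrame, path: str) -> None:
    df[_COLUMNS].to_csv(path, index=False)
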