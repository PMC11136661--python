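"""BED (0-based half-open) readers/writers for tracts, ROH and windows."""

from __future__ import annotations

import pandas as pd

_CORE = ["chrom", "start", "end"]


def read_bed(path: str, extra_columns: list[str] | None = None) -> pd.DataFrame:
    names = _CORE + (extra_columns or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = _CORE + [c for c in df.columns if c not in _CORE]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
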