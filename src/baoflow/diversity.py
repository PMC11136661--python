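"""Windowed heterozygosity and runs of homozygosity (ROH).

Genome-wide heterozygosity (GWH) is the fraction of callable sites that
are heterozygous, computed per tiling window and aggregated per
chromosome and genome-wide.  ROH are maximal runs of consecutive
low-heterozygosity windows; long runs (> 2 Mb) indicate recent
inbreeding, short runs older inbreeding.

ROH are called from observed per-window heterozygosity against an
explicit threshold (default: 0.25 x the genome-wide median window het).
This windowed-observed-het rule is a deliberate, documented stand-in
for likelihood-based per-window mutation-rate fitting; at low diversity
the observed het converges to the per-site theta it proxies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iokit.genotypes import MISSING, GenotypeMatrix

LONG_ROH_BP = 2_000_000
SHORT_ROH_BP = 500_000


def windowed_het(matrix: GenotypeMatrix, species: str, w: int = 100_000) -> pd.DataFrame:
    """Per-window heterozygosity profile for one species.

    Columns: chrom, start, end (0-based half-open), n_callable, n_het,
    het (NaN where no site is callable).
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    geno = matrix.column(species)
    records = []
    for chrom in matrix.chromosomes:
        m = matrix.chrom == chrom
        g = geno[m]
        pos0 = matrix.pos[m] - 1
        n_windows = int(np.ceil((pos0.max() + 1) / w)) if m.any() else 0
        win = pos0 // w
        callable_ = g != MISSING
        for k in range(n_windows):
            in_w = win == k
            n_callable = int((in_w & callable_).sum())
            n_het = int((in_w & (g == 1)).sum())
            het = n_het / n_callable if n_callable else np.nan
            records.append((chrom, k * w, (k + 1) * w, n_callable, n_het, het))
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_callable", "n_het", "het"]
    )


def genome_het(profile: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-chromosome and genome-wide theta-hat = sum(n_het)/sum(n_callable)."""
    if profile["n_callable"].sum() == 0:
        raise ValueError("no callable windows")
    per_chrom = (
        profile.groupby("chrom", sort=False)[["n_het", "n_callable"]].sum().reset_index()
    )
    per_chrom["theta"] = per_chrom["n_het"] / per_chrom["n_callable"]
    genome = float(profile["n_het"].sum() / profile["n_callable"].sum())
    return per_chrom, genome


def _classify(length: int) -> str:
    if length > LONG_ROH_BP:
        return "long"
    if length >= SHORT_ROH_BP:
        return "intermediate"
    return "short"


def call_roh(
    profile: pd.DataFrame,
    het_threshold: float | None = None,
    min_len: int = 100_000,
    merge_gap: int = 1,
) -> pd.DataFrame:
    """Call ROH segments from a heterozygosity profile.

    A window is "low" when its het is callable and <= ``het_threshold``
    (default 0.25 x the median het over callable windows).  Maximal runs
    of low windows separated by at most ``merge_gap`` non-low windows
    are merged; merged runs shorter than ``min_len`` bp are dropped.
    Returns chrom, start, end, length, class with
    short < 500 kb <= intermediate <= 2 Mb < long.
    """
    if min_len <= 0 or merge_gap < 0:
        raise ValueError("min_len must be > 0 and merge_gap >= 0")
    if het_threshold is None:
        med = float(np.nanmedian(profile["het"]))
        het_threshold = 0.25 * med
    segments = []
    for chrom, grp in profile.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        low = (grp["het"] <= het_threshold) & grp["het"].notna()
        idx = np.flatnonzero(low.to_numpy())
        if len(idx) == 0:
            continue
        # group runs allowing up to merge_gap intervening windows
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            if i - prev - 1 <= merge_gap:
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            start = int(grp.loc[a, "start"])
            end = int(grp.loc[b, "end"])
            length = end - start
            if length >= min_len:
                segments.append((chrom, start, end, length, _classify(length)))
    return pd.DataFrame(segments, columns=["chrom", "start", "end", "length", "class"])


@dataclass
class RohSummary:
    counts: pd.Series  # per class
    total_length: pd.Series  # per class, bp
    top_longest: pd.DataFrame  # length-sorted listing (default top 100)


def roh_summary(segments: pd.DataFrame, top_n: int = 100) -> RohSummary:
    """Per-class counts and total lengths plus the top-N longest ROH."""
    classes = ["short", "intermediate", "long"]
    if segments.empty:
        zero = pd.Series(0, index=classes)
        return RohSummary(zero, zero.astype(float), segments.copy())
    counts = segments["class"].value_counts().reindex(classes, fill_value=0)
    total = segments.groupby("class")["length"].sum().reindex(classes, fill_value=0)
    top = segments.sort_values("length", ascending=False).head(top_n).reset_index(drop=True)
    return RohSummary(counts, total, top)
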