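"""Quartet site-pattern statistics and their genomic localization.

For a quartet (((P1,P2),P3),O) with per-species derived-allele
frequencies p1..p4, the frequency-weighted site-pattern sums are

    ABBA = sum (1-p1) p2 p3 (1-p4),    BABA = sum p1 (1-p2) p3 (1-p4)

and Patterson's D = (ABBA-BABA)/(ABBA+BABA).  Significance comes from a
delete-one block jackknife over contiguous blocks of equal numbers of
used sites.  The f4 admixture ratio divides the ABBA-BABA numerator by
the same numerator with the donor P3 substituted for P2 (the
"homozygous-proxy" denominator), estimating the admixed fraction.  The
f-branch statistic maps these signals onto branches of a species tree.
A 100-kb tiling window scan plus the interval-length analysis of the
gaps between significant windows date introgression qualitatively:
recent tracts give clustered windows with short (often 0 bp) gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .iokit.genotypes import MISSING, GenotypeMatrix
from .iokit.trees import SpeciesTree

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000
DEFAULT_BLOCKS = 20
DEFAULT_MIN_SITES = 20


@dataclass
class SitePatternCounts:
    """Frequency-weighted ABBA/BABA sums with per-block partials."""

    abba: float
    baba: float
    n_used: int
    block_abba: np.ndarray
    block_baba: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.block_abba)


@dataclass
class DResult:
    d: float
    z: float
    se: float
    f4ratio: float
    n_blocks: int
    n_used: int


def _frequencies(matrix: GenotypeMatrix, quartet) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequencies (n_kept, 4) after dropping
    sites with missing genotypes or a heterozygous outgroup, polarized
    so the outgroup carries the ancestral (0) allele."""
    if len(set(quartet)) != 4:
        raise ValueError(f"quartet species must be distinct, got {quartet}")
    cols = np.stack([matrix.column(s) for s in quartet], axis=1)
    keep = (cols != MISSING).all(axis=1)
    keep &= cols[:, 3] != 1  # a single outgroup cannot polarize its het sites
    p = cols[keep].astype(np.float64) / 2.0
    flip = p[:, 3] > 0.5
    p[flip] = 1.0 - p[flip]
    return p, keep


def _weighted_sums(p: np.ndarray, duplicate_p3: bool = False) -> tuple[np.ndarray, np.ndarray]:
    p2 = p[:, 2] if duplicate_p3 else p[:, 1]
    abba = (1.0 - p[:, 0]) * p2 * p[:, 2] * (1.0 - p[:, 3])
    baba = p[:, 0] * (1.0 - p2) * p[:, 2] * (1.0 - p[:, 3])
    return abba, baba


def site_pattern_sums(
    matrix: GenotypeMatrix, quartet, n_blocks: int = DEFAULT_BLOCKS
) -> SitePatternCounts:
    """ABBA/BABA sums for ``quartet = (P1, P2, P3, O)`` with per-block
    partial sums over contiguous blocks of equal numbers of informative
    sites (sites carrying nonzero ABBA or BABA weight)."""
    p, _ = _frequencies(matrix, quartet)
    abba, baba = _weighted_sums(p)
    informative = (abba + baba) > 0
    abba, baba = abba[informative], baba[informative]
    n_used = int(informative.sum())
    n_blocks_eff = max(1, min(n_blocks, n_used)) if n_used else 1
    block_abba = np.array([b.sum() for b in np.array_split(abba, n_blocks_eff)])
    block_baba = np.array([b.sum() for b in np.array_split(baba, n_blocks_eff)])
    return SitePatternCounts(float(abba.sum()), float(baba.sum()), n_used, block_abba, block_baba)


def patterson_d(counts: SitePatternCounts) -> float:
    """(ABBA - BABA) / (ABBA + BABA); NaN when the test is unperformable."""
    denom = counts.abba + counts.baba
    if denom <= 0:
        return float("nan")
    return (counts.abba - counts.baba) / denom


def block_jackknife(counts: SitePatternCounts) -> tuple[float, float]:
    """Delete-one block jackknife of D.  Returns (z, se); z is NaN when
    se = 0 or fewer than 2 usable blocks exist."""
    ba, bb = counts.block_abba, counts.block_baba
    nonempty = (ba + bb) > 0
    if nonempty.sum() < 2:
        return float("nan"), float("nan")
    d = patterson_d(counts)
    A, B = counts.abba, counts.baba
    with np.errstate(invalid="ignore", divide="ignore"):
        d_del = ((A - ba) - (B - bb)) / ((A - ba) + (B - bb))
    d_del = d_del[np.isfinite(d_del)]
    m = len(d_del)
    if m < 2:
        return float("nan"), float("nan")
    se = float(np.sqrt((m - 1) / m * np.sum((d_del - d_del.mean()) ** 2)))
    if se == 0.0 or not np.isfinite(d):
        return float("nan"), se
    return d / se, se


def f4_admixture_ratio(matrix: GenotypeMatrix, quartet) -> float:
    """f4-ratio admixed-fraction estimate for ``(P1, P2, P3, O)``.

    The denominator duplicates P3 in the P2 slot; both numerator and
    denominator are evaluated on the same polarized site set.  NaN when
    the denominator is not positive.
    """
    p, _ = _frequencies(matrix, quartet)
    abba_n, baba_n = _weighted_sums(p)
    abba_d, baba_d = _weighted_sums(p, duplicate_p3=True)
    num = abba_n.sum() - baba_n.sum()
    den = abba_d.sum() - baba_d.sum()
    if den <= 0:
        logger.info("f4 ratio unperformable: denominator %.4g <= 0", den)
        return float("nan")
    return float(num / den)


def dstat(matrix: GenotypeMatrix, quartet, n_blocks: int = DEFAULT_BLOCKS) -> DResult:
    """Patterson's D with jackknife Z and the f4 admixture ratio."""
    counts = site_pattern_sums(matrix, quartet, n_blocks=n_blocks)
    d = patterson_d(counts)
    z, se = block_jackknife(counts)
    f4 = f4_admixture_ratio(matrix, quartet)
    return DResult(d, z, se, f4, counts.n_blocks, counts.n_used)


def f_branch(tree: SpeciesTree, matrix: GenotypeMatrix, outgroup: str) -> pd.DataFrame:
    """f-branch matrix: rows are tree branches, columns candidate donors.

    f_b(C) = median over B in descendants(b) of the minimum over A in
    descendants(sister(b)) of f4_admixture_ratio(A, B, C, O).  Cells
    with no valid (A, B, C) combination are NaN; negative estimates are
    floored at 0 (logged).
    """
    leaves = tree.leaf_labels
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    donors = [s for s in leaves if s != outgroup]
    rows = {}
    n_floored = 0
    for b in tree.branch_ids:
        desc_b = set(tree.descendants(b))
        if outgroup in desc_b:
            continue
        sis = tree.sister(b)
        if sis is None:
            continue
        desc_s = set(tree.descendants(sis))
        if outgroup in desc_s:
            continue
        row = {}
        for c in donors:
            if c in desc_b or c in desc_s:
                row[c] = float("nan")
                continue
            medians = []
            for B in sorted(desc_b):
                f_vals = [
                    f4_admixture_ratio(matrix, (A, B, c, outgroup)) for A in sorted(desc_s)
                ]
                f_vals = [v for v in f_vals if np.isfinite(v)]
                if f_vals:
                    medians.append(min(f_vals))
            if not medians:
                row[c] = float("nan")
            else:
                fb = float(np.median(medians))
                if fb < 0:
                    n_floored += 1
                    fb = 0.0
                row[c] = fb
        rows[b] = row
    if n_floored:
        logger.info("f_branch: floored %d negative cells at 0", n_floored)
    return pd.DataFrame.from_dict(rows, orient="index", columns=donors)


def window_scan(
    matrix: GenotypeMatrix,
    quartet,
    w: int = DEFAULT_WINDOW,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Non-overlapping tiling-window D scan.

    Returns a frame with columns chrom, start, end (0-based half-open),
    d, n_used, masked; ``n_used`` counts informative sites (nonzero
    ABBA or BABA weight) and windows with fewer than ``min_sites`` of
    them are masked and carry NaN d.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    records = []
    for chrom in matrix.chromosomes:
        sub = matrix.subset_chrom(chrom)
        p, keep = _frequencies(sub, quartet)
        abba, baba = _weighted_sums(p)
        pos0 = sub.pos[keep] - 1
        informative = (abba + baba) > 0
        n_windows = int(np.ceil(sub.pos.max() / w)) if sub.n_sites else 0
        win = pos0 // w
        for k in range(n_windows):
            in_w = win == k
            n_used = int((in_w & informative).sum())
            if n_used < min_sites:
                records.append((chrom, k * w, (k + 1) * w, np.nan, n_used, True))
                continue
            a, b = abba[in_w].sum(), baba[in_w].sum()
            d = (a - b) / (a + b) if (a + b) > 0 else np.nan
            records.append((chrom, k * w, (k + 1) * w, d, n_used, bool(np.isnan(d))))
    return pd.DataFrame(records, columns=["chrom", "start", "end", "d", "n_used", "masked"])


def classify_windows(scan: pd.DataFrame, q: float) -> dict[str, pd.DataFrame]:
    """Top-``q`` fraction of unmasked windows by |d|, split by sign.

    ``ceil(q * N)`` windows are selected; ties at the cutoff are broken
    by (chrom, start) ascending.  Returns {"positive": ..., "negative": ...}.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    unmasked = scan.loc[~scan["masked"]].copy()
    if unmasked.empty:
        raise ValueError("all windows are masked")
    unmasked["_absd"] = unmasked["d"].abs()
    ranked = unmasked.sort_values(
        ["_absd", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    )
    k = int(np.ceil(q * len(unmasked)))
    selected = ranked.head(k).drop(columns="_absd")
    return {
        "positive": selected.loc[selected["d"] >= 0].sort_values(["chrom", "start"]),
        "negative": selected.loc[selected["d"] < 0].sort_values(["chrom", "start"]),
    }


@dataclass
class IntervalAnalysis:
    """Gap-length comparison between significant and random windows."""

    gaps: np.ndarray
    control_gaps: np.ndarray
    u: float
    p: float
    n_control: int
    seed: int
    window_starts: pd.DataFrame = field(repr=False, default=None)


def _gaps_between(windows: pd.DataFrame) -> np.ndarray:
    """Per-chromosome bp gaps between adjacent windows (0 if adjacent)."""
    out = []
    for _chrom, grp in windows.groupby("chrom", sort=True):
        g = grp.sort_values("start")
        out.extend((g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1]).tolist())
    return np.asarray(out, dtype=np.int64)


def interval_analysis(
    scan: pd.DataFrame,
    significant: pd.DataFrame,
    n_control: int = 100,
    seed: int = 0,
) -> IntervalAnalysis:
    """Compare gap lengths of significant windows against the gaps of
    ``n_control`` random unmasked windows.

    One-sided Mann-Whitney U (normal approximation with continuity and
    tie correction): alternative = significant-set gaps are smaller.
    """
    if len(significant) < 2:
        raise ValueError("interval analysis needs >= 2 significant windows")
    unmasked = scan.loc[~scan["masked"]]
    rng = np.random.default_rng(seed)
    n_take = min(n_control, len(unmasked))
    if n_take < n_control:
        logger.info("interval_analysis: only %d unmasked windows for control", n_take)
    control = unmasked.iloc[np.sort(rng.choice(len(unmasked), size=n_take, replace=False))]
    gaps = _gaps_between(significant)
    control_gaps = _gaps_between(control)
    if len(gaps) == 0 or len(control_gaps) == 0:
        raise ValueError("no gaps available on either side of the comparison")
    res = stats.mannwhitneyu(
        gaps, control_gaps, alternative="less", method="asymptotic", use_continuity=True
    )
    return IntervalAnalysis(
        gaps, control_gaps, float(res.statistic), float(res.pvalue), n_control, seed, significant
    )
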