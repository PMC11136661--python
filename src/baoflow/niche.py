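"""Ecological valence, habitat superimposition, niche overlap and
land-area reconstruction.

The valence (ecological amplitude) of a species is its min-max
tolerance interval per environmental variable, read off the values at
its occurrence records.  Superimposing the per-variable in-range
layers gives an overlap-count raster; cells where every selected
variable is in range form the predicted habitat.  Niche overlap between
species is Schoener's D = 1 - 0.5 * sum|z1 - z2| on normalized
occurrence densities over a PCA niche space, with permutation
(equivalency) and background-randomization (similarity) tests.  Island
land area under a sea level s counts cells with elevation > s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .iokit.rasters import EnvRaster

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- variables


def select_variables(env_table: pd.DataFrame, r_max: float = 0.8):
    """Greedy decorrelation: drop the variable with the largest mean
    absolute Pearson correlation until all pairwise |r| < ``r_max``.

    Returns (selected variable names, correlation matrix of the input).
    Constant variables (undefined r) are dropped first and logged.
    """
    numeric = env_table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2 or len(numeric) < 3:
        raise ValueError("need >= 2 numeric variables and >= 3 rows")
    constant = [c for c in numeric.columns if numeric[c].nunique() <= 1]
    if constant:
        logger.info("select_variables: dropping constant variables %s", constant)
    work = numeric.drop(columns=constant)
    corr_full = numeric.corr()
    keep = list(work.columns)
    while len(keep) > 1:
        sub = work[keep].corr().abs()
        np.fill_diagonal(sub.values, 0.0)
        if sub.values.max() < r_max:
            break
        keep.remove(sub.mean().idxmax())
    return keep, corr_full


def extract_env(rasters: dict[str, EnvRaster], occurrences: pd.DataFrame) -> pd.DataFrame:
    """Nearest-cell extraction of every raster at each occurrence.

    Points off the raster extent or on nodata cells are excluded (and
    counted in the log).  Returns species + one column per variable.
    """
    rows = []
    n_dropped = 0
    for _, rec in occurrences.iterrows():
        vals = {"species": rec["species"]}
        ok = True
        for var, rast in rasters.items():
            try:
                v = rast.value_at(rec["lon"], rec["lat"])
            except IndexError:
                ok = False
                break
            if np.isnan(v):
                ok = False
                break
            vals[var] = v
        if ok:
            rows.append(vals)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("extract_env: excluded %d points (off-raster or nodata)", n_dropped)
    if not rows:
        raise ValueError("all occurrence points fell off the rasters")
    return pd.DataFrame(rows)


def ecological_valence(env_table: pd.DataFrame) -> pd.DataFrame:
    """Per species x variable (min, max) tolerance table.

    Tidy output: species, variable, min, max.
    """
    variables = [c for c in env_table.columns if c != "species"]
    rows = []
    for sp, grp in env_table.groupby("species", sort=True):
        for var in variables:
            rows.append((sp, var, float(grp[var].min()), float(grp[var].max())))
    return pd.DataFrame(rows, columns=["species", "variable", "min", "max"])


# ------------------------------------------------------------------ habitat


@dataclass
class HabitatMap:
    counts: EnvRaster  # overlap count per cell (0..n_vars)
    habitat: EnvRaster  # 1 where every variable is in range, else 0
    n_vars: int


def superimpose_habitat(
    rasters: dict[str, EnvRaster], valence: pd.DataFrame, species: str
) -> HabitatMap:
    """Overlay the per-variable in-range layers for one species.

    In-range tests are inclusive of the valence endpoints; the habitat
    mask keeps cells at the maximal overlap count (all variables in
    range).  Nodata propagates.
    """
    v = valence.loc[valence["species"] == species]
    ranges = {r["variable"]: (r["min"], r["max"]) for _, r in v.iterrows()}
    missing = [var for var in rasters if var not in ranges]
    if missing:
        raise ValueError(f"valence for {species!r} missing variables {missing}")
    first = next(iter(rasters.values()))
    count = np.zeros(first.values.shape)
    nodata = np.zeros(first.values.shape, dtype=bool)
    for var, rast in rasters.items():
        lo, hi = ranges[var]
        vals = rast.values
        nodata |= np.isnan(vals)
        count += ((vals >= lo) & (vals <= hi)).astype(float)
    n_vars = len(rasters)
    count[nodata] = np.nan
    habitat = np.where(nodata, np.nan, (count == n_vars).astype(float))
    mk = lambda vals: EnvRaster(vals, first.xll, first.yll, first.cellsize, first.nodata)
    return HabitatMap(mk(count), mk(habitat), n_vars)


# -------------------------------------------------------------- niche space


@dataclass
class NicheSpace:
    """PCA niche space fitted on background (land) cells."""

    scaler: object
    pca: object
    background_scores: np.ndarray  # (n_cells, 2)
    variables: list[str]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        b = self.background_scores
        return b[:, 0].min(), b[:, 0].max(), b[:, 1].min(), b[:, 1].max()

    def project(self, env_table: pd.DataFrame) -> np.ndarray:
        x = self.scaler.transform(env_table[self.variables].to_numpy())
        return self.pca.transform(x)[:, :2]


def pca_niche_space(rasters: dict[str, EnvRaster], variables: list[str]) -> NicheSpace:
    """Standardize the selected layers over land cells and fit a 2-D PCA."""
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    if len(variables) < 2:
        raise ValueError("need >= 2 variables for a niche space")
    stack = np.stack([rasters[v].values.ravel() for v in variables], axis=1)
    land = ~np.isnan(stack).any(axis=1)
    x = stack[land]
    if len(x) < len(variables):
        raise ValueError("fewer land cells than variables")
    scaler = StandardScaler().fit(x)
    pca = PCA(n_components=2).fit(scaler.transform(x))
    scores = pca.transform(scaler.transform(x))[:, :2]
    return NicheSpace(scaler, pca, scores, list(variables))


@dataclass
class DensityGrid:
    z: np.ndarray  # (R, R), sums to 1
    extent: tuple[float, float, float, float]
    bandwidth: float | None


def niche_density(
    scores: np.ndarray,
    extent: tuple[float, float, float, float],
    R: int = 100,
    bandwidth=None,
) -> DensityGrid:
    """Normalized Gaussian-KDE occurrence density on an R x R grid over
    the niche-space extent (Scott plug-in bandwidth by default)."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 1:
        raise ValueError("need at least one point")
    x0, x1, y0, y1 = extent
    xs = np.linspace(x0, x1, R)
    ys = np.linspace(y0, y1, R)
    xx, yy = np.meshgrid(xs, ys)
    try:
        if len(scores) < 2:
            raise np.linalg.LinAlgError("degenerate")
        kde = stats.gaussian_kde(scores.T, bw_method=bandwidth)
        z = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(R, R)
        bw = float(kde.factor)
    except np.linalg.LinAlgError:
        # zero-variance cloud: all mass in the containing cell(s)
        z, _, _ = np.histogram2d(
            scores[:, 1], scores[:, 0], bins=R, range=[[y0, y1], [x0, x1]]
        )
        bw = None
    total = z.sum()
    if total <= 0:
        raise ValueError("density has no mass on the grid")
    return DensityGrid(z / total, extent, bw)


def schoener_d(z1, z2) -> float:
    """D = 1 - 0.5 * sum|z1 - z2| over cells; 0 = no overlap, 1 = complete."""
    a = z1.z if isinstance(z1, DensityGrid) else np.asarray(z1, dtype=float)
    b = z2.z if isinstance(z2, DensityGrid) else np.asarray(z2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    # clip away float rounding so the analytic endpoints are exact
    return float(min(1.0, max(0.0, 1.0 - 0.5 * np.abs(a - b).sum())))


# ------------------------------------------------------------ overlap tests


def _overlap_from_scores(s1, s2, extent, R, bandwidth) -> float:
    return schoener_d(
        niche_density(s1, extent, R=R, bandwidth=bandwidth),
        niche_density(s2, extent, R=R, bandwidth=bandwidth),
    )


def equivalency_test(
    scores1: np.ndarray,
    scores2: np.ndarray,
    space: NicheSpace,
    n_reps: int = 1000,
    seed: int = 0,
    R: int = 100,
    bandwidth=None,
) -> tuple[float, float]:
    """Niche equivalency by pooled label permutation.

    Returns (observed D, p) with p = (#{D_null <= D_obs} + 1)/(n_reps + 1);
    a low p means the niches overlap less than label-equivalent ones.
    """
    if len(scores1) < 2 or len(scores2) < 2:
        raise ValueError("each occurrence set needs >= 2 points")
    extent = space.extent
    d_obs = _overlap_from_scores(scores1, scores2, extent, R, bandwidth)
    pool = np.vstack([scores1, scores2])
    n1 = len(scores1)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_reps):
        perm = rng.permutation(len(pool))
        d_null = _overlap_from_scores(pool[perm[:n1]], pool[perm[n1:]], extent, R, bandwidth)
        if d_null <= d_obs:
            n_le += 1
    return d_obs, (n_le + 1) / (n_reps + 1)


def similarity_test(
    scores1: np.ndarray,
    scores2: np.ndarray,
    space: NicheSpace,
    n_reps: int = 1000,
    seed: int = 0,
    direction: int = 2,
    R: int = 100,
    bandwidth=None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Niche similarity against random background niches.

    The ``direction``-specified species (1 or 2) is replaced by points
    drawn uniformly from the background cells in each replicate.
    Returns (observed D, p).  With the default ``alternative``
    "greater", p = (#{D_null >= D_obs} + 1)/(n_reps + 1): a small p
    means the niches overlap more than random background niches do
    (niche conservatism); "less" counts D_null <= D_obs instead.
    """
    if direction not in (1, 2):
        raise ValueError("direction must be 1 or 2")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    extent = space.extent
    d_obs = _overlap_from_scores(scores1, scores2, extent, R, bandwidth)
    bg = space.background_scores
    n = len(scores1) if direction == 1 else len(scores2)
    replace = n > len(bg)
    if replace:
        logger.info("similarity_test: background smaller than sample; sampling with replacement")
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_reps):
        rand = bg[rng.choice(len(bg), size=n, replace=replace)]
        pair = (rand, scores2) if direction == 1 else (scores1, rand)
        d_null = _overlap_from_scores(*pair, extent, R, bandwidth)
        if (d_null >= d_obs) if alternative == "greater" else (d_null <= d_obs):
            n_le += 1
    return d_obs, (n_le + 1) / (n_reps + 1)


@dataclass
class OverlapResult:
    schoener_d: float
    p_equivalency: float
    p_similarity_12: float
    p_similarity_21: float
    n_reps: int
    seed: int


def overlap_tests(
    scores1,
    scores2,
    space: NicheSpace,
    n_reps: int = 1000,
    seed: int = 0,
    R: int = 100,
    bandwidth=None,
) -> OverlapResult:
    """Schoener's D with the equivalency test and both similarity directions."""
    d_obs, p_eq = equivalency_test(scores1, scores2, space, n_reps, seed, R, bandwidth)
    _, p12 = similarity_test(scores1, scores2, space, n_reps, seed + 1, 1, R, bandwidth)
    _, p21 = similarity_test(scores1, scores2, space, n_reps, seed + 2, 2, R, bandwidth)
    return OverlapResult(d_obs, p_eq, p12, p21, n_reps, seed)


# ---------------------------------------------------------------- sea level


def land_area(elevation: EnvRaster, sea_level: float, baseline: float = 0.0) -> dict:
    """Land area at one sea level: cells with elevation strictly > s.

    Area is in cellsize^2 units; percent change is relative to the area
    at the ``baseline`` level.
    """
    vals = elevation.values
    n_land = int(np.nansum(vals > sea_level))
    n_base = int(np.nansum(vals > baseline))
    area = n_land * elevation.cellsize**2
    pct = 100.0 * (n_land - n_base) / n_base if n_base else float("nan")
    return {
        "sea_level": float(sea_level),
        "n_cells": n_land,
        "area": area,
        "pct_change": pct,
    }


def area_curve(elevation: EnvRaster, sea_levels, baseline: float = 0.0) -> pd.DataFrame:
    """Land-area curve over a sweep of sea levels (e.g. a GMSL/RSL series)."""
    return pd.DataFrame([land_area(elevation, s, baseline) for s in np.asarray(sea_levels)])
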