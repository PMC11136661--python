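"""Synthetic data with the statistical structure the analyses assume.

Four generators cover the pipeline end to end without any downloads:

* quartet / multi-species genotypes under the multispecies coalescent
  with an optional introgression pulse of known donor, recipient and
  proportion (the truth the f4-ratio and f-branch statistics estimate);
* whole "genomes" of such sites with introgression confined to known
  tracts, for the window scan and interval-length timing analysis;
* single-species genomes with planted low-heterozygosity tracts, for
  heterozygosity profiling and ROH recovery;
* an island-shaped elevation grid plus smooth bioclim-like layers and
  occurrences sampled from known per-variable tolerance ranges, for the
  valence/habitat/overlap/sea-level analyses.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._msc import SpeciesTreeEncoding, run_msc
from .iokit.genotypes import GenotypeMatrix
from .iokit.rasters import EnvRaster

QUARTET_SPECIES = ["P1", "P2", "P3", "O"]


@dataclass(frozen=True)
class QuartetModel:
    """Coalescent model for a quartet (((P1,P2),P3),O).

    Times are in coalescent units before present.  ``gamma`` is the
    per-site introgression probability at ``t_m`` (forward-time
    direction donor -> recipient; the default P3 -> P2 inflates ABBA).
    ``pulse_mode`` "join" replaces the recipient's haplotype by the
    donor lineage (f4-ratio recovers gamma); "migrate" moves the
    recipient lineage into the donor's population instead.
    """

    t1: float = 1.0
    t2: float = 1.5
    t3: float = 4.0
    gamma: float = 0.0
    t_m: float = 0.1
    direction: tuple[str, str] = ("P3", "P2")
    pulse_mode: str = "join"

    def __post_init__(self) -> None:
        if not (0 < self.t_m < self.t1 < self.t2 < self.t3):
            raise ValueError("require 0 < t_m < t1 < t2 < t3")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.direction[0] not in QUARTET_SPECIES or self.direction[1] not in QUARTET_SPECIES:
            raise ValueError(f"direction species must be in {QUARTET_SPECIES}")

    def encoding(self) -> SpeciesTreeEncoding:
        # nodes: 0..3 leaves; 4 = (P1,P2) @ t1; 5 = (+P3) @ t2; 6 = root @ t3
        child1 = np.array([-1, -1, -1, -1, 0, 4, 5], dtype=np.int64)
        child2 = np.array([-1, -1, -1, -1, 1, 2, 3], dtype=np.int64)
        height = np.array([0, 0, 0, 0, self.t1, self.t2, self.t3], dtype=float)
        return SpeciesTreeEncoding(QUARTET_SPECIES, child1, child2, height)


def simulate_quartet_sites(
    model: QuartetModel,
    n_sites: int,
    seed: int,
    return_topologies: bool = False,
    chrom: str = "chr1",
):
    """Simulate independent biallelic sites for the quartet.

    With ``return_topologies`` also return the per-site gene-tree
    topology restricted to (P1,P2,P3): 0 = P1+P2 sister (concordant),
    1 = P2+P3, 2 = P1+P3.
    """
    enc = model.encoding()
    geno, topo = run_msc(
        enc,
        n_sites,
        model.gamma,
        seed,
        t_m=model.t_m,
        donor=model.direction[0],
        recipient=model.direction[1],
        trio=(0, 1, 2) if return_topologies else None,
        mode=model.pulse_mode,
    )
    matrix = GenotypeMatrix(
        QUARTET_SPECIES,
        np.array([chrom] * n_sites, dtype=object),
        np.arange(1, n_sites + 1),
        geno,
    )
    return (matrix, topo) if return_topologies else matrix


def simulate_tree_sites(
    newick: str,
    n_sites: int,
    seed: int,
    gamma: float = 0.0,
    t_m: float = -1.0,
    donor: str | None = None,
    recipient: str | None = None,
    chrom: str = "chr1",
    pulse_mode: str = "join",
) -> GenotypeMatrix:
    """Simulate sites on an arbitrary ultrametric species tree.

    Branch lengths are coalescent units; an optional pulse acts at
    ``t_m`` with the given donor/recipient and mode (see
    :class:`QuartetModel`).
    """
    enc = SpeciesTreeEncoding.from_newick(newick)
    geno, _ = run_msc(
        enc, n_sites, gamma, seed, t_m=t_m, donor=donor, recipient=recipient, mode=pulse_mode
    )
    return GenotypeMatrix(
        enc.labels, np.array([chrom] * n_sites, dtype=object), np.arange(1, n_sites + 1), geno
    )


@dataclass
class GenomeSimConfig:
    """A multi-chromosome quartet genome with introgression tracts.

    ``tracts`` rows are (chrom, start, end, gamma_local) with 0-based
    half-open coordinates; sites outside tracts use ``model.gamma``.
    ``site_density`` is segregating sites per bp.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 5_000_000 for i in range(1, 11)}
    )
    site_density: float = 1e-3
    tracts: list[tuple[str, int, int, float]] = field(default_factory=list)
    model: QuartetModel = field(default_factory=QuartetModel)
    seed: int = 0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _g in self.tracts:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"tract chromosome {chrom!r} not in chrom_lengths")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"tract ({chrom}, {start}, {end}) outside chromosome bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping tracts on {chrom}")


def simulate_genome_with_tracts(config: GenomeSimConfig):
    """Returns ``(GenotypeMatrix, truth)``; truth is a BED-like frame of
    the seeded tracts (chrom, start, end, gamma)."""
    rng = np.random.default_rng(config.seed)
    enc = config.model.encoding()
    chroms_all, pos_all, geno_all = [], [], []
    for i, (chrom, length) in enumerate(config.chrom_lengths.items()):
        n_sites = int(round(length * config.site_density))
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))  # 0-based
        gamma = np.full(n_sites, config.model.gamma)
        for tchrom, start, end, g_local in config.tracts:
            if tchrom == chrom:
                gamma[(pos0 >= start) & (pos0 < end)] = g_local
        geno, _ = run_msc(
            enc,
            n_sites,
            gamma,
            int(rng.integers(2**31 - 1)),
            t_m=config.model.t_m,
            donor=config.model.direction[0],
            recipient=config.model.direction[1],
            mode=config.model.pulse_mode,
        )
        chroms_all.append(np.array([chrom] * n_sites, dtype=object))
        pos_all.append(pos0 + 1)
        geno_all.append(geno)
    matrix = GenotypeMatrix(
        QUARTET_SPECIES,
        np.concatenate(chroms_all),
        np.concatenate(pos_all),
        np.concatenate(geno_all),
    )
    truth = pd.DataFrame(config.tracts, columns=["chrom", "start", "end", "gamma"])
    return matrix, truth


def simulate_het_genome(
    chrom_lengths: dict[str, int],
    base_het: float,
    roh_tracts: list[tuple[str, int, int]],
    seed: int,
    site_density: float = 1e-2,
    het_in_factor: float = 0.02,
    species: str = "S1",
):
    """Single-species genome with planted low-heterozygosity tracts.

    Outside tracts each site is heterozygous with probability
    ``base_het``; inside, with ``het_in_factor * base_het``.  Returns
    ``(GenotypeMatrix, truth)`` with truth the tract BED frame.
    """
    if not (0.0 <= base_het <= 1.0):
        raise ValueError("base_het must be in [0, 1]")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in roh_tracts:
        ivs.setdefault(chrom, []).append((start, end))
    for chrom, lst in ivs.items():
        lst.sort()
        for (s1, e1), (s2, _e2) in zip(lst, lst[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping ROH tracts on {chrom}")
    rng = np.random.default_rng(seed)
    chroms_all, pos_all, geno_all = [], [], []
    for chrom, length in chrom_lengths.items():
        n_sites = int(round(length * site_density))
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))
        p_het = np.full(n_sites, base_het)
        for start, end in ivs.get(chrom, []):
            p_het[(pos0 >= start) & (pos0 < end)] = het_in_factor * base_het
        is_het = rng.random(n_sites) < p_het
        hom = rng.choice(np.array([0, 2], dtype=np.int8), size=n_sites)
        geno = np.where(is_het, np.int8(1), hom).astype(np.int8)
        chroms_all.append(np.array([chrom] * n_sites, dtype=object))
        pos_all.append(pos0 + 1)
        geno_all.append(geno[:, None])
    matrix = GenotypeMatrix(
        [species],
        np.concatenate(chroms_all),
        np.concatenate(pos_all),
        np.concatenate(geno_all),
    )
    truth = pd.DataFrame(roh_tracts, columns=["chrom", "start", "end"])
    return matrix, truth


@dataclass
class IslandConfig:
    """A conical island with smooth environmental fields.

    The elevation is a radial cone (peak ``peak_elev`` at the grid
    centre, shore at ``radius`` cells) plus optional smooth noise; the
    cone continues below 0 offshore (bathymetry), so lowering the sea
    level exposes new land.  Each environmental variable is a smooth
    random field rescaled to ``env_ranges[var]`` over present-day land
    (elevation > 0); sea cells are nodata there.  ``species_ranges``
    gives each synthetic species' true tolerance interval per variable.
    """

    nrows: int = 100
    ncols: int = 100
    cellsize: float = 0.02
    xll: float = 44.0
    yll: float = -20.0
    peak_elev: float = 1500.0
    radius_frac: float = 0.85  # island radius as fraction of half min-dimension
    noise_amp: float = 0.0  # elevation noise amplitude (m)
    noise_smooth: float = 6.0  # gaussian smoothing sigma (cells)
    env_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bio1": (12.0, 28.0),
            "bio4": (20.0, 70.0),
            "bio12": (300.0, 2500.0),
        }
    )
    species_ranges: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "sp1": {"bio1": (18.0, 26.0), "bio4": (25.0, 50.0), "bio12": (400.0, 1500.0)}
        }
    )
    seed: int = 0

    @property
    def radius_cells(self) -> float:
        return self.radius_frac * (min(self.nrows, self.ncols) / 2.0)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.min()) / (f.max() - f.min() + 1e-300)


def simulate_island_rasters(config: IslandConfig):
    """Returns ``(elevation, env)`` — an elevation EnvRaster carrying
    both topography and offshore bathymetry (sea = values <= 0) and a
    dict of bioclim-like EnvRasters masked to present-day land."""
    rng = np.random.default_rng(config.seed)
    rows, cols = np.mgrid[0 : config.nrows, 0 : config.ncols]
    cy, cx = (config.nrows - 1) / 2.0, (config.ncols - 1) / 2.0
    r = np.hypot(rows - cy, cols - cx)
    elev = config.peak_elev * (1.0 - r / config.radius_cells)
    if config.noise_amp > 0:
        elev = elev + config.noise_amp * (
            2.0 * _smooth_field(rng, elev.shape, config.noise_smooth) - 1.0
        )
    land = elev > 0.0
    elevation = EnvRaster(elev, config.xll, config.yll, config.cellsize)
    env: dict[str, EnvRaster] = {}
    for var, (lo, hi) in config.env_ranges.items():
        f = _smooth_field(rng, elev.shape, config.noise_smooth)
        vals = np.where(land, lo + (hi - lo) * f, np.nan)
        env[var] = EnvRaster(vals, config.xll, config.yll, config.cellsize)
    return elevation, env


def sample_occurrences(
    rasters: dict[str, EnvRaster],
    true_ranges: dict[str, tuple[float, float]],
    n: int,
    seed: int,
    species: str = "sp1",
) -> pd.DataFrame:
    """Occurrences drawn uniformly among cells where every variable lies
    inside its true tolerance range (positions uniform within the cell)."""
    first = next(iter(rasters.values()))
    suitable = np.ones(first.values.shape, dtype=bool)
    for var, (lo, hi) in true_ranges.items():
        v = rasters[var].values
        suitable &= ~np.isnan(v) & (v >= lo) & (v <= hi)
    rr, cc = np.nonzero(suitable)
    if len(rr) == 0:
        raise ValueError("no cell satisfies all tolerance ranges")
    rng = np.random.default_rng(seed)
    pick = rng.integers(len(rr), size=n)
    jit_lon = rng.random(n)
    jit_lat = rng.random(n)
    lon = first.xll + (cc[pick] + jit_lon) * first.cellsize
    lat = first.yll + (first.nrows - 1 - rr[pick] + jit_lat) * first.cellsize
    return pd.DataFrame({"species": species, "lon": lon, "lat": lat})
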