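import numpy as np
import pytest

from baoflow.iokit.genotypes import MISSING, GenotypeMatrix
from baoflow.synthgen import IslandConfig, simulate_island_rasters


def make_matrix(geno, species=("P1", "P2", "P3", "O"), chrom="chr1", pos=None):
    geno = np.asarray(geno, dtype=np.int8)
    n = len(geno)
    return GenotypeMatrix(
        list(species),
        np.array([chrom] * n, dtype=object),
        np.asarray(pos) if pos is not None else np.arange(1, n + 1),
        geno,
    )


def brute_force_sums(matrix, quartet):
    """Independent per-site oracle for the weighted ABBA/BABA sums."""
    abba = baba = 0.0
    n_used = 0
    cols = [matrix.species_index(s) for s in quartet]
    for i in range(matrix.n_sites):
        g = [int(matrix.geno[i, c]) for c in cols]
        if MISSING in g or g[3] == 1:
            continue
        p = [x / 2.0 for x in g]
        if p[3] > 0.5:
            p = [1.0 - x for x in p]
        w_abba = (1 - p[0]) * p[1] * p[2] * (1 - p[3])
        w_baba = p[0] * (1 - p[1]) * p[2] * (1 - p[3])
        abba += w_abba
        baba += w_baba
        if w_abba + w_baba > 0:
            n_used += 1
    return abba, baba, n_used


@pytest.fixture(scope="session")
def island():
    """A small noisy island with three environmental layers."""
    cfg = IslandConfig(nrows=80, ncols=80, noise_amp=60.0, seed=7)
    elevation, env = simulate_island_rasters(cfg)
    return cfg, elevation, env
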