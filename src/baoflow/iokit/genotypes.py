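"""Genotype matrix container and VCF round-trip.

The study design is one diploid individual per species, so a genotype is
simply the per-site count of ALT (derived, after polarization) alleles:
0, 1, 2, or :data:`MISSING`.  Positions are 1-based as in VCF; all
interval-shaped outputs elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Per-site diploid ALT-allele counts for named species.

    Parameters
    ----------
    species_names
        Ordered sample labels, one diploid sample per species.
    chrom
        Per-site chromosome identifier (array of str).
    pos
        Per-site 1-based coordinate in bp, strictly increasing within a
        chromosome.
    geno
        ``(n_sites, n_species)`` int8 array with values 0/1/2 or
        :data:`MISSING` (-1).
    """

    species_names: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2 or self.geno.shape != (len(self.pos), len(self.species_names)):
            raise ValueError(
                f"geno shape {self.geno.shape} does not match "
                f"{len(self.pos)} sites x {len(self.species_names)} species"
            )
        valid = np.isin(self.geno, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.geno[~valid])
            raise ValueError(f"invalid genotype codes {bad}; expected 0/1/2/{MISSING}")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        self._index = {s: i for i, s in enumerate(self.species_names)}

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"species {name!r} not in matrix ({self.species_names})") from None

    def column(self, name: str) -> np.ndarray:
        return self.geno[:, self.species_index(name)]

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        m = self.chrom == chrom
        return GenotypeMatrix(self.species_names, self.chrom[m], self.pos[m], self.geno[m])


def read_vcf(path: str, species_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records and indels are skipped (counted in the log).
    ``species_map`` renames VCF samples to species labels; samples not in
    the map are dropped.  Missing GT becomes :data:`MISSING`.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if species_map is None:
        species_map = {s: s for s in samples}
    absent = [s for s in species_map if s not in samples]
    if absent:
        raise ValueError(f"samples {absent} in species_map absent from VCF header {samples}")
    keep = [i for i, s in enumerate(samples) if s in species_map]
    names = [species_map[samples[i]] for i in keep]

    chroms: list[str] = []
    poss: list[int] = []
    rows: list[list[int]] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = v.gt_types
        row = [(0, 1, MISSING, 2)[gt[i]] for i in keep]
        chroms.append(v.CHROM)
        poss.append(v.POS)
        rows.append(row)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/indel records", n_skipped)
    geno = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(names)), dtype=np.int8)
    return GenotypeMatrix(names, np.array(chroms, dtype=object), np.array(poss), geno)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=baoflow
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a matrix as a minimal VCF (REF=A, ALT=T placeholder alleles)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in matrix.chromosomes:
            n = int(matrix.pos[matrix.chrom == c].max()) if (matrix.chrom == c).any() else 0
            fh.write(f"##contig=<ID={c},length={max(n + 1, 1)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.species_names) + "\n")
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT[int(g)] for g in matrix.geno[i])
            fh.write(f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
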