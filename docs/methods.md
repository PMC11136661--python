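# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic data do and do not emulate, and the design
choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Genotypes and hard filtering

All genotype-based statistics consume a `GenotypeMatrix`: one diploid
sample per species, per-site ALT/derived-allele counts in {0, 1, 2,
missing}, biallelic SNPs only, 1-based positions (VCF convention).
Interval-shaped outputs (windows, tracts, ROH) are 0-based half-open
BED; the conversion happens once, at the I/O boundary.

Hard filtering follows the GATK convention: a record is removed iff
any of QD < 2.0, QUAL < 30.0, SOR > 3.0, FS > 60.0, MQ < 40.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0; an absent annotation passes
its criterion (logged). Boundary values are retained (strict
inequalities).

## The coalescent site simulator

`synthgen` simulates each site as an independent gene tree under the
multispecies coalescent on a fixed ultrametric species tree, one
haploid lineage per species, times in coalescent units. Exactly one
mutation is placed uniformly on the gene tree (infinite-sites, one
segregating site per simulated site) and carriers are emitted as
homozygous diploids (0/2), so site patterns are unambiguous and
ABBA/BABA weights take values in {0, ¼, ½, 1} only at planted
heterozygous sites (which this simulator does not produce — diversity
is simulated separately, see below).

Introgression is a single pulse at time `t_m`, applied per site with
probability γ, in one of two modes:

* **join** (default): the recipient's lineage coalesces onto the
  donor's lineage at `t_m` — complete replacement of the recipient
  haplotype by a donor haplotype. Under this model the f4 admixture
  ratio is unbiased for γ up to an O(`t_m`) edge term, because a
  replaced site contributes to the numerator exactly what a duplicated
  donor lineage contributes to the denominator.
* **migrate**: the recipient's lineage moves into the donor's
  population at `t_m` and coalesces there at the ordinary rate — the
  classic pulse. This mode is retained because it is the textbook
  model, but the homozygous-proxy f4 denominator then systematically
  exceeds the migrated-site numerator and the ratio underestimates γ
  (by roughly 40% at the default tree heights); no parameter choice
  removes that attenuation, which is why recovery tests use "join".

Default quartet: t1 = 1.0, t2 = 1.5, t3 = 4.0 coalescent units,
`t_m` = 0.1, direction P3 → P2. The internal branch of 0.5 units gives
a discordance rate of (2/3)·e^(−0.5) ≈ 0.40 — heavy incomplete lineage
sorting, as expected for a rapid radiation. The simulator's topology
frequencies are tested against the closed-form concordance probability
and, independently, against an msprime simulation of the same species
tree; the simulator itself never depends on msprime.

The kernel is a numba-compiled per-site event loop (~1 µs/site), so
the calibration studies below run at full size on one CPU.

What the genotype generators do **not** emulate: linkage (sites are
independent gene trees; tract structure is imposed directly on site
coordinates rather than arising from recombination), reference bias
from the choice of mapping genome, sequencing/genotyping error, and
within-species polymorphism sampling (one individual per species by
design). Passing tests therefore demonstrate correctness of the
statistics under their own model assumptions, not robustness to those
real-data complications.

## Introgression statistics

Frequencies are per-species derived-allele frequencies p = geno/2.
Sites with a missing genotype in the quartet are skipped; a
heterozygous single outgroup cannot polarize its own site, so those
sites are skipped too; where the outgroup frequency exceeds 0.5 all
frequencies are flipped (derived = allele absent from the outgroup).

* ABBA = Σ (1−p1)·p2·p3·(1−p4), BABA = Σ p1·(1−p2)·p3·(1−p4);
  D = (ABBA−BABA)/(ABBA+BABA), NaN when the denominator is 0
  (unperformable).
* **Informative sites** (`n_used`) are sites with nonzero ABBA or BABA
  weight. Jackknife blocks are contiguous with equal numbers of
  informative sites (default 20 blocks); Z = D/SE from the
  delete-one-block jackknife; SE = 0 or < 2 usable blocks gives NaN.
* f4 ratio: numerator as above; denominator recomputed with P3
  duplicated into the P2 slot on the same polarized site set; ≤ 0
  denominator gives NaN.
* f-branch: for each branch b with sister s and donor C outside both,
  f_b(C) = median over B ∈ desc(b) of min over A ∈ desc(s) of
  f4-ratio(A, B, C, O); negative cells floored at 0 (logged), NaN
  where no valid combination exists.

The window scan tiles each chromosome with non-overlapping windows
(default 100,000 bp) and masks windows with fewer than `min_sites`
informative sites (default 20). Masking on informative rather than
total sites matters: with sparse pattern-informative sites, windows
tie at |D| = 1 and any deterministic tie-break would cluster the
selected set. Window classification ranks unmasked windows by |D|
descending, takes ceil(q·N) for q ∈ {0.01, 0.05, 0.10}, breaks ties at
the cutoff by (chrom, start), and splits the selection by the sign
of D.

The interval analysis computes per-chromosome gaps (bp between the end
of one significant window and the start of the next; 0 when adjacent;
never spanning chromosomes) and compares them against gaps computed
identically over `n_control` windows (default 100) sampled uniformly
without replacement from the unmasked windows, genome-wide. The test
is a one-sided Mann–Whitney U (normal approximation with continuity
and tie correction), alternative: significant-set gaps smaller. Note
that the null distribution of p is uniform only when the significant
set and the control have (near-)equal sizes — two samples of different
sizes from the same window universe have systematically different gap
densities — so the calibration study uses a size-matched control,
while power analyses keep the fixed 100-window control.

Calibration/recovery study sizes (chosen once, reported by the tests):
200 null replicates of 20,000 sites (D centring and the |Z| > 3 false
positive rate); 20 seeds × γ ∈ {0.1, 0.2, 0.4} × 50,000 sites (f4
recovery); 20 seeds × 20,000 sites on a 5-taxon tree (f-branch
localization); 20 clustered and 100 null genomes of 20 × 10 Mb at
6 × 10⁻³ sites/bp (interval timing). The 6 × 10⁻³ density gives
~20 informative sites per 100-kb window; the 2,000-window genome with
q = 0.05 makes the significant set comparable to the 100-window
control.

## Heterozygosity and ROH

Windowed heterozygosity is n_het/n_callable per tiling window (default
100 kb), NaN where nothing is callable; θ̂ per chromosome and
genome-wide is Σn_het/Σn_callable. ROH are maximal runs of windows
with het ≤ threshold, merged across gaps of at most `merge_gap`
windows (default 1), dropped below `min_len` (default 100 kb), and
classed short < 500 kb ≤ intermediate ≤ 2 Mb < long. The long
boundary (> 2 Mb, recent inbreeding) is the substantive one; 500 kb is
a package convention.

The default threshold is 0.25 × the genome-wide median window het.
This windowed observed-heterozygosity rule is a deliberate, documented
replacement for likelihood-based per-window mutation-rate fitting
(MlRho's best-fit K ≤ 2 criterion): at low diversity observed het
converges to per-site θ, and the explicit rule makes recovery tests
exact. Corollary: the median-based default assumes ROH occupy a
minority of the genome; if half the genome is ROH the median itself
collapses and an absolute threshold should be supplied.

The diversity generator plants heterozygous sites as independent
Bernoulli draws (rate `base_het` outside tracts, 0.02 × `base_het`
inside), which emulates the window-level statistics of ROH but not the
haplotype structure that produces them.

## Competition model

Fixed-step integration (RK4 default, Euler available) of the coupled
logistic equations. Three stages: growth; at stage-2 entry Y is
multiplied by ρ (default 0.1) and X receives the identical
perturbation after `delay` (default 5 × 10⁵ model-time units; the
multiplicative instantaneous drop is the simplest event reproducing an
asynchronous crash-and-recovery, with a ramped alternative out of
scope); growth again to `t_final`. Defaults a = b = 10⁻⁵,
m = n = 5 × 10⁴, X0 = Y0 = 100, stage boundaries 2 × 10⁶ / 4 × 10⁶ /
6 × 10⁶, dt = 500 — chosen so the default run shows growth to the
shared capacity, the staggered crashes, and recovery. Event times are
required to be integer multiples of dt so perturbations land exactly
on grid points and the event log is exact; a negative population
aborts with advice to reduce dt. The "asynchronous minima" property is
evaluated from stage-2 entry onward (the crash era), since with small
initial sizes the global minimum is trivially the initial condition.

## Niche, habitat and sea level

* Variable selection: greedy elimination — drop the variable with the
  largest mean |Pearson r| until all pairwise |r| < 0.8 (constant
  variables dropped first). The r < 0.8 criterion is fixed; the greedy
  order is a package choice.
* Valence: per species × variable (min, max) over values extracted at
  occurrences (nearest cell; off-raster and nodata points excluded and
  counted). In-range tests are inclusive; habitat = cells where every
  selected variable is in range (the strictest reading of "most
  overlapping layers"), with the overlap-count raster exposed so a
  softer cut can be applied downstream.
* Niche space: layers standardized over land cells, 2-component PCA
  fitted on the background cells; occurrence densities are Gaussian
  KDE on an R × R grid (default R = 100) spanning the background
  extent, Scott bandwidth, normalized to sum 1; a zero-variance cloud
  degenerates to single-cell mass. Densities are used directly —
  the environmental-availability correction of occurrence densities is
  a documented extension, not implemented, because its parameters are
  not fixed by the study design and Schoener's D semantics are
  unchanged.
* Schoener's D = 1 − ½Σ|z1 − z2|, clipped into [0, 1] against float
  rounding. Equivalency test: pooled label permutation,
  p = (#{D_null ≤ D_obs}+1)/(n_reps+1) (small p: less overlap than
  label-equivalent samples), default 1,000 replicates. Similarity
  test: the direction-specified species is replaced by uniform draws
  from the background cells; the default alternative is "greater"
  (small p: more overlap than random background niches — niche
  conservatism), since that is the direction the test is used to
  assess; "less" is available. The full land mask is the default
  background.
* Land area: land = cells with elevation strictly greater than the sea
  level (shoreline cells at exactly s count as sea, stated for
  bit-reproducibility); area = count × cellsize²; percent change is
  relative to the area at level 0. Sea-level curves (GMSL or RSL) are
  consumed as two-column CSV inputs; no geophysical sea-level model is
  re-implemented, and areas are planar cell counts, not geodesic.

The island generator is a radial cone plus smoothed noise whose
elevation continues below zero offshore, so the land-area curve
responds in both directions of the sea-level sweep; environmental
layers are smooth random fields rescaled to known ranges over
present-day land. It does not emulate real topographic roughness,
spatial autocorrelation structure of climate, or occurrence sampling
bias.

## Degenerate inputs and numerical conventions

NaN uniformly means "unperformable, not zero": D with an empty
denominator, Z with zero jackknife variance, f4 with a non-positive
denominator, f-branch cells without a valid (A, B, C) split, windows
below the informative-site mask, heterozygosity without callable
sites. Reader/writer pairs round-trip integer fields exactly and
floats to the printed precision (ASC default %.6g); all stochastic
entry points take explicit seeds and are reproducible bit-for-bit for
a given seed.
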