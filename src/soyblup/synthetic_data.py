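"""Synthetic genotypes and phenotypes with the structure of an elite
multi-family soybean breeding population.

The generator emulates the statistical features the analysis pipeline
assumes, so every stage is testable without real accessions:

* 301 inbred lines from 34 biparental families (sizes 1–28, median 8),
  produced by crossing two founder haplotypes drawn from a shared base pool
  and selfing with recombination until residual heterozygosity is below 2%
  (F5-derived-like material);
* linkage disequilibrium from founder haplotype blocks (latent AR(1)
  process along each chromosome) plus roughly one crossover per chromosome
  per meiosis;
* a minor-allele-frequency spectrum with a heavy rare-allele tail
  (U-shaped Beta base frequencies);
* GBS-style missingness that is low near chromosome ends and high in
  pericentromeric regions, calibrated to a mean/median per-marker
  missingness of 0.18/0.08;
* multi-environment plot phenotypes from an augmented incomplete block
  design (blocks of 27–39 entries plus three repeated checks, two
  replications) with genotypic, genotype-by-environment and residual
  variance components matching a typical grain-yield trial
  (12.9 / 7.28 / 31.4 over 4 locations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from soyblup.marker_io import GenotypeMatrix


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding population and trial.

    Genome / population structure defaults mirror the emulated breeding
    program; trait defaults mirror a grain-yield trial (variance components
    in squared trait units, 4 locations x 2 replications).
    """

    # population
    n_lines: int = 301
    n_families: int = 34
    family_size_range: tuple[int, int] = (1, 28)
    family_size_median: float = 8.0
    n_founder_haplotypes: int = 30
    n_selfing_generations: int = 6
    # genome
    n_chromosomes: int = 20
    markers_per_chromosome: int = 150
    chromosome_length_bp: int = 50_000_000
    ld_decay_bp: float = 2_000_000.0
    maf_beta: tuple[float, float] = (0.35, 0.35)
    crossovers_per_chromosome: float = 1.0
    # missingness
    missing_mean: float = 0.18
    missing_median: float = 0.08
    missing_bump_power: int = 4
    # trait architecture
    n_qtl: int = 100
    n_epistatic_pairs: int = 0
    additive_variance: float = 12.9
    epistatic_variance: float = 0.0
    # trial design
    n_locations: int = 4
    n_reps: int = 2
    block_size_range: tuple[int, int] = (27, 39)
    n_checks: int = 3
    gxe_variance: float = 7.28
    residual_variance: float = 31.4
    location_sd: float = 3.0
    replicate_sd: float = 1.0
    block_sd: float = 1.0
    trait_mean: float = 0.0
    trait_name: str = "GY"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_lines:
            raise ValueError("n_families cannot exceed n_lines")
        lo, hi = self.family_size_range
        if not (lo * self.n_families <= self.n_lines <= hi * self.n_families):
            raise ValueError(
                f"{self.n_lines} lines cannot be partitioned into {self.n_families} "
                f"families of size {lo}..{hi}"
            )
        for v in (self.additive_variance, self.epistatic_variance,
                  self.gxe_variance, self.residual_variance):
            if v < 0:
                raise ValueError("variances must be non-negative")


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for recovery tests."""

    seed: int
    breeding_values: pd.Series | None = None
    qtl_index: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None
    varcomps: dict = field(default_factory=dict)
    family_of_line: dict = field(default_factory=dict)


def _family_sizes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Family sizes in [lo, hi] summing to n_lines, median near the target."""
    lo, hi = cfg.family_size_range
    sizes = np.clip(
        np.round(rng.lognormal(np.log(cfg.family_size_median), 0.75, cfg.n_families)),
        lo, hi,
    ).astype(int)
    # repair the sum with +-1 nudges inside the bounds
    diff = cfg.n_lines - sizes.sum()
    while diff != 0:
        i = rng.integers(cfg.n_families)
        step = 1 if diff > 0 else -1
        if lo <= sizes[i] + step <= hi:
            sizes[i] += step
            diff -= step
    return sizes


def _founder_haplotypes(cfg: SimConfig, rng: np.random.Generator,
                        positions: list[np.ndarray]) -> list[np.ndarray]:
    """Base-pool haplotypes per chromosome via a latent AR(1) Gaussian.

    Marker j carries allele 1 on haplotype h when the latent value falls
    below the marker's Beta-distributed base-frequency quantile, giving both
    the configured allele-frequency spectrum and distance-decaying LD.
    """
    from scipy.stats import norm

    H = cfg.n_founder_haplotypes
    haps = []
    for pos in positions:
        p = len(pos)
        freq = rng.beta(*cfg.maf_beta, size=p)
        thresh = norm.ppf(np.clip(freq, 1e-12, 1 - 1e-12))
        z = np.empty((H, p))
        z[:, 0] = rng.standard_normal(H)
        for j in range(1, p):
            rho = np.exp(-(pos[j] - pos[j - 1]) / cfg.ld_decay_bp)
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(H)
        haps.append((z < thresh).astype(np.int8))
    return haps


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, pos: np.ndarray, length: int,
            lam: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a haplotype pair (Poisson crossovers)."""
    n_xo = rng.poisson(lam)
    current = rng.integers(2)
    if n_xo == 0:
        return (hap_a if current == 0 else hap_b).copy()
    xo = np.sort(rng.uniform(0, length, n_xo))
    segment = np.searchsorted(xo, pos)  # segment index per marker
    use_b = (segment + current) % 2 == 1
    out = np.where(use_b, hap_b, hap_a)
    return out.astype(np.int8)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a complete (no-missing) major-allele dosage matrix.

    Returns the matrix plus a :class:`SimTruth` carrying the seed and the
    family assignment of every line.  Fixed seed means identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = [
        np.sort(rng.choice(np.arange(1, cfg.chromosome_length_bp, dtype=np.int64),
                           size=cfg.markers_per_chromosome, replace=False))
        for _ in range(cfg.n_chromosomes)
    ]
    pool = _founder_haplotypes(cfg, rng, positions)
    sizes = _family_sizes(cfg, rng)

    n_total = cfg.n_chromosomes * cfg.markers_per_chromosome
    hapA = np.empty((cfg.n_lines, n_total), dtype=np.int8)
    hapB = np.empty((cfg.n_lines, n_total), dtype=np.int8)
    family_of_line: dict[str, int] = {}
    line = 0
    for fam, size in enumerate(sizes):
        f1, f2 = rng.choice(cfg.n_founder_haplotypes, size=2, replace=False)
        for _ in range(size):
            a_chunks, b_chunks = [], []
            for c in range(cfg.n_chromosomes):
                a, b = pool[c][f1].copy(), pool[c][f2].copy()
                for _ in range(cfg.n_selfing_generations):
                    g1 = _gamete(a, b, positions[c], cfg.chromosome_length_bp,
                                 cfg.crossovers_per_chromosome, rng)
                    g2 = _gamete(a, b, positions[c], cfg.chromosome_length_bp,
                                 cfg.crossovers_per_chromosome, rng)
                    a, b = g1, g2
                a_chunks.append(a)
                b_chunks.append(b)
            hapA[line] = np.concatenate(a_chunks)
            hapB[line] = np.concatenate(b_chunks)
            family_of_line[f"L{line + 1:03d}"] = fam
            line += 1

    alt_count = (hapA + hapB).astype(float)  # copies of allele "1"
    freq1 = alt_count.mean(axis=0) / 2.0
    # major allele: the more frequent one; ties go to allele "1" ('A' < 'C')
    one_major = freq1 >= 0.5
    dosage = np.where(one_major, alt_count, 2.0 - alt_count)

    chroms = np.repeat([str(c + 1) for c in range(cfg.n_chromosomes)],
                       cfg.markers_per_chromosome)
    pos_all = np.concatenate(positions)
    meta = pd.DataFrame(
        {
            "marker_id": [f"S{c}_{p}" for c, p in zip(chroms, pos_all)],
            "chromosome": chroms,
            "position": pos_all,
            "major_allele": np.where(one_major, "A", "C"),
            "minor_allele": np.where(one_major, "C", "A"),
        }
    )
    line_ids = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    matrix = GenotypeMatrix(dosage=dosage, marker_meta=meta, line_ids=line_ids)
    truth = SimTruth(seed=cfg.seed, family_of_line=family_of_line)
    return matrix, truth


def _missingness_rates(cfg: SimConfig, meta: pd.DataFrame) -> np.ndarray:
    """Per-marker missing probability: pericentromeric cosine-type bump.

    The bump ``sin(pi t)^(2k)`` (t = relative position) peaks mid-chromosome;
    the affine calibration ``c1 + c2 * bump`` matches the configured mean and
    median missingness in expectation.
    """
    if cfg.missing_mean <= 0:
        return np.zeros(len(meta))
    t = np.empty(len(meta))
    for chrom, idx in meta.groupby("chromosome", sort=False).groups.items():
        pos = meta.loc[idx, "position"].to_numpy(float)
        t[np.asarray(idx)] = pos / cfg.chromosome_length_bp
    bump = np.sin(np.pi * t) ** (2 * cfg.missing_bump_power)
    spread = bump.mean() - np.median(bump)
    if spread < 1e-6:
        return np.full(len(meta), cfg.missing_mean)
    c2 = (cfg.missing_mean - cfg.missing_median) / spread
    c1 = cfg.missing_median - c2 * np.median(bump)
    return np.clip(c1 + c2 * bump, 0.0, 0.95)


def apply_missingness(matrix: GenotypeMatrix, cfg: SimConfig) -> GenotypeMatrix:
    """Mask entries with position-dependent GBS-style missingness.

    The input matrix is left untouched (the caller keeps it as truth for
    masking experiments); the returned copy has NaN at masked entries.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    rates = _missingness_rates(cfg, matrix.marker_meta)
    mask = rng.random(matrix.dosage.shape) < rates[None, :]
    out = matrix.copy()
    out.dosage[mask] = np.nan
    return out


def _blocks(entries: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition shuffled entries into blocks of the configured size range."""
    lo, hi = cfg.block_size_range
    order = rng.permutation(entries)
    blocks, i = [], 0
    while i < len(order):
        size = int(rng.integers(lo, hi + 1))
        blocks.append(order[i:i + size])
        i += size
    return blocks


def simulate_phenotypes(matrix: GenotypeMatrix, cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Plot-level phenotypes from an augmented incomplete block design.

    Breeding values are sums of QTL effects at sampled polymorphic markers
    (plus optional pairwise-product epistatic effects), rescaled so the
    realized genetic variance equals the configured target exactly.  Plot
    value = mean + g + location + replicate + block + GxE + residual, with
    three check cultivars repeated in every block.  Requires a complete
    (or imputed) matrix for QTL sampling.
    """
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    X = matrix.dosage
    if np.isnan(X).any():
        raise ValueError("simulate_phenotypes needs a complete matrix; impute first")
    n, p = X.shape
    if cfg.n_qtl > p:
        raise ValueError(f"n_qtl={cfg.n_qtl} exceeds {p} markers")

    freq = X.mean(axis=0) / 2.0
    poly = np.flatnonzero((freq > 0.0) & (freq < 1.0))
    if len(poly) < cfg.n_qtl:
        raise ValueError("not enough polymorphic markers for the requested QTL count")
    qtl = np.sort(rng.choice(poly, size=cfg.n_qtl, replace=False))
    effects = rng.standard_normal(cfg.n_qtl)
    Xc = X[:, qtl] - X[:, qtl].mean(axis=0)
    g = Xc @ effects
    if cfg.additive_variance > 0 and g.std() > 0:
        scale = np.sqrt(cfg.additive_variance) / g.std()
        g = g * scale
        effects = effects * scale
    else:
        g = np.zeros(n)
        effects = np.zeros(cfg.n_qtl)
    if cfg.epistatic_variance > 0 and cfg.n_epistatic_pairs > 0:
        pa = rng.choice(poly, size=cfg.n_epistatic_pairs)
        pb = rng.choice(poly, size=cfg.n_epistatic_pairs)
        prod = (X[:, pa] - X[:, pa].mean(axis=0)) * (X[:, pb] - X[:, pb].mean(axis=0))
        epi = prod @ rng.standard_normal(cfg.n_epistatic_pairs)
        if epi.std() > 0:
            epi *= np.sqrt(cfg.epistatic_variance) / epi.std()
        g = g + epi

    check_ids = [f"CHECK{i + 1}" for i in range(cfg.n_checks)]
    g_checks = rng.normal(0.0, np.sqrt(max(cfg.additive_variance, 1e-12)), cfg.n_checks) \
        if cfg.additive_variance > 0 else np.zeros(cfg.n_checks)
    gvalues = pd.Series(
        np.concatenate([g, g_checks]), index=list(matrix.line_ids) + check_ids
    )

    locations = [f"LOC{j + 1}" for j in range(cfg.n_locations)]
    loc_eff = rng.normal(0.0, cfg.location_sd, cfg.n_locations)
    gxe = {
        (lid, loc): rng.normal(0.0, np.sqrt(cfg.gxe_variance)) if cfg.n_locations > 1 else 0.0
        for lid in gvalues.index for loc in locations
    }

    entries = np.arange(n)
    rows = []
    for j, loc in enumerate(locations):
        for r in range(cfg.n_reps):
            rep_eff = rng.normal(0.0, cfg.replicate_sd)
            for b, block in enumerate(_blocks(entries, cfg, rng)):
                blk_eff = rng.normal(0.0, cfg.block_sd)
                members = [matrix.line_ids[i] for i in block] + check_ids
                for lid in members:
                    value = (
                        cfg.trait_mean + gvalues[lid] + loc_eff[j] + rep_eff + blk_eff
                        + gxe[(lid, loc)] + rng.normal(0.0, np.sqrt(cfg.residual_variance))
                    )
                    rows.append((lid, loc, f"R{r + 1}", f"B{b + 1}", value))

    plots = pd.DataFrame(rows, columns=["line_id", "location", "replicate", "block",
                                        cfg.trait_name])
    truth = SimTruth(
        seed=cfg.seed,
        breeding_values=gvalues,
        qtl_index=qtl,
        qtl_effects=effects,
        varcomps={
            "sigma2_g": cfg.additive_variance,
            "sigma2_ge": cfg.gxe_variance if cfg.n_locations > 1 else 0.0,
            "sigma2_e": cfg.residual_variance,
            "n_env": cfg.n_locations,
            "n_rep": cfg.n_reps,
        },
    )
    return plots, truth
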