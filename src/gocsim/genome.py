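"""Base-population genomes, SNP panels, and gamete formation.

The base population is generated at mutation--drift--linkage equilibrium for a
small effective size (default Ne = 100), mirroring a closed nucleus whose
historical size equals the effective size targeted by the breeding scheme.
Two backends are available:

* ``coalescent`` (default) -- msprime with an infinite-sites binary mutation
  model; the stationary coalescent is the equilibrium limit of the forward
  Wright--Fisher process, so the site-frequency spectrum and heterozygosity
  match the forward model run for >= 4 Ne generations.
* ``forward`` -- an explicit diploid Wright--Fisher simulation with
  infinite-sites mutation and Poisson recombination; retained for fidelity
  tests at small parameter values.

Downstream code consumes only the t = 0 haplotype pool, so the backends are
interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

__all__ = [
    "GenomeMap",
    "HaplotypePool",
    "PanelAssignment",
    "Gamete",
    "simulate_base_genomes",
    "sample_panels",
    "meiosis",
    "recombination_fractions",
    "sample_gametes_batch",
]


@dataclass(frozen=True)
class GenomeMap:
    """Genome layout: equally sized chromosomes with a uniform genetic map.

    The genetic map is uniform, so 1 Morgan corresponds to the physical length
    of one chromosome and ROH length thresholds are convertible between cM and
    Mb.
    """

    n_chromosomes: int = 10
    morgans_per_chromosome: float = 1.0
    bp_per_chromosome: float = 140e6

    @property
    def total_morgans(self) -> float:
        return self.n_chromosomes * self.morgans_per_chromosome

    @property
    def total_bp(self) -> float:
        return self.n_chromosomes * self.bp_per_chromosome

    def bp_to_morgan(self, bp):
        return np.asarray(bp) * self.morgans_per_chromosome / self.bp_per_chromosome

    def morgan_to_bp(self, morgan):
        return np.asarray(morgan) * self.bp_per_chromosome / self.morgans_per_chromosome


@dataclass
class HaplotypePool:
    """Biallelic haplotypes over segregating sites of the base population.

    ``haplotypes`` is (n_haplotypes, n_sites) with 0/1 alleles; sites are
    sorted by (chromosome, position).
    """

    haplotypes: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    genome_map: GenomeMap

    def __post_init__(self):
        if self.haplotypes.shape[0] % 2:
            raise ValueError("haplotype count must be even")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def position_morgan(self) -> np.ndarray:
        return self.genome_map.bp_to_morgan(self.position_bp)

    @property
    def frequencies(self) -> np.ndarray:
        """Frequency of the '1' allele in the pool sample."""
        return self.haplotypes.mean(axis=0)

    def mean_pairwise_heterozygosity_per_bp(self) -> float:
        """Mean pairwise diversity per bp (neutral expectation 4*Ne*mu)."""
        p = self.frequencies
        n = self.n_haplotypes
        # unbiased per-site pairwise diversity, summed and scaled by genome length
        pi = (2.0 * p * (1.0 - p) * n / (n - 1)).sum()
        return float(pi / self.genome_map.total_bp)


@dataclass
class PanelAssignment:
    """Disjoint SNP panels on a common, position-sorted tracked-locus axis.

    Tracked loci are the union of all panel loci, sorted by (chromosome,
    genetic position).  ``panel_index`` maps a panel name (``M``, ``Q``, ``N``,
    ``D``) to an index array into the tracked axis.  ``p0`` holds base
    (generation-0) frequencies of the reference allele per tracked locus; the
    reference allele at each locus is chosen at random when the panels are
    sampled, and allele codes on the tracked axis are re-oriented so that
    allele 1 is the reference.
    """

    chromosome: np.ndarray
    position_morgan: np.ndarray
    position_bp: np.ndarray
    panel_index: dict
    p0: np.ndarray
    pool_site_index: np.ndarray
    flipped: np.ndarray

    @property
    def n_tracked(self) -> int:
        return self.chromosome.shape[0]

    def panel_p0(self, name: str) -> np.ndarray:
        return self.p0[self.panel_index[name]]

    def panel_names(self):
        return list(self.panel_index)


@dataclass
class Gamete:
    """A single gamete: alleles at tracked loci plus its founder-descent mosaic.

    ``segments`` is a list of ``(chromosome, start_morgan, end_morgan,
    founder_haplotype)`` tuples tiling each chromosome exactly once.
    """

    alleles: np.ndarray
    segments: list = field(default_factory=list)

    def segments_on(self, chromosome: int):
        return [s for s in self.segments if s[0] == chromosome]


def simulate_base_genomes(
    ne: int = 100,
    n_generations: int = 400,
    mu: float = 1e-8,
    genome_map: GenomeMap | None = None,
    n_haplotypes: int = 200,
    seed: int | None = None,
    backend: str = "coalescent",
) -> HaplotypePool:
    """Generate base-population haplotypes in mutation-drift-linkage balance.

    Parameters
    ----------
    ne
        Diploid effective population size of the historical population.
    n_generations
        Length of the forward burn-in (used by the ``forward`` backend; the
        coalescent backend samples the stationary distribution directly, which
        the forward process approaches after ~4 Ne generations).
    mu
        Mutation rate per base pair per generation (infinite-sites).
    n_haplotypes
        Number of haplotypes sampled from the equilibrium population.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    gmap = genome_map or GenomeMap()
    if backend == "coalescent":
        return _coalescent_pool(ne, mu, gmap, n_haplotypes, seed)
    if backend == "forward":
        return _forward_pool(ne, n_generations, mu, gmap, n_haplotypes, seed)
    raise ValueError(f"unknown backend {backend!r}")


def _coalescent_pool(ne, mu, gmap, n_haplotypes, seed) -> HaplotypePool:
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even")
    ss = np.random.SeedSequence(seed)
    chrom_seeds = ss.generate_state(2 * gmap.n_chromosomes, dtype=np.uint32) % (2**31 - 1) + 1
    haps, chroms, pos = [], [], []
    rr = gmap.morgans_per_chromosome / gmap.bp_per_chromosome
    for c in range(gmap.n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_haplotypes // 2,
            population_size=ne,
            ploidy=2,
            sequence_length=gmap.bp_per_chromosome,
            recombination_rate=rr,
            random_seed=int(chrom_seeds[2 * c]),
        )
        if mu > 0:
            ts = msprime.sim_mutations(
                ts,
                rate=mu,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
                random_seed=int(chrom_seeds[2 * c + 1]),
            )
        if ts.num_sites == 0:
            continue
        g = ts.genotype_matrix().T.astype(np.int8)  # (haplotypes, sites)
        site_pos = np.array([s.position for s in ts.sites()])
        # keep strictly biallelic polymorphic sites
        freq = g.mean(axis=0)
        keep = (freq > 0) & (freq < 1) & (g.max(axis=0) <= 1)
        haps.append(g[:, keep])
        pos.append(site_pos[keep])
        chroms.append(np.full(int(keep.sum()), c, dtype=np.int32))
    if not haps:
        empty = np.zeros((n_haplotypes, 0), dtype=np.int8)
        return HaplotypePool(empty, np.zeros(0, np.int32), np.zeros(0), gmap)
    return HaplotypePool(
        np.concatenate(haps, axis=1),
        np.concatenate(chroms),
        np.concatenate(pos),
        gmap,
    )


def _forward_pool(ne, n_generations, mu, gmap, n_haplotypes, seed) -> HaplotypePool:
    """Diploid Wright-Fisher with infinite-sites mutation and recombination.

    Intended for small parameter values (fidelity tests); every site is kept on
    a continuous per-chromosome coordinate.
    """
    rng = np.random.default_rng(seed)
    n_hap = 2 * ne
    # sites stored as (chrom, pos_bp); alleles (n_hap, n_sites)
    chrom = np.zeros(0, dtype=np.int32)
    pos = np.zeros(0)
    alleles = np.zeros((n_hap, 0), dtype=np.int8)
    mu_genome = mu * gmap.total_bp
    for _ in range(n_generations):
        order = np.argsort(chrom * (gmap.bp_per_chromosome + 1) + pos, kind="stable")
        chrom, pos, alleles = chrom[order], pos[order], alleles[:, order]
        pos_m = gmap.bp_to_morgan(pos)
        sires = rng.integers(ne, size=ne)
        dams = rng.integers(ne, size=ne)
        new = np.empty_like(alleles)
        for i in range(ne):
            for j, par in enumerate((sires[i], dams[i])):
                ph = alleles[2 * par : 2 * par + 2]
                strand = _strand_at_loci(chrom, pos_m, gmap, rng)
                new[2 * i + j] = np.where(strand == 0, ph[0], ph[1])
        alleles = new
        # infinite-sites mutations
        n_mut = rng.poisson(mu_genome * n_hap)
        if n_mut:
            mchrom = rng.integers(gmap.n_chromosomes, size=n_mut).astype(np.int32)
            mpos = rng.random(n_mut) * gmap.bp_per_chromosome
            mcol = np.zeros((n_hap, n_mut), dtype=np.int8)
            mcol[rng.integers(n_hap, size=n_mut), np.arange(n_mut)] = 1
            chrom = np.concatenate([chrom, mchrom])
            pos = np.concatenate([pos, mpos])
            alleles = np.concatenate([alleles, mcol], axis=1)
        # prune fixed / lost
        f = alleles.mean(axis=0)
        seg = (f > 0) & (f < 1)
        chrom, pos, alleles = chrom[seg], pos[seg], alleles[:, seg]
    order = np.lexsort((pos, chrom))
    chrom, pos, alleles = chrom[order], pos[order], alleles[:, order]
    take = rng.choice(n_hap, size=min(n_haplotypes, n_hap), replace=False)
    sub = alleles[take]
    f = sub.mean(axis=0)
    seg = (f > 0) & (f < 1)
    return HaplotypePool(sub[:, seg], chrom[seg], pos[seg], gmap)


def _strand_at_loci(chrom, pos_m, gmap, rng):
    """Parental-strand indicator at sorted loci for one meiosis (Markov form)."""
    r = recombination_fractions(chrom, pos_m)
    flips = rng.random(r.shape[0]) < r
    return np.bitwise_xor.accumulate(flips.astype(np.int8))


def sample_panels(
    pool: HaplotypePool,
    panel_sizes: dict | None = None,
    seed=None,
    founder_dosages: np.ndarray | None = None,
) -> PanelAssignment:
    """Sample disjoint SNP panels uniformly without replacement.

    Parameters
    ----------
    panel_sizes
        Mapping of panel name to size, default ``{"M":7000,"Q":7000,"N":7000,
        "D":7000}``.
    founder_dosages
        Optional (n_founders, n_pool_sites) 0/1/2 dosage matrix of the
        generation-0 breeding individuals.  When given, panels are restricted
        to sites segregating among the founders and base frequencies ``p0``
        are recorded from the founders; otherwise from the pool sample.

    At each panel locus a reference allele is chosen at random and the allele
    orientation on the tracked axis is flipped accordingly, so ``p0`` is the
    frequency of a randomly chosen reference allele at t = 0.
    """
    sizes = panel_sizes or {"M": 7000, "Q": 7000, "N": 7000, "D": 7000}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if founder_dosages is not None:
        freq = founder_dosages.mean(axis=0) / 2.0
    else:
        freq = pool.frequencies
    eligible = np.flatnonzero((freq > 0) & (freq < 1))
    total = int(sum(sizes.values()))
    if eligible.size < total:
        raise ValueError(
            f"insufficient segregating sites: need {total}, have {eligible.size} "
            f"(shortfall {total - eligible.size})"
        )
    chosen = rng.choice(eligible, size=total, replace=False)
    # assign contiguous blocks of the permutation to panels
    panel_of = {}
    off = 0
    for name, size in sizes.items():
        panel_of[name] = chosen[off : off + size]
        off += size
    all_idx = np.sort(chosen)
    order_in_tracked = {site: i for i, site in enumerate(all_idx)}
    panel_index = {
        name: np.array(sorted(order_in_tracked[s] for s in sites), dtype=np.int64)
        for name, sites in panel_of.items()
    }
    flipped = rng.random(all_idx.size) < 0.5
    p_ref = np.where(flipped, 1.0 - freq[all_idx], freq[all_idx])
    return PanelAssignment(
        chromosome=pool.chromosome[all_idx].copy(),
        position_morgan=pool.position_morgan[all_idx].copy(),
        position_bp=pool.position_bp[all_idx].copy(),
        panel_index=panel_index,
        p0=p_ref,
        pool_site_index=all_idx,
        flipped=flipped,
    )


def recombination_fractions(chrom: np.ndarray, pos_morgan: np.ndarray) -> np.ndarray:
    """Per-locus strand-flip probabilities for sorted tracked loci.

    Entry 0 and each first locus of a chromosome get 0.5 (independent strand
    choice); within a chromosome the Haldane recombination fraction
    (1 - exp(-2 d)) / 2 of the preceding interval.  Under Poisson crossovers
    without interference, the parental-origin process along a chromosome is
    exactly Markov with these flip probabilities.
    """
    L = chrom.shape[0]
    r = np.empty(L)
    if L == 0:
        return r
    r[0] = 0.5
    d = np.diff(pos_morgan)
    same = chrom[1:] == chrom[:-1]
    r[1:] = np.where(same, 0.5 * (1.0 - np.exp(-2.0 * np.clip(d, 0, None))), 0.5)
    return r


def meiosis(
    parent_alleles: np.ndarray,
    parent_segments,
    panels: PanelAssignment,
    genome_map: GenomeMap,
    seed=None,
) -> Gamete:
    """Form one gamete by Poisson recombination of a phased parent.

    ``parent_alleles`` is (2, n_tracked); ``parent_segments`` a pair of descent
    mosaics (lists of ``(chrom, start, end, founder_hap)`` in Morgans).
    Crossover counts per chromosome are Poisson(map length), positions uniform,
    no interference.  Returns the recombinant allele vector and the composed
    descent mosaic.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = panels.n_tracked
    alleles = np.empty(L, dtype=np.int8)
    segments = []
    clen = genome_map.morgans_per_chromosome
    for c in range(genome_map.n_chromosomes):
        n_x = rng.poisson(clen)
        xpos = np.sort(rng.random(n_x) * clen)
        start = int(rng.integers(2))
        mask = panels.chromosome == c
        if mask.any():
            pos = panels.position_morgan[mask]
            strand = (start + np.searchsorted(xpos, pos, side="right")) % 2
            alleles[mask] = np.where(strand == 0, parent_alleles[0, mask], parent_alleles[1, mask])
        # compose the descent mosaic over alternating intervals
        bounds = np.concatenate([[0.0], xpos, [clen]])
        for k in range(bounds.size - 1):
            lo, hi = bounds[k], bounds[k + 1]
            if hi <= lo:
                continue
            h = (start + k) % 2
            for (sc, ss, se, fid) in parent_segments[h]:
                if sc != c:
                    continue
                a, b = max(ss, lo), min(se, hi)
                if b > a:
                    segments.append((c, a, b, fid))
    segments.sort(key=lambda s: (s[0], s[1]))
    # merge touching segments from the same founder haplotype
    merged = []
    for s in segments:
        if merged and merged[-1][0] == s[0] and merged[-1][3] == s[3] and abs(merged[-1][2] - s[1]) < 1e-12:
            merged[-1] = (s[0], merged[-1][1], s[2], s[3])
        else:
            merged.append(list(s) if False else (s[0], s[1], s[2], s[3]))
    return Gamete(alleles=alleles, segments=[tuple(s) for s in merged])


def sample_gametes_batch(
    parent_alleles: np.ndarray,
    parent_origin: np.ndarray | None,
    parent_index: np.ndarray,
    recomb_fractions: np.ndarray,
    rng: np.random.Generator,
):
    """Sample one gamete per entry of ``parent_index`` at tracked loci.

    Uses the exact Markov representation of Poisson crossovers: the strand
    indicator flips between consecutive loci with the Haldane recombination
    fraction of the interval (0.5 across chromosome boundaries).  Returns
    (alleles, origin) arrays of shape (n_gametes, n_loci); ``origin`` is None
    when ``parent_origin`` is None.
    """
    n_g = parent_index.shape[0]
    L = recomb_fractions.shape[0]
    flips = rng.random((n_g, L), dtype=np.float32) < recomb_fractions.astype(np.float32)[None, :]
    strand = np.bitwise_xor.accumulate(flips.astype(np.int8), axis=1)
    pa = parent_alleles[parent_index]  # (n_g, 2, L)
    alleles = np.where(strand == 0, pa[:, 0, :], pa[:, 1, :])
    origin = None
    if parent_origin is not None:
        po = parent_origin[parent_index]
        origin = np.where(strand == 0, po[:, 0, :], po[:, 1, :])
    return alleles, origin
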