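"""Base-genome simulation, panel sampling and meiosis."""

import numpy as np
import pytest
from scipy import stats

from gocsim.genome import (
    GenomeMap,
    meiosis,
    recombination_fractions,
    sample_gametes_batch,
    sample_panels,
    simulate_base_genomes,
)

SMALL_MAP = GenomeMap(n_chromosomes=2, bp_per_chromosome=5e6)


class TestSimulateBaseGenomes:
    def test_no_mutation_no_sites(self):
        pool = simulate_base_genomes(ne=50, mu=0.0, genome_map=SMALL_MAP, n_haplotypes=20, seed=1)
        assert pool.n_sites == 0

    def test_heterozygosity_matches_neutral_theory(self):
        """Mean pairwise diversity per bp ~ 4 Ne mu at equilibrium."""
        gmap = GenomeMap(n_chromosomes=4, bp_per_chromosome=50e6)
        pis = [
            simulate_base_genomes(
                ne=100, mu=1e-8, genome_map=gmap, n_haplotypes=100, seed=s
            ).mean_pairwise_heterozygosity_per_bp()
            for s in range(6)
        ]
        assert np.mean(pis) == pytest.approx(4 * 100 * 1e-8, rel=0.25)

    def test_all_sites_polymorphic_and_biallelic(self):
        pool = simulate_base_genomes(ne=60, mu=5e-8, genome_map=SMALL_MAP, n_haplotypes=40, seed=3)
        f = pool.frequencies
        assert np.all((f > 0) & (f < 1))
        assert pool.haplotypes.max() <= 1
        assert pool.n_haplotypes % 2 == 0

    def test_site_frequency_spectrum_decreasing(self):
        """Counts per minor-allele-count class decline on average (~1/i)."""
        pool = simulate_base_genomes(
            ne=100, mu=1e-8, genome_map=GenomeMap(n_chromosomes=4, bp_per_chromosome=80e6),
            n_haplotypes=60, seed=5,
        )
        counts = (pool.haplotypes.sum(axis=0)).astype(int)
        mac = np.minimum(counts, pool.n_haplotypes - counts)
        hist = np.bincount(mac, minlength=10)[1:10]
        # singletons dominate and the first classes decline
        assert hist[0] == hist.max()
        assert hist[0] > 2 * hist[4]

    def test_forward_backend_matches_neutral_expectation(self):
        gmap = GenomeMap(n_chromosomes=1, bp_per_chromosome=2e6)
        pool = simulate_base_genomes(
            ne=20, n_generations=120, mu=2e-6, genome_map=gmap,
            n_haplotypes=40, seed=7, backend="forward",
        )
        assert pool.n_sites > 0
        f = pool.frequencies
        assert np.all((f > 0) & (f < 1))
        pi = pool.mean_pairwise_heterozygosity_per_bp()
        assert pi == pytest.approx(4 * 20 * 2e-6, rel=0.6)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_base_genomes(ne=1)
        with pytest.raises(ValueError):
            simulate_base_genomes(mu=-1e-9)


class TestSamplePanels:
    @pytest.fixture(scope="class")
    def pool(self):
        return simulate_base_genomes(ne=80, mu=2e-8, genome_map=GenomeMap(3, 1.0, 40e6),
                                     n_haplotypes=60, seed=11)

    def test_exhaustive_partition(self, pool):
        sizes = {"M": 2, "Q": 2, "N": 2, "D": 2}
        sub_pool = pool
        # restrict to exactly 8 sites by faking a smaller pool
        from gocsim.genome import HaplotypePool

        sub_pool = HaplotypePool(
            pool.haplotypes[:, :8], pool.chromosome[:8], pool.position_bp[:8], pool.genome_map
        )
        panels = sample_panels(sub_pool, sizes, seed=0)
        used = np.concatenate([panels.pool_site_index[panels.panel_index[k]] for k in sizes])
        assert sorted(used) == list(range(8))

    def test_disjoint_panels(self, pool):
        panels = sample_panels(pool, {"M": 50, "Q": 50, "N": 50, "D": 50}, seed=1)
        sets = [set(panels.pool_site_index[panels.panel_index[k]]) for k in "MQND"]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not sets[i] & sets[j]

    def test_sizing_error_names_shortfall(self, pool):
        need = pool.n_sites + 100
        with pytest.raises(ValueError, match="insufficient segregating sites"):
            sample_panels(pool, {"M": need}, seed=2)

    def test_panel_maf_matches_pool_distribution(self, pool):
        """Uniform sampling: panel MAF indistinguishable from the pool's."""
        panels = sample_panels(pool, {"N": 150}, seed=3)
        f_pool = np.minimum(pool.frequencies, 1 - pool.frequencies)
        idx = panels.pool_site_index[panels.panel_index["N"]]
        f_panel = f_pool[idx]
        stat = stats.ks_2samp(f_pool, f_panel)
        assert stat.pvalue > 0.05

    def test_p0_strictly_polymorphic(self, pool):
        panels = sample_panels(pool, {"M": 100}, seed=4)
        assert np.all((panels.p0 > 0) & (panels.p0 < 1))


class TestMeiosis:
    def _parent(self, panels):
        rng = np.random.default_rng(0)
        L = panels.n_tracked
        alleles = rng.integers(0, 2, size=(2, L)).astype(np.int8)
        segments = [
            [(c, 0.0, 1.0, h) for c in range(3)] for h in (0, 1)
        ]
        return alleles, segments

    @pytest.fixture(scope="class")
    def panels(self):
        pool = simulate_base_genomes(ne=80, mu=2e-8, genome_map=GenomeMap(3, 1.0, 40e6),
                                     n_haplotypes=60, seed=21)
        return sample_panels(pool, {"M": 90}, seed=1)

    def test_zero_map_length_returns_parental_haplotype(self, panels):
        gmap = GenomeMap(3, morgans_per_chromosome=0.0, bp_per_chromosome=40e6)
        alleles, segments = self._parent(panels)
        pz = panels
        # with zero map length positions collapse to 0; crossover count is 0
        g = meiosis(alleles, segments, pz, gmap, seed=5)
        per_chrom_ids = {s[0]: s[3] for s in g.segments}
        for c, hap in per_chrom_ids.items():
            mask = panels.chromosome == c
            assert np.array_equal(g.alleles[mask], alleles[hap, mask])

    def test_alleles_always_parental(self, panels):
        gmap = GenomeMap(3, 1.0, 40e6)
        alleles, segments = self._parent(panels)
        for seed in range(10):
            g = meiosis(alleles, segments, panels, gmap, seed=seed)
            ok = (g.alleles == alleles[0]) | (g.alleles == alleles[1])
            assert ok.all()

    def test_descent_mosaic_tiles_genome(self, panels):
        gmap = GenomeMap(3, 1.0, 40e6)
        alleles, segments = self._parent(panels)
        g = meiosis(alleles, segments, panels, gmap, seed=3)
        for c in range(3):
            segs = sorted(g.segments_on(c), key=lambda s: s[1])
            assert segs[0][1] == 0.0
            assert segs[-1][2] == pytest.approx(1.0)
            for a, b in zip(segs, segs[1:]):
                assert b[1] == pytest.approx(a[2])
            total = sum(s[2] - s[1] for s in segs)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_mean_crossovers_equals_map_length(self, panels):
        """Poisson(1 Morgan) per chromosome: boundaries average to map length."""
        gmap = GenomeMap(3, 1.0, 40e6)
        alleles, segments = self._parent(panels)
        rng = np.random.default_rng(9)
        n_x = [
            len(meiosis(alleles, segments, panels, gmap, seed=rng).segments) - 3
            for _ in range(800)
        ]
        assert np.mean(n_x) == pytest.approx(3.0, abs=0.25)

    def test_batch_strands_match_poisson_parity(self, panels):
        """Markov flips reproduce Poisson-crossover strand statistics."""
        L = panels.n_tracked
        parent_alleles = np.zeros((1, 2, L), dtype=np.int8)
        parent_alleles[0, 1] = 1  # haplotype id readable from allele
        r = recombination_fractions(panels.chromosome, panels.position_morgan)
        rng = np.random.default_rng(13)
        al, _ = sample_gametes_batch(parent_alleles, None, np.zeros(4000, dtype=int), r, rng)
        # each locus: both strands equally likely
        assert np.allclose(al.mean(axis=0), 0.5, atol=0.05)
        # switch frequency between distant loci within a chromosome ~ Haldane
        mask = panels.chromosome == 0
        first, last = np.flatnonzero(mask)[[0, -1]]
        d = panels.position_morgan[last] - panels.position_morgan[first]
        expect = 0.5 * (1 - np.exp(-2 * d))
        observed = (al[:, first] != al[:, last]).mean()
        assert observed == pytest.approx(expect, abs=0.04)


class TestRecombinationFractions:
    def test_chromosome_starts_are_half(self):
        chrom = np.array([0, 0, 1, 1])
        pos = np.array([0.1, 0.4, 0.05, 0.6])
        r = recombination_fractions(chrom, pos)
        assert r[0] == 0.5 and r[2] == 0.5
        assert r[1] == pytest.approx(0.5 * (1 - np.exp(-0.6)))
        assert r[3] == pytest.approx(0.5 * (1 - np.exp(-1.1)))
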