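"""Relationship matrices: pedigree, VanRaden variants, ROH, IBD, PD repair."""

import numpy as np
import pytest

from gocsim.gebv import centered, standardize
from gocsim.genome import GenomeMap
from gocsim.relmat import (
    f_roh,
    g_05,
    g_ip,
    g_la_hmm,
    g_la_true,
    g_roh,
    g_vr1,
    g_vr2,
    make_positive_definite,
    pedigree_A,
    propagate_A,
    shared_segments,
)


class TestPedigreeA:
    def test_founders_are_identity(self):
        A = pedigree_A([-1, -1, -1], [-1, -1, -1]).values
        assert np.array_equal(A, np.eye(3))

    def test_full_sibs_related_by_half(self):
        # 0,1 founders; 2,3 their full sibs
        A = pedigree_A([-1, -1, 0, 0], [-1, -1, 1, 1]).values
        assert A[2, 3] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)

    def test_full_sib_mating_gives_quarter_inbreeding(self):
        # 4 is offspring of full sibs 2 x 3: F = 1/4 by path counting
        A = pedigree_A([-1, -1, 0, 0, 2], [-1, -1, 1, 1, 3]).values
        assert A[4, 4] == pytest.approx(1.25)

    def test_child_before_parent_rejected(self):
        with pytest.raises(ValueError):
            pedigree_A([1, -1], [-1, -1])

    def test_propagation_matches_tabular_method(self, rng):
        n0, n1, n2 = 6, 10, 12
        s1 = rng.integers(0, n0, size=n1)
        d1 = rng.integers(0, n0, size=n1)
        s2 = rng.integers(0, n1, size=n2)
        d2 = rng.integers(0, n1, size=n2)
        sire = np.concatenate([np.full(n0, -1), s1, s2 + n0])
        dam = np.concatenate([np.full(n0, -1), d1, d2 + n0])
        A_tab = pedigree_A(sire, dam).values
        A1 = propagate_A(np.eye(n0), s1, d1)
        A2 = propagate_A(A1, s2, d2)
        assert np.allclose(A2, A_tab[n0 + n1 :, n0 + n1 :], atol=1e-12)


class TestVanRadenMatrices:
    def test_identical_individuals_identical_rows(self, rng):
        dos = rng.integers(0, 3, size=(4, 30))
        dos[1] = dos[0]
        p0 = rng.uniform(0.2, 0.8, size=30)
        G = g_vr2(standardize(dos, p0).X).values
        assert np.allclose(G[0], G[1])
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_single_locus_hand_value(self):
        # one locus, p0 = 0.5, dosages (0, 2): X = (-1, 1)/sqrt(0.5)
        X = standardize(np.array([[0], [2]]), np.array([0.5])).X
        G = g_vr2(X).values
        assert np.allclose(G, np.array([[2.0, -2.0], [-2.0, 2.0]]))

    def test_mean_diagonal_near_one_under_hwe(self, rng):
        p = rng.uniform(0.1, 0.9, size=400)
        dos = rng.binomial(2, p, size=(200, 400))
        G = g_vr2(standardize(dos, p).X).values
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)

    def test_vr1_equals_vr2_for_single_locus(self, rng):
        dos = rng.integers(0, 3, size=(5, 1))
        p0 = np.array([0.3])
        G1 = g_vr1(centered(dos, p0), p0).values
        G2 = g_vr2(standardize(dos, p0).X).values
        assert np.allclose(G1, G2)

    def test_vr1_equals_vr2_when_all_p_half(self, rng):
        dos = rng.integers(0, 3, size=(6, 20))
        p0 = np.full(20, 0.5)
        assert np.allclose(
            g_vr1(centered(dos, p0), p0).values,
            g_vr2(standardize(dos, p0).X).values,
        )

    def test_vr1_is_heterozygosity_weighted_mean_of_single_locus_vr2(self, rng):
        """G_VR1 re-weights single-locus estimates by 2 p0 (1 - p0)."""
        dos = rng.integers(0, 3, size=(5, 12))
        p0 = rng.uniform(0.1, 0.9, size=12)
        w = 2 * p0 * (1 - p0)
        per_locus = np.stack(
            [g_vr2(standardize(dos[:, [k]], p0[[k]]).X).values for k in range(12)]
        )
        weighted = np.tensordot(w / w.sum(), per_locus, axes=1)
        assert np.allclose(weighted, g_vr1(centered(dos, p0), p0).values, atol=1e-12)

    def test_expectation_over_meiosis_equals_pedigree(self, rng):
        """E[G_VR2] = A for neutral unlinked loci (two-generation check)."""
        L = 4000
        p0 = rng.uniform(0.2, 0.8, size=L)
        founders = rng.binomial(1, p0, size=(4, 2, L)).astype(np.int8)
        # offspring: 0x1 full sibs (2) and 2x3 full sibs (2)
        def gamete(ind):
            pick = rng.integers(0, 2, size=L)
            return founders[ind, pick, np.arange(L)]
        offs = np.stack([
            np.stack([gamete(0), gamete(1)]),
            np.stack([gamete(0), gamete(1)]),
            np.stack([gamete(2), gamete(3)]),
        ])
        dos = np.concatenate([founders.sum(axis=1), offs.sum(axis=1)])
        G = g_vr2(standardize(dos, p0).X).values
        assert G[4, 5] == pytest.approx(0.5, abs=0.08)   # full sibs
        assert G[4, 6] == pytest.approx(0.0, abs=0.08)   # unrelated
        assert G[4, 4] == pytest.approx(1.0, abs=0.08)


class TestHomozygosityMatrices:
    def test_fully_heterozygous_row_is_zero(self):
        dos = np.array([[1, 1, 1], [0, 2, 1]])
        G = g_05(dos).values
        assert np.allclose(G[0], 0.0)

    def test_identical_fully_homozygous_pair(self):
        dos = np.array([[0, 2, 0], [0, 2, 0]])
        G = g_05(dos).values
        assert np.allclose(G, 2.0)

    def test_diagonal_is_twice_homozygous_fraction(self, rng):
        dos = rng.integers(0, 3, size=(10, 40))
        G = g_05(dos).values
        hom_frac = (dos != 1).mean(axis=1)
        assert np.allclose(np.diag(G), 2 * hom_frac)


class TestIntensityMatrix:
    def test_zero_row_when_frequencies_match_base(self):
        p0 = np.array([0.5, 0.25])
        dos = np.array([[1, 1], [2, 0]])  # ind 0: m/2 = p0 at locus 0 only
        p0_exact = np.array([0.5, 0.5])
        G = g_ip(np.array([[1, 1]]), p0_exact).values
        assert np.allclose(G, 0.0)

    def test_single_locus_arcsine_value(self):
        # p0 = 1/4, dosage 2: iota = 2[arcsin(1) - arcsin(1/2)] = 2 pi / 3
        from gocsim.relmat import angular_scores

        iota = angular_scores(np.array([[2]]), np.array([0.25]))
        assert iota[0, 0] == pytest.approx(2 * np.pi / 3, abs=1e-12)

    def test_first_order_agreement_with_standardized_change(self):
        """Near p0 the angular score matches dp / sqrt(p0 (1 - p0))."""
        from gocsim.relmat import angular_scores

        p0 = np.array([0.3])
        for dp in (0.01, -0.01, 0.02):
            m = np.array([[2 * (0.3 + dp)]])
            iota = angular_scores(m, p0)[0, 0]
            assert iota == pytest.approx(dp / np.sqrt(0.3 * 0.7), rel=0.05)


class TestSharedSegments:
    GMAP = GenomeMap(n_chromosomes=2, bp_per_chromosome=100e6)

    def _grid(self, per_chrom=50):
        chrom = np.repeat([0, 1], per_chrom)
        pos = np.tile(np.linspace(1e6, 99e6, per_chrom), 2)
        return chrom, pos

    def test_identical_haplotypes_cover_genome(self):
        chrom, pos = self._grid()
        h = np.ones(100, dtype=np.int8)
        segs = shared_segments(h, h, chrom, pos, self.GMAP, min_length_mb=7)
        assert len(segs) == 2
        total = sum(s.length_bp for s in segs)
        assert total == pytest.approx(self.GMAP.total_bp)

    def test_alternating_disagreement_yields_nothing(self):
        chrom, pos = self._grid()
        a = np.zeros(100, dtype=np.int8)
        b = np.arange(100, dtype=np.int8) % 2
        segs = shared_segments(a, b, chrom, pos, self.GMAP, min_length_mb=7)
        assert segs == []

    def test_matches_brute_force_scan(self, rng):
        """Segment loci match maximal agreement runs found exhaustively."""
        chrom, pos = self._grid()
        left_edge = {0: 0.0, 1: 0.0}
        a = rng.integers(0, 2, size=100).astype(np.int8)
        b = np.where(rng.random(100) < 0.7, a, 1 - a).astype(np.int8)
        segs = shared_segments(a, b, chrom, pos, self.GMAP, min_length_mb=5)
        # brute force: all maximal runs of agreement
        runs = []
        i = 0
        while i < 100:
            if a[i] == b[i]:
                j = i
                while j + 1 < 100 and chrom[j + 1] == chrom[i] and a[j + 1] == b[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        # every emitted segment corresponds to a run spanning >= threshold
        starts = {(s.chromosome, round(s.start_bp)) for s in segs}
        for (i, j) in runs:
            lo = 0.0 if i == 0 or chrom[i - 1] != chrom[i] else 0.5 * (pos[i - 1] + pos[i])
            hi = (
                self.GMAP.bp_per_chromosome
                if j == 99 or chrom[j + 1] != chrom[j]
                else 0.5 * (pos[j] + pos[j + 1])
            )
            if hi - lo >= 5e6:
                assert (chrom[i], round(lo)) in starts
        assert len(segs) == sum(
            1 for (i, j) in runs
            if (self.GMAP.bp_per_chromosome if j == 99 or chrom[j+1] != chrom[j] else 0.5*(pos[j]+pos[j+1]))
             - (0.0 if i == 0 or chrom[i-1] != chrom[i] else 0.5*(pos[i-1]+pos[i])) >= 5e6
        )


class TestGRoh:
    GMAP = GenomeMap(n_chromosomes=1, bp_per_chromosome=140e6)

    def test_homozygous_clones(self):
        chrom = np.zeros(20, dtype=np.int64)
        pos = np.linspace(1e6, 139e6, 20)
        alleles = np.zeros((2, 2, 20), dtype=np.int8)
        G = g_roh(alleles, chrom, pos, self.GMAP, min_length_mb=7).values
        assert G[0, 0] == pytest.approx(2.0)
        assert G[0, 1] == pytest.approx(1.0)

    def test_unshared_pair_is_zero(self):
        chrom = np.zeros(20, dtype=np.int64)
        pos = np.linspace(1e6, 139e6, 20)
        a = np.zeros((2, 20), dtype=np.int8)
        b = np.ones((2, 20), dtype=np.int8)
        alleles = np.stack([a, b]).astype(np.int8)
        G = g_roh(alleles, chrom, pos, self.GMAP, min_length_mb=7).values
        assert G[0, 1] == 0.0

    def test_f_roh_known_tract_fraction(self):
        """A single ~10 Mb homozygous tract on a 140 Mb chromosome of a
        10-chromosome genome gives F_ROH = 10/1400."""
        gmap = GenomeMap(n_chromosomes=10, bp_per_chromosome=140e6)
        per = 1401
        chrom = np.repeat(np.arange(10), per).astype(np.int64)
        pos = np.tile(np.linspace(0.5e6, 139.5e6, per), 10)
        rng = np.random.default_rng(0)
        hapA = rng.integers(0, 2, size=10 * per).astype(np.int8)
        hapB = 1 - hapA  # disagree everywhere
        # make loci between 60 and 70 Mb of chromosome 3 homozygous
        mask = (chrom == 3) & (pos >= 60e6) & (pos <= 70e6)
        hapB[mask] = hapA[mask]
        f = f_roh(np.stack([hapA, hapB]), chrom, pos, gmap, min_length_mb=7)
        assert f == pytest.approx(10e6 / 1400e6, rel=0.05)


class TestGLa:
    def test_generation_zero_identity(self):
        origin = np.arange(8, dtype=np.int16).reshape(4, 2, 1).repeat(5, axis=2)
        G = g_la_true(origin).values
        assert np.allclose(G, np.eye(4))

    def test_diagonal_is_one_plus_ibd_fraction(self, rng):
        origin = rng.integers(0, 4, size=(3, 2, 40)).astype(np.int16)
        G = g_la_true(origin).values
        for i in range(3):
            f = (origin[i, 0] == origin[i, 1]).mean()
            assert G[i, i] == pytest.approx(1 + f)

    def test_full_sib_expectation_half(self, tiny_shared, rng):
        """Mean G_LA over many meioses approaches the pedigree value 0.5."""
        from gocsim.population import reproduce

        shared = tiny_shared
        n_off = 300
        # parents from different full-sib families (unrelated, non-inbred)
        off = reproduce(
            shared.gen1, np.full(n_off, 2), np.full(n_off, 97), shared.panels, rng
        )
        grid = shared.panels.panel_index["M"][::4]
        G = g_la_true(off.origin[:, :, grid]).values
        off_diag = G[np.triu_indices(n_off, 1)]
        assert off_diag.mean() == pytest.approx(0.5, abs=0.05)

    def test_hmm_estimator_close_to_true_descent(self, rng):
        """Marker-HMM posterior IBD approaches the exact descent IBD."""
        # dense map on 2 chromosomes, small 3-generation pedigree
        L = 140
        chrom = np.repeat([0, 1], L // 2).astype(np.int64)
        pos = np.tile(np.linspace(0.005, 0.995, L // 2), 2)
        p = rng.uniform(0.2, 0.8, size=L)
        n0 = 6
        founders = rng.binomial(1, p, size=(n0, 2, L)).astype(np.int8)
        origin0 = np.broadcast_to(
            np.arange(2 * n0, dtype=np.int16).reshape(n0, 2, 1), founders.shape
        ).copy()

        from gocsim.genome import recombination_fractions, sample_gametes_batch

        r = recombination_fractions(chrom, pos)
        def make_gen(par_alleles, par_origin, sire, dam):
            pa, po = sample_gametes_batch(par_alleles, par_origin, sire, r, rng)
            ma, mo = sample_gametes_batch(par_alleles, par_origin, dam, r, rng)
            return np.stack([pa, ma], 1), np.stack([po, mo], 1)

        s1 = np.array([0, 0, 1, 2, 3]); d1 = np.array([4, 4, 5, 5, 4])
        a1, o1 = make_gen(founders, origin0, s1, d1)
        s2 = np.array([0, 1, 2]); d2 = np.array([3, 4, 4])
        a2, o2 = make_gen(a1, o1, s2, d2)

        G_true = g_la_true(o2).values
        G_hmm = g_la_hmm(
            [(None, None), (s1, d1), (s2, d2)], chrom, pos, [founders, a1, a2]
        ).values
        assert np.abs(G_hmm - G_true).mean() < 0.02


class TestMakePositiveDefinite:
    def test_identity_gets_alpha(self):
        from gocsim.relmat import RelationshipMatrix

        G = RelationshipMatrix(np.eye(3), name="G_VR2", kind="drift")
        out = make_positive_definite(G)
        assert np.allclose(out.values, 1.01 * np.eye(3))
        assert out.alpha == 0.01

    def test_rank_deficient_crossproduct_repaired(self, rng):
        from gocsim.relmat import RelationshipMatrix
        from scipy import linalg

        Z = rng.standard_normal((6, 10))
        Z -= Z.mean(axis=0)  # centring introduces a zero eigenvalue
        G = RelationshipMatrix(Z @ Z.T / 10, name="G_VR2", kind="drift")
        out = make_positive_definite(G)
        linalg.cholesky(out.values)  # must not raise

    def test_escalation_stops_at_first_sufficient_alpha(self):
        """Min eigenvalue -0.2: schedule 0.05, 0.1, 0.2, 0.4 ends at 0.4."""
        from gocsim.relmat import RelationshipMatrix

        Q = np.linalg.qr(np.random.default_rng(1).standard_normal((4, 4)))[0]
        M = Q @ np.diag([1.0, 0.5, 0.3, -0.2]) @ Q.T
        G = RelationshipMatrix(M, name="G_ROH", kind="hybrid")
        out = make_positive_definite(G)
        assert out.alpha == pytest.approx(0.4)

    def test_ibd_matrices_untouched(self):
        from gocsim.relmat import RelationshipMatrix

        A = RelationshipMatrix(np.eye(4) + 0.1, name="A", kind="IBD")
        out = make_positive_definite(A)
        assert out.alpha == 0.0
        assert np.allclose(out.values, A.values)
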