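"""Numba kernels for the pairwise relationship computations."""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def ibd_fraction_matrix(origin: np.ndarray) -> np.ndarray:
    """True-descent IBD relationship from founder-origin codes.

    ``origin`` is (n, 2, L) integer founder-gamete identifiers at the
    evaluation loci.  Entry (i, j) is 2 f_ij with f_ij the mean over loci of
    the probability that alleles drawn at random from i and j descend from
    the same founder gamete; the diagonal is 1 + F_IBD.
    """
    n, _, L = origin.shape
    G = np.empty((n, n))
    for i in range(n):
        m_self = 0
        for l in range(L):
            if origin[i, 0, l] == origin[i, 1, l]:
                m_self += 1
        G[i, i] = 1.0 + m_self / L
        for j in range(i + 1, n):
            m = 0
            for l in range(L):
                a0 = origin[i, 0, l]
                a1 = origin[i, 1, l]
                b0 = origin[j, 0, l]
                b1 = origin[j, 1, l]
                if a0 == b0:
                    m += 1
                if a0 == b1:
                    m += 1
                if a1 == b0:
                    m += 1
                if a1 == b1:
                    m += 1
            G[i, j] = G[j, i] = 2.0 * m / (4.0 * L)
    return G


@numba.njit(cache=True)
def shared_fraction(hapA, hapB, chrom, left, right, min_len):
    """Total length covered by agreement runs spanning >= min_len.

    ``left``/``right`` are the interval edges owned by each locus (midpoints
    between neighbours, chromosome ends at the extremes).  A maximal run of
    agreeing loci covers [left[first], right[last]] and contributes its length
    when >= min_len.
    """
    L = hapA.shape[0]
    total = 0.0
    run_open = False
    run_start = 0.0
    run_end = 0.0
    run_chrom = -1
    for l in range(L):
        agree = hapA[l] == hapB[l]
        if run_open and (chrom[l] != run_chrom or not agree):
            if run_end - run_start >= min_len:
                total += run_end - run_start
            run_open = False
        if agree:
            if not run_open:
                run_open = True
                run_start = left[l]
                run_chrom = chrom[l]
            run_end = right[l]
    if run_open and run_end - run_start >= min_len:
        total += run_end - run_start
    return total


@numba.njit(cache=True)
def roh_matrix(alleles, chrom, left, right, min_len, total_len):
    """Pairwise ROH-sharing relationship matrix.

    ``alleles`` is (n, 2, L).  Off-diagonal (i, j) averages the covered genome
    fraction over the four haplotype pairings of i and j; the diagonal is
    1 + F_ROH of the individual's own two haplotypes.
    """
    n = alleles.shape[0]
    G = np.empty((n, n))
    for i in range(n):
        G[i, i] = 1.0 + shared_fraction(
            alleles[i, 0], alleles[i, 1], chrom, left, right, min_len
        ) / total_len
        for j in range(i + 1, n):
            s = 0.0
            for a in range(2):
                for b in range(2):
                    s += shared_fraction(
                        alleles[i, a], alleles[j, b], chrom, left, right, min_len
                    )
            G[i, j] = G[j, i] = 0.25 * s / total_len
    return G
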