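"""Relationship matrices for diversity management.

Seven candidate-by-candidate matrices are supported, falling into three
classes by what they measure:

* drift (squared standardized allele-frequency change): ``G_VR2`` = XX'/N
  (VanRaden method 2), ``G_VR1`` = ZZ'/sum(H0) (method 1), and the
  intensity-based ``G_i(p)`` built on the angular (arcsine) transform of
  frequencies, which integrates di/dp = [p(1-p)]^(-1/2);
* homozygosity: ``G_0.5`` (reference frequencies fixed at 0.5, proportional
  to expected progeny homozygosity) and the hybrid ``G_ROH`` built from runs
  of homozygosity / shared haplotype segments;
* IBD relative to the generation-0 base: the pedigree matrix ``A`` and the
  marker/descent-based ``G_LA``.

Cross-product matrices (XX' types) are positive semi-definite with one zero
eigenvalue from centring and are repaired by adding alpha = 0.01 to the
diagonal; ``G_ROH`` can be indefinite and uses an escalating-alpha repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from ._kernels import ibd_fraction_matrix, roh_matrix, shared_fraction
from .genome import GenomeMap

__all__ = [
    "RelationshipMatrix",
    "RohSegment",
    "pedigree_A",
    "propagate_A",
    "g_vr2",
    "g_vr1",
    "g_05",
    "g_ip",
    "angular_scores",
    "shared_segments",
    "g_roh",
    "g_la_true",
    "g_la_hmm",
    "make_positive_definite",
]


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix with provenance metadata."""

    values: np.ndarray
    name: str                      # e.g. "G_VR2", "A"
    kind: str                      # drift | homozygosity | hybrid | IBD
    panel: str | None = None
    alpha: float | None = None     # diagonal repair actually applied
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class RohSegment:
    """A shared (homozygous) haplotype segment."""

    chromosome: int
    start_bp: float
    end_bp: float

    @property
    def length_bp(self) -> float:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def pedigree_A(sire: np.ndarray, dam: np.ndarray) -> RelationshipMatrix:
    """Wright's numerator relationship matrix by the tabular method.

    ``sire``/``dam`` hold the within-array index of each parent, or -1 for a
    generation-0 founder (treated unrelated and non-inbred).  Parents must
    precede their offspring.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = sire.shape[0]
    for i in range(n):
        if sire[i] >= i or dam[i] >= i:
            raise ValueError(f"individual {i} precedes a parent")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(A, name="A", kind="IBD", alpha=0.0)


def propagate_A(A_parents: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Relationship matrix of one offspring generation from its parents'.

    Equivalent to the tabular method when generations are discrete: off-
    diagonals average the four parent-pair relationships, the diagonal is
    1 + a(sire, dam)/2.
    """
    half = 0.5 * (A_parents[sire, :] + A_parents[dam, :])   # (n_off, n_par)
    A_off = 0.5 * (half[:, sire] + half[:, dam])
    np.fill_diagonal(A_off, 1.0 + 0.5 * A_parents[sire, dam])
    return A_off


# ---------------------------------------------------------------------------
# allele-frequency based matrices
# ---------------------------------------------------------------------------

def g_vr2(X: np.ndarray, panel: str | None = None) -> RelationshipMatrix:
    """VanRaden method 2 on standardized genotypes: XX' / N_SNP."""
    X = np.asarray(X, dtype=np.float64)
    G = X @ X.T / X.shape[1]
    return RelationshipMatrix(G, name="G_VR2", kind="drift", panel=panel)


def g_vr1(Z: np.ndarray, p0: np.ndarray, panel: str | None = None) -> RelationshipMatrix:
    """VanRaden method 1 on centred genotypes: ZZ' / sum_k 2 p0k (1 - p0k)."""
    Z = np.asarray(Z, dtype=np.float64)
    h0 = 2.0 * np.asarray(p0) * (1.0 - np.asarray(p0))
    G = Z @ Z.T / h0.sum()
    return RelationshipMatrix(G, name="G_VR1", kind="drift", panel=panel)


def g_05(dosages: np.ndarray, panel: str | None = None) -> RelationshipMatrix:
    """Homozygosity-based matrix: reference frequencies fixed at 0.5.

    Entries are (1/N) sum_k 2 (m_ik - 1)(m_jk - 1); element (i, j) is
    proportional to the expected homozygosity of progeny of i and j.
    """
    m = np.asarray(dosages, dtype=np.float64) - 1.0
    G = 2.0 * (m @ m.T) / m.shape[1]
    return RelationshipMatrix(G, name="G_0.5", kind="homozygosity", panel=panel)


def angular_scores(dosages: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Cumulative selection-intensity scores via the angular transform.

    iota_ik = 2 [arcsin sqrt(m_ik / 2) - arcsin sqrt(p0k)] integrates
    di/dp = [p (1 - p)]^(-1/2), so squared scores approximate squared total
    intensities applied to each locus; to first order around p0 this matches
    the G_VR2 standardization delta_p / sqrt(p0 (1 - p0)).
    """
    m = np.asarray(dosages, dtype=np.float64)
    p0 = np.asarray(p0, dtype=np.float64)
    return 2.0 * (np.arcsin(np.sqrt(m / 2.0)) - np.arcsin(np.sqrt(p0))[None, :])


def g_ip(dosages: np.ndarray, p0: np.ndarray, panel: str | None = None) -> RelationshipMatrix:
    """Intensity-based relationship matrix G_i(p) = Upsilon Upsilon' / N_SNP."""
    U = angular_scores(dosages, p0)
    G = U @ U.T / U.shape[1]
    return RelationshipMatrix(G, name="G_i(p)", kind="drift", panel=panel)


# ---------------------------------------------------------------------------
# ROH / shared segments
# ---------------------------------------------------------------------------

def _locus_edges(chrom: np.ndarray, pos_bp: np.ndarray, genome_map: GenomeMap):
    """bp interval owned by each locus: midpoints between neighbours,
    chromosome ends at the extremes."""
    L = chrom.shape[0]
    left = np.empty(L)
    right = np.empty(L)
    mid = 0.5 * (pos_bp[:-1] + pos_bp[1:])
    same = chrom[:-1] == chrom[1:]
    left[0] = 0.0
    left[1:] = np.where(same, mid, 0.0)
    right[-1] = genome_map.bp_per_chromosome
    right[:-1] = np.where(same, mid, genome_map.bp_per_chromosome)
    return left, right


def shared_segments(
    hapA: np.ndarray,
    hapB: np.ndarray,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    genome_map: GenomeMap,
    min_length_mb: float = 7.0,
) -> list[RohSegment]:
    """Maximal runs of allelic agreement between two haplotypes.

    A run covers the bp interval owned by its loci (midpoints between
    neighbouring loci, chromosome ends at the extremes) and is emitted when it
    spans at least ``min_length_mb``.  No heterozygous-call allowance is made.
    """
    if hapA.shape != hapB.shape:
        raise ValueError("haplotypes must have equal length")
    left, right = _locus_edges(chrom, pos_bp, genome_map)
    min_len = min_length_mb * 1e6
    segs = []
    run = None  # (chrom, start, end)
    for l in range(hapA.shape[0]):
        agree = hapA[l] == hapB[l]
        if run is not None and (chrom[l] != run[0] or not agree):
            if run[2] - run[1] >= min_len:
                segs.append(RohSegment(int(run[0]), run[1], run[2]))
            run = None
        if agree:
            if run is None:
                run = (chrom[l], left[l], right[l])
            else:
                run = (run[0], run[1], right[l])
    if run is not None and run[2] - run[1] >= min_len:
        segs.append(RohSegment(int(run[0]), run[1], run[2]))
    return segs


def g_roh(
    alleles: np.ndarray,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    genome_map: GenomeMap,
    min_length_mb: float = 7.0,
    panel: str | None = None,
) -> RelationshipMatrix:
    """ROH-sharing relationship matrix (not guaranteed positive semi-definite).

    Off-diagonal (i, j): mean over the four haplotype pairings of the genome
    fraction covered by shared segments; diagonal: 1 + F_ROH of the
    individual.  ``alleles`` is (n, 2, L) phased at the panel loci.
    """
    left, right = _locus_edges(chrom, pos_bp, genome_map)
    G = roh_matrix(
        np.ascontiguousarray(alleles),
        chrom.astype(np.int64),
        left,
        right,
        min_length_mb * 1e6,
        genome_map.total_bp,
    )
    return RelationshipMatrix(
        G, name="G_ROH", kind="hybrid", panel=panel, meta={"min_length_mb": min_length_mb}
    )


def f_roh(
    alleles_i: np.ndarray,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    genome_map: GenomeMap,
    min_length_mb: float = 7.0,
) -> float:
    """Genome fraction of one individual's two haplotypes in runs of homozygosity."""
    left, right = _locus_edges(chrom, pos_bp, genome_map)
    cov = shared_fraction(
        np.ascontiguousarray(alleles_i[0]),
        np.ascontiguousarray(alleles_i[1]),
        chrom.astype(np.int64),
        left,
        right,
        min_length_mb * 1e6,
    )
    return float(cov / genome_map.total_bp)


# ---------------------------------------------------------------------------
# IBD / linkage analysis
# ---------------------------------------------------------------------------

def g_la_true(origin: np.ndarray, panel: str | None = None) -> RelationshipMatrix:
    """IBD relationship from the simulator's founder-descent codes (exact).

    ``origin`` is (n, 2, L) founder-gamete identifiers at the evaluation loci
    (typically a thinned grid of the management panel).  Generation-0 gametes
    are mutually non-IBD, so generation-0 individuals get diagonal 1 and
    off-diagonal 0, as in the pedigree matrix.
    """
    G = ibd_fraction_matrix(np.ascontiguousarray(origin))
    return RelationshipMatrix(G, name="G_LA", kind="IBD", panel=panel, alpha=0.0)


def _gamete_posterior(gamete_alleles, parent_haps, r):
    """Posterior P(parental strand = 0) along one gamete by forward-backward.

    Two-state inhomogeneous Markov chain (grand-paternal / grand-maternal
    origin); transition probability between consecutive loci is the Haldane
    recombination fraction of the interval; emissions compare the gamete
    allele with the phased parental alleles.
    """
    L = gamete_alleles.shape[0]
    eps = 1e-9
    e = np.where(parent_haps == gamete_alleles[None, :], 1.0, eps)  # (2, L)
    fwd = np.empty((L, 2))
    fwd[0] = 0.5 * e[:, 0]
    for l in range(1, L):
        stay, flip = 1.0 - r[l], r[l]
        fwd[l, 0] = e[0, l] * (fwd[l - 1, 0] * stay + fwd[l - 1, 1] * flip)
        fwd[l, 1] = e[1, l] * (fwd[l - 1, 1] * stay + fwd[l - 1, 0] * flip)
        fwd[l] /= fwd[l].sum()
    bwd = np.empty((L, 2))
    bwd[-1] = 1.0
    for l in range(L - 2, -1, -1):
        stay, flip = 1.0 - r[l + 1], r[l + 1]
        bwd[l, 0] = e[0, l + 1] * bwd[l + 1, 0] * stay + e[1, l + 1] * bwd[l + 1, 1] * flip
        bwd[l, 1] = e[1, l + 1] * bwd[l + 1, 1] * stay + e[0, l + 1] * bwd[l + 1, 0] * flip
        bwd[l] /= bwd[l].sum()
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 0]


def g_la_hmm(states, chrom, pos_morgan, alleles_by_state, panel: str | None = None):
    """Marker-HMM estimator of the linkage-analysis IBD matrix.

    ``states`` is a list of (sire, dam) index-array pairs per generation
    (generation 0 first, entries -1 for founders); ``alleles_by_state`` the
    matching list of (n, 2, L) phased allele arrays at the evaluation loci.
    Parents must be phased (known haplotypes), which holds in simulation.
    Founder-origin probability distributions are propagated generation by
    generation; returns the matrix for the last generation.

    Intended for small pedigrees: memory scales with
    n_gametes x loci x founder gametes.
    """
    from .genome import recombination_fractions

    r = recombination_fractions(chrom, pos_morgan)
    n0 = alleles_by_state[0].shape[0]
    L = alleles_by_state[0].shape[2]
    nF = 2 * n0
    # dists[g][i, h] -> (L, nF) founder distribution of haplotype h of ind i
    dists = np.zeros((n0, 2, L, nF))
    for i in range(n0):
        for h in range(2):
            dists[i, h, :, 2 * i + h] = 1.0
    for g in range(1, len(states)):
        sire, dam = states[g]
        alleles = alleles_by_state[g]
        if alleles_by_state[g - 1] is None:
            raise ValueError("parents must be phased for the marker-HMM estimator")
        n = alleles.shape[0]
        new = np.zeros((n, 2, L, nF))
        par_alleles = alleles_by_state[g - 1]
        for i in range(n):
            for h, parent in ((0, sire[i]), (1, dam[i])):
                post0 = _gamete_posterior(alleles[i, h], par_alleles[parent], r)
                new[i, h] = (
                    post0[:, None] * dists[parent, 0]
                    + (1.0 - post0)[:, None] * dists[parent, 1]
                )
        dists = new
    n = dists.shape[0]
    G = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            f = 0.25 * (
                (dists[i, 0] * dists[j, 0]).sum()
                + (dists[i, 0] * dists[j, 1]).sum()
                + (dists[i, 1] * dists[j, 0]).sum()
                + (dists[i, 1] * dists[j, 1]).sum()
            ) / L
            if i == j:
                G[i, i] = 1.0 + (dists[i, 0] * dists[i, 1]).sum() / L
            else:
                G[i, j] = G[j, i] = 2.0 * f
    return RelationshipMatrix(G, name="G_LA", kind="IBD", panel=panel, alpha=0.0, meta={"estimator": "hmm"})


# ---------------------------------------------------------------------------
# positive-definiteness repair
# ---------------------------------------------------------------------------

_POLICY_BY_NAME = {
    "G_VR1": "add_alpha",
    "G_VR2": "add_alpha",
    "G_0.5": "add_alpha",
    "G_i(p)": "add_alpha",
    "A": "none",
    "G_LA": "none",
    "G_ROH": "escalate",
}


def _chol_ok(M: np.ndarray) -> bool:
    try:
        linalg.cholesky(M, lower=True)
        return True
    except linalg.LinAlgError:
        return False


def make_positive_definite(G: RelationshipMatrix, policy: str | None = None) -> RelationshipMatrix:
    """Repair a relationship matrix to positive definiteness.

    Policies: ``add_alpha`` adds 0.01 to the diagonal unconditionally
    (cross-product matrices are semi-definite with a zero eigenvalue from
    centring); ``none`` records alpha = 0 (A and G_LA are already positive
    definite); ``escalate`` starts at alpha = 0.05, tests invertibility by
    Cholesky decomposition, and on failure doubles alpha while alpha < 1,
    otherwise increases it by 1, until the decomposition succeeds.
    """
    pol = policy or _POLICY_BY_NAME.get(G.name, "add_alpha")
    M = np.asarray(G.values, dtype=np.float64)
    M = 0.5 * (M + M.T)
    if pol == "none":
        alpha = 0.0
        out = M
    elif pol == "add_alpha":
        alpha = 0.01
        out = M + alpha * np.eye(M.shape[0])
    elif pol == "escalate":
        alpha = 0.05
        while True:
            out = M + alpha * np.eye(M.shape[0])
            if _chol_ok(out):
                break
            alpha = alpha * 2.0 if alpha < 1.0 else alpha + 1.0
    else:
        raise ValueError(f"unknown policy {pol!r}")
    return RelationshipMatrix(
        out, name=G.name, kind=G.kind, panel=G.panel, alpha=alpha, meta=dict(G.meta)
    )
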