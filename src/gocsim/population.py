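"""Population state for the breeding scheme.

A generation is stored as flat arrays over individuals: phased alleles at the
tracked loci (reference-allele coded), founder-descent origin of every
haplotype (the identifier of the generation-0 gamete each position descends
from), pedigree links, sexes, candidate/test-sib roles, true breeding values
and phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import HaplotypePool, PanelAssignment, recombination_fractions

MALE, FEMALE = 0, 1


@dataclass
class PopulationState:
    """All individuals of one generation."""

    generation: int
    alleles: np.ndarray              # (n, 2, L) int8, allele 1 = reference
    origin: np.ndarray | None        # (n, 2, L) int16 founder-gamete ids
    sire: np.ndarray                 # index into previous generation (-1 for founders)
    dam: np.ndarray
    sex: np.ndarray                  # 0 male / 1 female
    is_candidate: np.ndarray         # bool; test sibs are the complement
    tbv: np.ndarray | None = None
    phenotype: np.ndarray | None = None   # NaN for unphenotyped individuals
    ids: np.ndarray | None = None         # globally unique ids for pedigree export

    def __post_init__(self):
        if self.ids is None:
            self.ids = np.arange(self.n)

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[2]

    def dosages(self, index: np.ndarray | slice = slice(None)) -> np.ndarray:
        """0/1/2 reference-allele counts, (n, n_selected_loci); cached."""
        cache = getattr(self, "_dosage_cache", None)
        if cache is None:
            cache = self.alleles[:, 0, :].astype(np.int16) + self.alleles[:, 1, :]
            self._dosage_cache = cache
        return cache[:, index]

    def panel_frequencies(self, panels: PanelAssignment, name: str) -> np.ndarray:
        idx = panels.panel_index[name]
        return self.dosages(idx).mean(axis=0) / 2.0

    def candidates(self) -> np.ndarray:
        return np.flatnonzero(self.is_candidate)

    def test_sibs(self) -> np.ndarray:
        return np.flatnonzero(~self.is_candidate)


def make_founder_population(
    pool: HaplotypePool,
    n_individuals: int = 2000,
    rng: np.random.Generator | None = None,
    panel_sizes: dict | None = None,
    track_descent: bool = True,
):
    """Create the generation-0 breeding individuals and sample the SNP panels.

    By default the pool is the final generation of a small (Ne = 100)
    historical population, so the founders are produced by one round of
    random mating among the pool individuals: every founder gamete is a
    fresh recombinant of the pool, the expansion a real nucleus founded from
    a small closed population undergoes.  When the pool already holds at
    least ``2 n_individuals`` haplotypes, founder gametes are pool
    haplotypes paired at random instead.  Panels are sampled from sites
    still segregating among these founders, so 0 < p0 < 1 holds for every
    panel locus.  Returns ``(PopulationState, PanelAssignment)``.
    """
    from .genome import sample_gametes_batch, sample_panels

    rng = rng or np.random.default_rng()
    if pool.n_haplotypes >= 2 * n_individuals:
        take = rng.permutation(pool.n_haplotypes)[: 2 * n_individuals]
        founder_all_sites = pool.haplotypes[take]
        founder_dos = (
            founder_all_sites[0::2].astype(np.int16) + founder_all_sites[1::2]
        )
    else:
        n_pool_ind = pool.n_haplotypes // 2
        pool_alleles = pool.haplotypes.reshape(n_pool_ind, 2, pool.n_sites)
        sires = rng.integers(n_pool_ind, size=n_individuals)
        dams = (sires + 1 + rng.integers(n_pool_ind - 1, size=n_individuals)) % n_pool_ind
        r = recombination_fractions(pool.chromosome, pool.position_morgan)
        pat, _ = sample_gametes_batch(pool_alleles, None, sires, r, rng)
        mat, _ = sample_gametes_batch(pool_alleles, None, dams, r, rng)
        founder_all_sites = np.empty((2 * n_individuals, pool.n_sites), dtype=np.int8)
        founder_all_sites[0::2] = pat
        founder_all_sites[1::2] = mat
        founder_dos = pat.astype(np.int16) + mat
    panels = sample_panels(pool, panel_sizes, seed=rng, founder_dosages=founder_dos)
    sub = founder_all_sites[:, panels.pool_site_index]
    # orient alleles so that 1 = the randomly chosen reference allele
    sub = np.where(panels.flipped[None, :], 1 - sub, sub).astype(np.int8)
    alleles = sub.reshape(n_individuals, 2, panels.n_tracked)
    origin = None
    if track_descent:
        origin = np.broadcast_to(
            np.arange(2 * n_individuals, dtype=np.int16).reshape(n_individuals, 2, 1),
            alleles.shape,
        ).copy()
    sex = _balanced_sexes(n_individuals, rng)
    state = PopulationState(
        generation=0,
        alleles=alleles,
        origin=origin,
        sire=np.full(n_individuals, -1, dtype=np.int64),
        dam=np.full(n_individuals, -1, dtype=np.int64),
        sex=sex,
        is_candidate=np.ones(n_individuals, dtype=bool),
        tbv=None,
        phenotype=np.full(n_individuals, np.nan),
    )
    return state, panels


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.empty(n, dtype=np.int8)
    half = n // 2
    sex[:half] = MALE
    sex[half:] = FEMALE
    rng.shuffle(sex)
    return sex


@dataclass
class PedigreeRecorder:
    """Accumulates (id, sire_id, dam_id, generation) rows across generations."""

    ids: list = field(default_factory=list)
    sires: list = field(default_factory=list)
    dams: list = field(default_factory=list)
    generations: list = field(default_factory=list)
    _next_id: int = 0

    def register(self, state: PopulationState, parent_state: PopulationState | None):
        n = state.n
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        state.ids = ids
        if parent_state is None:
            sire_ids = np.full(n, -1, dtype=np.int64)
            dam_ids = np.full(n, -1, dtype=np.int64)
        else:
            sire_ids = parent_state.ids[state.sire]
            dam_ids = parent_state.ids[state.dam]
        self.ids.append(ids)
        self.sires.append(sire_ids)
        self.dams.append(dam_ids)
        self.generations.append(np.full(n, state.generation, dtype=np.int64))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.concatenate(self.ids),
                "sire": np.concatenate(self.sires),
                "dam": np.concatenate(self.dams),
                "generation": np.concatenate(self.generations),
            }
        )


def reproduce(
    parents: PopulationState,
    sire_index: np.ndarray,
    dam_index: np.ndarray,
    panels: PanelAssignment,
    rng: np.random.Generator,
) -> PopulationState:
    """Produce offspring from per-offspring (sire, dam) assignments.

    One gamete per parent via the Markov crossover process at tracked loci.
    """
    from .genome import sample_gametes_batch

    r = recombination_fractions(panels.chromosome, panels.position_morgan)
    pat_alleles, pat_origin = sample_gametes_batch(
        parents.alleles, parents.origin, sire_index, r, rng
    )
    mat_alleles, mat_origin = sample_gametes_batch(
        parents.alleles, parents.origin, dam_index, r, rng
    )
    n = sire_index.shape[0]
    alleles = np.stack([pat_alleles, mat_alleles], axis=1)
    origin = None
    if pat_origin is not None:
        origin = np.stack([pat_origin, mat_origin], axis=1)
    return PopulationState(
        generation=parents.generation + 1,
        alleles=alleles,
        origin=origin,
        sire=np.asarray(sire_index, dtype=np.int64),
        dam=np.asarray(dam_index, dtype=np.int64),
        sex=_balanced_sexes(n, rng),
        is_candidate=np.zeros(n, dtype=bool),
        phenotype=np.full(n, np.nan),
    )
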