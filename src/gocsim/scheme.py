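"""The sib-testing genomic optimal-contribution breeding scheme.

Each generation has 2000 offspring.  Every full-sib family is split in two:
half the sibs become selection candidates (genotyped, no phenotype), the other
half test sibs (genotyped and phenotyped, e.g. disease-challenge tested).
Candidates receive SNP-BLUP GEBVs from the current generation's test-sib
records, a relationship matrix is built over the candidates according to the
scheme configuration, and optimal contributions are solved under the group
coancestry target K_t = K_{t-1} + dF (1 - K_{t-1}) with dF = 0.005 per
generation (target Ne = 100).  Matings are random with sire/dam probabilities
proportional to the optimized contributions.

The first generation after the base is produced by random selection (100
sires + 100 dams, monogamous pairs of 20 offspring) purely to create the
sib-family structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gebv as gebv_mod
from . import metrics as metrics_mod
from . import ocs as ocs_mod
from . import relmat as relmat_mod
from .genome import GenomeMap, simulate_base_genomes
from .population import (
    MALE,
    PopulationState,
    make_founder_population,
    reproduce,
)
from .trait import TraitModel, assign_qtl_effects, phenotype, true_bv

__all__ = [
    "BaseConfig",
    "SchemeConfig",
    "SharedReplicate",
    "SchemeResult",
    "table1_schemes",
    "initialize_replicate",
    "initial_random_generation",
    "advance_generation",
    "run_scheme",
    "run_random_mating",
]

MATRICES = ("A", "G_VR1", "G_VR2", "G_0.5", "G_i(p)", "G_LA", "G_ROH")


@dataclass(frozen=True)
class BaseConfig:
    """Population, genome and trait parameters shared by all schemes."""

    ne: int = 100
    n_hist_generations: int = 400
    mu: float = 1e-8
    genome_map: GenomeMap = field(default_factory=GenomeMap)
    n_pool_haplotypes: int = 200
    n_founders: int = 2000
    n_offspring: int = 2000
    panel_sizes: dict = field(default_factory=lambda: {"M": 7000, "Q": 7000, "N": 7000, "D": 7000})
    n_initial_parents_per_sex: int = 100
    sigma_g2: float = 1.0
    sigma_e2: float = 1.5
    track_descent: bool = True
    backend: str = "coalescent"


@dataclass(frozen=True)
class SchemeConfig:
    """One Table-1 style scheme: matrix choice, EBV source and panels."""

    matrix: str = "G_VR2"
    ebv_panel: str | None = "M"          # None -> random GEBVs ("~")
    management_panel: str | None = "M"   # None for the pedigree matrix A
    delta_f: float = 0.005
    n_generations: int = 20
    roh_min_length_mb: float = 7.0
    la_grid_step: int = 10
    la_estimator: str = "descent"

    def __post_init__(self):
        if self.matrix not in MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if self.matrix == "A" and self.management_panel is not None:
            raise ValueError("the pedigree matrix A uses no management panel")
        if self.matrix != "A" and self.management_panel is None:
            raise ValueError(f"{self.matrix} requires a management panel")

    @property
    def label(self) -> str:
        e = self.ebv_panel or "~"
        m = self.management_panel or "~"
        return f"{self.matrix}({e},{m})"


def table1_schemes() -> list[SchemeConfig]:
    """The nine schemes of the study."""
    return [
        SchemeConfig(matrix="G_VR2", ebv_panel="M", management_panel="M"),
        SchemeConfig(matrix="G_VR2", ebv_panel="M", management_panel="D"),
        SchemeConfig(matrix="G_VR2", ebv_panel=None, management_panel="M"),
        SchemeConfig(matrix="G_VR1", ebv_panel="M", management_panel="M"),
        SchemeConfig(matrix="G_i(p)", ebv_panel="M", management_panel="M"),
        SchemeConfig(matrix="G_0.5", ebv_panel="M", management_panel="M"),
        SchemeConfig(matrix="G_ROH", ebv_panel="M", management_panel="M"),
        SchemeConfig(matrix="G_LA", ebv_panel="M", management_panel="M"),
        SchemeConfig(matrix="A", ebv_panel="M", management_panel=None),
    ]


@dataclass
class SharedReplicate:
    """Everything shared by all schemes within one replicate.

    One replicate generates a new base population; the haplotype pool, SNP
    panels, QTL effects and the initial random-selection generation are common
    to every scheme run on the replicate, which removes simulation error from
    between-scheme comparisons.
    """

    base: BaseConfig
    panels: object
    trait_model: TraitModel
    gen1: PopulationState
    n_founders: int


def initialize_replicate(base: BaseConfig, seed) -> SharedReplicate:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pool, s_found, s_qtl, s_gen1 = ss.spawn(4)
    pool = simulate_base_genomes(
        ne=base.ne,
        n_generations=base.n_hist_generations,
        mu=base.mu,
        genome_map=base.genome_map,
        n_haplotypes=base.n_pool_haplotypes,
        seed=int(s_pool.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)),
        backend=base.backend,
    )
    rng_found = np.random.default_rng(s_found)
    founders, panels = make_founder_population(
        pool,
        n_individuals=base.n_founders,
        rng=rng_found,
        panel_sizes=base.panel_sizes,
        track_descent=base.track_descent,
    )
    q_idx = panels.panel_index["Q"]
    model = assign_qtl_effects(
        _dosages(founders, q_idx),
        seed=np.random.default_rng(s_qtl),
        sigma_g2=base.sigma_g2,
        sigma_e2=base.sigma_e2,
    )
    founders.tbv = true_bv(_dosages(founders, q_idx), model)
    rng_gen1 = np.random.default_rng(s_gen1)
    gen1 = initial_random_generation(founders, panels, base, model, rng_gen1)
    return SharedReplicate(
        base=base, panels=panels, trait_model=model, gen1=gen1, n_founders=base.n_founders
    )


def _dosages(state: PopulationState, idx) -> np.ndarray:
    return state.dosages(idx)


def initial_random_generation(
    founders: PopulationState,
    panels,
    base: BaseConfig,
    model: TraitModel,
    rng: np.random.Generator,
) -> PopulationState:
    """Random selection creating the initial full-sib family structure."""
    n_pairs = base.n_initial_parents_per_sex
    males = np.flatnonzero(founders.sex == MALE)
    females = np.flatnonzero(founders.sex != MALE)
    sires = rng.choice(males, size=n_pairs, replace=False)
    dams = rng.choice(females, size=n_pairs, replace=False)
    per_pair = base.n_offspring // n_pairs
    sire_idx = np.repeat(sires, per_pair)
    dam_idx = np.repeat(dams, per_pair)
    state = reproduce(founders, sire_idx, dam_idx, panels, rng)
    state.generation = 1
    _finalize_generation(state, panels, model, rng)
    return state


def _finalize_generation(state, panels, model, rng):
    """Family split, TBVs and test-sib phenotypes for a fresh generation."""
    state.is_candidate = _split_families(state.sire, state.dam, rng)
    state.tbv = true_bv(_dosages(state, panels.panel_index["Q"]), model)
    state.phenotype = np.full(state.n, np.nan)
    ts = state.test_sibs()
    state.phenotype[ts] = phenotype(state.tbv[ts], model, seed=rng)


def _split_families(sire, dam, rng) -> np.ndarray:
    """Split every full-sib family as evenly as possible into candidates and
    test sibs; for odd sizes the extra sib's role is a seeded coin flip."""
    n = sire.shape[0]
    pair = sire.astype(np.int64) * (dam.max() + 1) + dam
    is_cand = np.zeros(n, dtype=bool)
    for p in np.unique(pair):
        members = np.flatnonzero(pair == p)
        members = rng.permutation(members)
        half = members.size // 2
        if members.size % 2 and rng.random() < 0.5:
            half += 1
        is_cand[members[:half]] = True
    return is_cand


def _candidate_gebv(state, shared, cfg, rng):
    cand = state.candidates()
    if cfg.ebv_panel is None:
        return gebv_mod.random_gebv(cand.size, seed=rng)
    idx = shared.panels.panel_index[cfg.ebv_panel]
    p0 = shared.panels.p0[idx]
    ts = state.test_sibs()
    X_all = gebv_mod.standardize(_dosages(state, idx), p0).X
    fit = gebv_mod.fit_snp_blup(
        state.phenotype[ts], X_all[ts], shared.base.sigma_g2, shared.base.sigma_e2
    )
    return fit.predict(X_all[cand])


def build_relationship(state, shared, cfg, A_full=None) -> relmat_mod.RelationshipMatrix:
    """Unrepaired relationship matrix over the current candidates."""
    cand = state.candidates()
    panels = shared.panels
    if cfg.matrix == "A":
        if A_full is None:
            raise ValueError("pedigree matrix requires the propagated A")
        return relmat_mod.RelationshipMatrix(
            A_full[np.ix_(cand, cand)], name="A", kind="IBD", alpha=0.0
        )
    if cfg.matrix == "G_LA":
        if cfg.la_estimator != "descent":
            raise ValueError("the breeding scheme uses the true-descent evaluator")
        grid = panels.panel_index["M"][:: cfg.la_grid_step]
        return relmat_mod.g_la_true(state.origin[cand][:, :, grid], panel="M")
    idx = panels.panel_index[cfg.management_panel]
    p0 = panels.p0[idx]
    dos = _dosages(state, idx)[cand]
    if cfg.matrix == "G_VR2":
        return relmat_mod.g_vr2(gebv_mod.standardize(dos, p0).X, panel=cfg.management_panel)
    if cfg.matrix == "G_VR1":
        return relmat_mod.g_vr1(gebv_mod.centered(dos, p0), p0, panel=cfg.management_panel)
    if cfg.matrix == "G_0.5":
        return relmat_mod.g_05(dos, panel=cfg.management_panel)
    if cfg.matrix == "G_i(p)":
        return relmat_mod.g_ip(dos, p0, panel=cfg.management_panel)
    if cfg.matrix == "G_ROH":
        return relmat_mod.g_roh(
            state.alleles[cand][:, :, idx],
            panels.chromosome[idx],
            panels.position_bp[idx],
            shared.base.genome_map,
            min_length_mb=cfg.roh_min_length_mb,
            panel=cfg.management_panel,
        )
    raise ValueError(cfg.matrix)


def advance_generation(state, shared, cfg, K, rng, A_full=None):
    """One round: GEBVs -> relationship matrix -> contributions -> offspring.

    Returns (new_state, selection_record, new_A_full).
    """
    cand = state.candidates()
    ghat = _candidate_gebv(state, shared, cfg, rng)
    G = relmat_mod.make_positive_definite(build_relationship(state, shared, cfg, A_full))
    sol = ocs_mod.solve_oc(ghat, G.values, state.sex[cand], K)
    males = state.sex[cand] == MALE
    p_m = np.clip(sol.c[males], 0, None)
    p_f = np.clip(sol.c[~males], 0, None)
    sire_pool = cand[males]
    dam_pool = cand[~males]
    n_off = shared.base.n_offspring
    sire_idx = rng.choice(sire_pool, size=n_off, p=p_m / p_m.sum())
    dam_idx = rng.choice(dam_pool, size=n_off, p=p_f / p_f.sum())
    new = reproduce(state, sire_idx, dam_idx, shared.panels, rng)
    _finalize_generation(new, shared.panels, shared.trait_model, rng)
    new_A = None
    if A_full is not None:
        new_A = relmat_mod.propagate_A(A_full, new.sire, new.dam)
    record = {
        "K": K,
        "coancestry": sol.coancestry,
        "objective": sol.objective,
        "n_parents": ocs_mod.count_parents(sol),
        "feasible": sol.feasible,
        "alpha": G.alpha,
        "mean_G": G.mean(),
    }
    return new, record, new_A


@dataclass
class SchemeResult:
    config: SchemeConfig
    panel_metrics: pd.DataFrame       # generation x panel F_hom / F_drift / cross
    generation_metrics: pd.DataFrame  # per-generation gain, variance, selection log
    final_state: PopulationState | None = None

    def f_series(self, panel: str, which: str) -> np.ndarray:
        df = self.panel_metrics
        sub = df[df["panel"] == panel].sort_values("generation")
        return sub[which].to_numpy()

    def delta_f(self, panel: str, which: str = "F_drift") -> metrics_mod.DeltaFEstimate:
        return metrics_mod.delta_f_regression(self.f_series(panel, which))

    def gain(self) -> float:
        gm = self.generation_metrics
        return float(gm.loc[gm["generation"].idxmax(), "mean_tbv_candidates"])


def _panel_rows(state, panels, rows):
    for name in panels.panel_names():
        if name == "Q":
            continue
        idx = panels.panel_index[name]
        p0 = panels.p0[idx]
        pt = _dosages(state, idx).mean(axis=0) / 2.0
        diff, cross = metrics_mod.hom_drift_decomposition(p0, pt)
        rows.append(
            {
                "generation": state.generation,
                "panel": name,
                "F_hom": metrics_mod.f_hom(p0, pt),
                "F_drift": metrics_mod.f_drift(p0, pt),
                "cross_cov": cross,
            }
        )


def run_scheme(
    shared: SharedReplicate,
    cfg: SchemeConfig,
    seed,
    keep_final_state: bool = False,
) -> SchemeResult:
    """Run one scheme for ``cfg.n_generations`` generations on a replicate.

    Deterministic given the replicate (shared base) and ``seed``.  Generation
    1 is the shared random-selection generation; generations 2..n are
    produced by genomic optimal contributions.
    """
    rng = np.random.default_rng(seed)
    state = shared.gen1
    A_full = None
    if cfg.matrix == "A":
        A_full = relmat_mod.propagate_A(
            np.eye(shared.n_founders), state.sire, state.dam
        )
    panel_rows: list[dict] = []
    gen_rows: list[dict] = []
    _panel_rows(state, shared.panels, panel_rows)
    gen_rows.append(_generation_row(state))
    schedule = None
    for t in range(1, cfg.n_generations):
        if schedule is None:
            G1 = relmat_mod.make_positive_definite(
                build_relationship(state, shared, cfg, A_full)
            )
            schedule = ocs_mod.constraint_schedule(
                G1.mean(), delta_f=cfg.delta_f, horizon=cfg.n_generations
            )
        K = schedule.k_at(t)
        state, record, A_full = advance_generation(state, shared, cfg, K, rng, A_full)
        _panel_rows(state, shared.panels, panel_rows)
        row = _generation_row(state)
        row.update(record)
        gen_rows.append(row)
    return SchemeResult(
        config=cfg,
        panel_metrics=pd.DataFrame(panel_rows),
        generation_metrics=pd.DataFrame(gen_rows),
        final_state=state if keep_final_state else None,
    )


def _generation_row(state: PopulationState) -> dict:
    cand = state.candidates()
    return {
        "generation": state.generation,
        "mean_tbv_candidates": float(state.tbv[cand].mean()),
        "mean_tbv": float(state.tbv.mean()),
        "var_tbv": float(state.tbv.var()),
        "n_candidates": int(cand.size),
    }


def run_random_mating(
    shared: SharedReplicate,
    n_generations: int = 20,
    n_parents_per_sex: int = 50,
    seed=None,
) -> pd.DataFrame:
    """Random selection with uniform contributions and no management.

    Each generation draws ``n_parents_per_sex`` sires and dams uniformly and
    mates them at random (sire and dam per offspring uniform over the selected
    parents).  Serves as the classical-theory control in which F_hom and
    F_drift agree with 1 - (1 - 1/(2 N_parents))^t in expectation.
    """
    rng = np.random.default_rng(seed)
    state = shared.gen1
    rows: list[dict] = []
    _panel_rows(state, shared.panels, rows)
    n_off = shared.base.n_offspring
    for _ in range(1, n_generations):
        cand = state.candidates()
        males = cand[state.sex[cand] == MALE]
        females = cand[state.sex[cand] != MALE]
        sires = rng.choice(males, size=n_parents_per_sex, replace=False)
        dams = rng.choice(females, size=n_parents_per_sex, replace=False)
        sire_idx = rng.choice(sires, size=n_off)
        dam_idx = rng.choice(dams, size=n_off)
        state = reproduce(state, sire_idx, dam_idx, shared.panels, rng)
        state.is_candidate = np.ones(state.n, dtype=bool)
        _panel_rows(state, shared.panels, rows)
    return pd.DataFrame(rows)
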