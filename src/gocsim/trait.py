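"""Additive trait model: QTL effects, true breeding values, phenotypes.

Every locus of Panel Q receives an i.i.d. standard-normal allelic effect; the
effect vector is rescaled once so that the variance of true breeding values
among the generation-0 individuals equals ``sigma_g2`` (default 1).  TBVs are
reported as deviations from the founder mean.  Phenotypes add an independent
normal environmental deviate with variance ``sigma_e2`` (default 1.5), giving
a heritability of sigma_g2 / (sigma_g2 + sigma_e2) = 0.4 at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SIGMA_G2 = 1.0
SIGMA_E2 = 1.5


@dataclass(frozen=True)
class TraitModel:
    """Scaled per-QTL allelic effects and the variance structure."""

    effects: np.ndarray        # scaled allelic effects, one per Panel-Q locus
    intercept: float           # founder-mean correction so founder TBVs average 0
    sigma_g2: float = SIGMA_G2
    sigma_e2: float = SIGMA_E2

    @property
    def heritability(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


def assign_qtl_effects(
    founder_q_dosages: np.ndarray,
    seed=None,
    sigma_g2: float = SIGMA_G2,
    sigma_e2: float = SIGMA_E2,
) -> TraitModel:
    """Draw QTL effects and rescale them to the target base genetic variance.

    ``founder_q_dosages`` is the (n_founders, n_qtl) 0/1/2 matrix of the
    generation-0 individuals at the QTL panel.
    """
    q = np.asarray(founder_q_dosages, dtype=np.float64)
    if q.shape[0] < 2:
        raise ValueError("need at least 2 founders to scale the genetic variance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.standard_normal(q.shape[1])
    tbv_raw = q @ raw
    v = tbv_raw.var()
    if v <= 1e-12 * float((raw**2).sum()):
        raise ValueError("degenerate QTL panel: founder TBV variance is zero")
    scale = np.sqrt(sigma_g2 / v)
    effects = raw * scale
    intercept = float((q @ effects).mean())
    return TraitModel(effects=effects, intercept=intercept, sigma_g2=sigma_g2, sigma_e2=sigma_e2)


def true_bv(q_dosages: np.ndarray, model: TraitModel) -> np.ndarray:
    """Sum of QTL allelic effects, centred to founder mean zero."""
    q = np.asarray(q_dosages, dtype=np.float64)
    return q @ model.effects - model.intercept


def phenotype(tbv: np.ndarray, model: TraitModel, seed=None) -> np.ndarray:
    """y = TBV + e with e ~ N(0, sigma_e2)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tbv = np.asarray(tbv, dtype=np.float64)
    if model.sigma_e2 == 0:
        return tbv.copy()
    return tbv + rng.normal(0.0, np.sqrt(model.sigma_e2), size=tbv.shape)
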