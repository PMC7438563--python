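"""SNP-BLUP estimation of breeding values from sib phenotypes.

Genotypes are standardized with base-generation (t = 0) reference-allele
frequencies:

    X_ik = (m_ik - 2 p0k) / sqrt(2 p0k (1 - p0k)),   m_ik in {0, 1, 2}

SNP effects b are ridge (BLUP) estimates under b ~ N(0, sigma_g2 / N_SNP I),
e ~ N(0, sigma_e2 I), with an overall mean as the only fixed effect:

    [1'1   1'X        ] [mu]   [1'y ]
    [X'1   X'X + lam I] [b ] = [X'y ],     lam = N_SNP sigma_e2 / sigma_g2

When the number of records is smaller than the number of SNPs the equivalent
n-dimensional (GBLUP) system is solved instead; the two routes agree to
machine precision and this equivalence is the primary correctness oracle in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["StandardizedGenotypes", "SnpBlupFit", "standardize", "centered", "fit_snp_blup", "random_gebv"]


@dataclass
class StandardizedGenotypes:
    """Standardized (X) and merely centred (Z) genotype codings."""

    X: np.ndarray
    Z: np.ndarray
    p0: np.ndarray


@dataclass
class SnpBlupFit:
    mu: float
    b: np.ndarray
    lam: float

    def predict(self, X_cand: np.ndarray) -> np.ndarray:
        """GEBVs g = X b (no intercept, as deviations)."""
        return X_cand @ self.b


def centered(dosages: np.ndarray, p0: np.ndarray) -> np.ndarray:
    """Z coding: dosage minus twice the base reference frequency."""
    return np.asarray(dosages, dtype=np.float64) - 2.0 * np.asarray(p0)[None, :]


def standardize(dosages: np.ndarray, p0: np.ndarray) -> StandardizedGenotypes:
    """Entry-wise standardization by sqrt(2 p0 (1 - p0)); requires 0 < p0 < 1."""
    p0 = np.asarray(p0, dtype=np.float64)
    if np.any((p0 <= 0) | (p0 >= 1)):
        raise ValueError("p0 must lie strictly between 0 and 1 at every locus")
    Z = centered(dosages, p0)
    X = Z / np.sqrt(2.0 * p0 * (1.0 - p0))[None, :]
    return StandardizedGenotypes(X=X, Z=Z, p0=p0)


def fit_snp_blup(
    y: np.ndarray,
    X: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
) -> SnpBlupFit:
    """BLUP of SNP effects from phenotyped records.

    Solves the mixed-model equations directly when N_SNP <= n_records,
    otherwise via the equivalent n-dimensional system
    V = sigma_b2 XX' + sigma_e2 I, mu = (1'V^-1 y)/(1'V^-1 1),
    b = sigma_b2 X'V^-1 (y - 1 mu).
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 records")
    if sigma_g2 <= 0 or sigma_e2 <= 0:
        raise ValueError("variance components must be positive")
    sigma_b2 = sigma_g2 / p
    lam = sigma_e2 / sigma_b2
    if p <= n:
        lhs = np.empty((p + 1, p + 1))
        lhs[0, 0] = n
        lhs[0, 1:] = X.sum(axis=0)
        lhs[1:, 0] = lhs[0, 1:]
        lhs[1:, 1:] = X.T @ X + lam * np.eye(p)
        rhs = np.concatenate([[y.sum()], X.T @ y])
        try:
            sol = linalg.solve(lhs, rhs, assume_a="sym")
        except linalg.LinAlgError as err:
            raise ValueError("singular mixed-model equations") from err
        mu, b = float(sol[0]), sol[1:]
    else:
        V = sigma_b2 * (X @ X.T) + sigma_e2 * np.eye(n)
        cf = linalg.cho_factor(V, lower=True)
        Vi_y = linalg.cho_solve(cf, y)
        Vi_1 = linalg.cho_solve(cf, np.ones(n))
        denom = Vi_1.sum()
        if denom <= 0:
            raise ValueError("singular system")
        mu = float(Vi_y.sum() / denom)
        b = sigma_b2 * (X.T @ linalg.cho_solve(cf, y - mu))
    return SnpBlupFit(mu=mu, b=b, lam=lam)


def random_gebv(n_candidates: int, seed=None) -> np.ndarray:
    """Random 'GEBVs': i.i.d. standard normal per candidate per generation.

    Used by the no-directional-selection control scheme to separate the
    effects of diversity management from those of selection.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal(int(n_candidates))
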