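"""Optimal-contribution selection.

Maximize the contribution-weighted mean breeding value c'g subject to a group
coancestry constraint  c'Gc / 2 = K, per-sex contribution sums of 1/2, and
c >= 0.  In a selection scheme the constraint binds from below (selection
wants more coancestry than K allows) and is met as an equality; if K exceeds
the coancestry of the unconstrained optimum the constraint acts as a cap and
the unconstrained optimum is returned, so relaxing K never reduces gain.

The solver uses the classical Lagrangian active-set scheme: on the current
candidate set the stationary point is

    c = G^-1 (g - Q lambda) / lambda_0,

where Q is the sex-incidence matrix and (lambda, lambda_0) are chosen to meet
the sex-sum and coancestry constraints in closed form; candidates receiving a
negative contribution are removed and the system re-solved until c >= 0.
If the requested K is below the minimum group coancestry achievable on the
sex-constrained simplex, the coancestry-minimizing solution is returned
flagged infeasible, so long multi-generation runs stay alive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["ConstraintSchedule", "ContributionSolution", "constraint_schedule", "solve_oc", "count_parents"]


@dataclass
class ConstraintSchedule:
    """Group-coancestry targets K_t = K_{t-1} + dF (1 - K_{t-1})."""

    k0: float
    delta_f: float = 0.005
    values: np.ndarray = field(default=None)

    def k_at(self, t: int) -> float:
        """Target after t rounds of selection (t >= 1)."""
        return 1.0 - (1.0 - self.k0) * (1.0 - self.delta_f) ** t


def constraint_schedule(G_gen1_mean: float, delta_f: float = 0.005, horizon: int = 20) -> ConstraintSchedule:
    """Schedule from the mean relationship among generation-1 candidates.

    K0 = mean(G)/2 over all candidate pairs including the diagonal.
    """
    k0 = 0.5 * G_gen1_mean
    ks = np.array([1.0 - (1.0 - k0) * (1.0 - delta_f) ** t for t in range(horizon + 1)])
    return ConstraintSchedule(k0=k0, delta_f=delta_f, values=ks)


@dataclass
class ContributionSolution:
    c: np.ndarray
    selected: np.ndarray          # indices with c > 0
    coancestry: float             # achieved c'Gc / 2
    objective: float              # achieved c'g
    feasible: bool
    n_iterations: int = 0

    @property
    def n_parents(self) -> int:
        return int(self.selected.size)


def count_parents(solution: ContributionSolution, tol: float = 1e-9) -> int:
    """Number of candidates with optimal contributions above tolerance."""
    return int(np.sum(solution.c > tol))


def _sex_incidence(sex: np.ndarray) -> np.ndarray:
    Q = np.zeros((sex.shape[0], 2))
    Q[sex == 0, 0] = 1.0
    Q[sex == 1, 1] = 1.0
    return Q


def _min_coancestry(G: np.ndarray, sex: np.ndarray):
    """Minimize c'Gc/2 s.t. per-sex sums 1/2, c >= 0 (active-set elimination)."""
    n = G.shape[0]
    active = np.arange(n)
    s = np.array([0.5, 0.5])
    for _ in range(n):
        Ga = G[np.ix_(active, active)]
        Qa = _sex_incidence(sex[active])
        cf = linalg.cho_factor(Ga, lower=True)
        GiQ = linalg.cho_solve(cf, Qa)
        QGQ = Qa.T @ GiQ
        lam = linalg.solve(QGQ, s, assume_a="sym")
        c_a = GiQ @ lam
        neg = c_a < 0
        # never empty a sex class
        for sx in (0, 1):
            in_sex = sex[active] == sx
            if np.all(neg[in_sex]):
                keep = np.flatnonzero(in_sex)[np.argmax(c_a[in_sex])]
                neg[keep] = False
        if not neg.any():
            c = np.zeros(n)
            c[active] = c_a
            return c, float(0.5 * c_a @ Ga @ c_a)
        active = active[~neg]
    raise RuntimeError("active-set elimination failed to converge")


def solve_oc(
    gebv: np.ndarray,
    G: np.ndarray,
    sex: np.ndarray,
    K: float,
    max_iter: int | None = None,
) -> ContributionSolution:
    """Solve the group-coancestry-constrained contribution problem.

    Parameters
    ----------
    gebv
        Estimated breeding values of the candidates.
    G
        Positive-definite relationship matrix (after repair).
    sex
        0 = male, 1 = female per candidate; both sexes must be present.
    K
        Target group coancestry c'Gc/2.
    """
    g = np.asarray(gebv, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    sex = np.asarray(sex)
    n = g.shape[0]
    if not (np.any(sex == 0) and np.any(sex == 1)):
        raise ValueError("need at least one candidate of each sex")
    try:
        linalg.cholesky(G, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError("G is not positive definite; apply make_positive_definite first") from err

    s = np.array([0.5, 0.5])

    def _solution(c, feasible, it):
        return ContributionSolution(
            c=c,
            selected=np.flatnonzero(c > 1e-9),
            coancestry=float(0.5 * c @ G @ c),
            objective=float(c @ g),
            feasible=feasible,
            n_iterations=it,
        )

    # flat objective (g within the span of the sex sums): any feasible c is
    # optimal; return the coancestry-minimizing solution
    Qf = _sex_incidence(sex)
    resid = g - Qf @ np.linalg.lstsq(Qf, g, rcond=None)[0]
    if float(resid @ resid) <= 1e-12 * max(1.0, float(g @ g)):
        c, cc = _min_coancestry(G, sex)
        return _solution(c, cc <= K + 1e-6, 0)

    # the constraint is a cap: if the unconstrained optimum (everything on
    # the best male and best female) already satisfies it, return that
    best_m = np.flatnonzero(sex == 0)[np.argmax(g[sex == 0])]
    best_f = np.flatnonzero(sex == 1)[np.argmax(g[sex == 1])]
    c_lp = np.zeros(n)
    c_lp[[best_m, best_f]] = 0.5
    if float(0.5 * c_lp @ G @ c_lp) <= K:
        return _solution(c_lp, True, 0)

    def _equality_step(active):
        """Stationary point on the active set; None when the active set
        cannot reach K (its minimum coancestry exceeds K) or has gone flat."""
        Ga = G[np.ix_(active, active)]
        ga = g[active]
        Qa = _sex_incidence(sex[active])
        cf = linalg.cho_factor(Ga, lower=True)
        Gi_g = linalg.cho_solve(cf, ga)
        Gi_Q = linalg.cho_solve(cf, Qa)
        QGQ_inv = linalg.inv(Qa.T @ Gi_Q)
        proj = QGQ_inv @ (Qa.T @ Gi_g)
        gt_Gi_gt = float(ga @ Gi_g - (Qa.T @ Gi_g) @ proj)
        denom = 2.0 * K - float(s @ QGQ_inv @ s)
        if denom <= 0 or gt_Gi_gt <= 1e-12:
            return None
        lam0 = np.sqrt(gt_Gi_gt / denom)
        lam = QGQ_inv @ (Qa.T @ Gi_g - lam0 * s)
        c_a = (Gi_g - Gi_Q @ lam) / lam0
        return c_a, lam0, lam

    # genuine infeasibility: K below the minimum coancestry of the full set
    if _equality_step(np.arange(n)) is None:
        c, cc = _min_coancestry(G, sex)
        return _solution(c, cc <= K + 1e-6, 1)

    it = 0
    for remove_all in (True, False):
        active = np.arange(n)
        dead = False
        for _outer in range(max_iter or (4 * n)):
            step = _equality_step(active)
            it += 1
            if step is None:
                dead = True   # elimination over-pruned; retry cautiously
                break
            c_a, lam0, lam = step
            neg = c_a < 0
            for sx in (0, 1):
                in_sex = sex[active] == sx
                if np.all(neg[in_sex]):
                    keep = np.flatnonzero(in_sex)[np.argmax(c_a[in_sex])]
                    neg[keep] = False
            if neg.any():
                if remove_all:
                    active = active[~neg]
                else:
                    active = np.delete(active, np.argmin(c_a))
                continue
            c = np.zeros(n)
            c[active] = np.clip(c_a, 0.0, None)
            # KKT check: a zeroed candidate with positive reduced gradient
            # would improve the objective; re-admit and re-solve
            mu = g - lam0 * (G @ c) - lam[sex]
            excluded = np.setdiff1d(np.arange(n), active)
            viol = excluded[mu[excluded] > 1e-9]
            if viol.size == 0:
                return _solution(c, True, it)
            active = np.union1d(active, viol)
        if not dead:
            break
    # last resort: polish on the convex cap form from the min-coancestry point
    from scipy import optimize

    c0, _ = _min_coancestry(G, sex)
    Qf2 = _sex_incidence(sex)
    res = optimize.minimize(
        lambda c: -c @ g,
        c0,
        jac=lambda c: -g,
        bounds=[(0, None)] * n,
        constraints=[
            {"type": "eq", "fun": lambda c: Qf2.T @ c - s, "jac": lambda c: Qf2.T},
            {
                "type": "ineq",
                "fun": lambda c: K - 0.5 * c @ G @ c,
                "jac": lambda c: -(G @ c),
            },
        ],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    return _solution(np.clip(res.x, 0, None), res.success, it)
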