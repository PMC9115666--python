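"""Sparsity-promoting endmember estimation and constrained unmixing.

The linear mixing model writes each pixel spectrum as a convex combination
of endmembers. Abundances for fixed endmembers are found by an exact
active-set quadratic program on the probability simplex (fully constrained
least squares, optionally with per-endmember linear sparsity penalties).
The full fit alternates that abundance step with a closed-form
ridge-dispersion endmember update, reweighting the sparsity penalties so
that endmembers with shrinking total abundance are pruned away — jointly
estimating the number, shape and abundances of the endmembers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .core import (
    AbundanceResult,
    DegenerateDataError,
    EndmemberSet,
    FeatureVector,
    InvalidParameterError,
    SpectraMatrix,
    pairwise_spectral_angles,
)

__all__ = [
    "SpiceParams",
    "SpiceResult",
    "solve_abundances",
    "spice_fit",
    "abundance_feature",
    "match_endmembers",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpiceParams:
    """Knobs of the sparsity-promoting unmixing fit."""

    gamma: float = 70.0
    m0: int = 20
    prune_threshold: float = 1e-6
    tol: float = 1e-6
    max_iter: int = 300
    mu: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.gamma <= 0:
            raise InvalidParameterError("gamma must be > 0")
        if self.m0 < 2:
            raise InvalidParameterError("m0 must be >= 2")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be > 0")
        if not 0 <= self.mu < 1:
            raise InvalidParameterError("mu must be in [0, 1)")


@dataclass
class SpiceResult:
    """Fitted endmembers plus abundances; iterable as a 2-tuple."""

    endmembers: EndmemberSet
    abundances: AbundanceResult
    objective_history: List[float] = field(default_factory=list)
    n_iterations: int = 0

    def __iter__(self):
        return iter((self.endmembers, self.abundances))


def _batch_simplex_qp(G: np.ndarray, C: np.ndarray, tol: float = 1e-10,
                      max_sweeps: Optional[int] = None) -> np.ndarray:
    """Minimize a_i' G a_i - 2 C_i . a_i over the simplex, for every row i.

    Primal active-set method run synchronously over all rows: rows sharing
    a free-coordinate pattern share one KKT factorization, so the dominant
    cost is a handful of small batched linear solves per sweep.
    """
    n, m = C.shape
    if m == 1:
        return np.ones((n, 1))
    ridge = 1e-9 * (np.trace(G) / m + 1.0)
    G = G + ridge * np.eye(m)
    a = np.full((n, m), 1.0 / m)
    free = np.ones((n, m), dtype=bool)
    done = np.zeros(n, dtype=bool)
    sweeps = max_sweeps or (6 * m + 30)
    for _ in range(sweeps):
        todo = np.where(~done)[0]
        if todo.size == 0:
            break
        patterns, inverse = np.unique(free[todo], axis=0, return_inverse=True)
        for pi in range(patterns.shape[0]):
            rows = todo[inverse == pi]
            idx = np.where(patterns[pi])[0]
            k = idx.size
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = 2.0 * G[np.ix_(idx, idx)]
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.empty((k + 1, rows.size))
            rhs[:k] = 2.0 * C[rows][:, idx].T
            rhs[k] = 1.0
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            cand = np.zeros((rows.size, m))
            cand[:, idx] = sol[:k].T
            lam = sol[k]
            has_neg = (cand[:, idx] < -tol).any(axis=1)

            ok = rows[~has_neg]
            if ok.size:
                a_ok = np.maximum(cand[~has_neg], 0.0)
                a_ok /= a_ok.sum(axis=1, keepdims=True)
                a[ok] = a_ok
                # KKT multipliers of the zero-bound constraints
                mu_b = 2.0 * (a_ok @ G - C[ok]) + lam[~has_neg][:, None]
                mu_b = np.where(free[ok], np.inf, mu_b)
                worst = mu_b.min(axis=1)
                release = worst < -tol
                done[ok[~release]] = True
                rel_rows = ok[release]
                if rel_rows.size:
                    free[rel_rows, mu_b[release].argmin(axis=1)] = True

            bad = rows[has_neg]
            if bad.size:
                cur = a[bad]
                delta = cand[has_neg] - cur
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratios = np.where(delta < -tol,
                                      cur / np.maximum(-delta, 1e-300), np.inf)
                ratios = np.where(free[bad], ratios, np.inf)
                alpha = np.minimum(ratios.min(axis=1), 1.0)
                block = ratios.argmin(axis=1)
                stepped = cur + alpha[:, None] * delta
                stepped[np.arange(bad.size), block] = 0.0
                stepped = np.maximum(stepped, 0.0)
                stepped /= stepped.sum(axis=1, keepdims=True)
                a[bad] = stepped
                free[bad, block] = False
    return a


def solve_abundances(
    spectra: SpectraMatrix,
    endmembers: EndmemberSet,
    sparsity_weights: Optional[np.ndarray] = None,
) -> AbundanceResult:
    """Per-pixel simplex-constrained least squares with optional linear
    sparsity penalties.

    Minimizes ||s_i - E' a_i||^2 + sum_k gamma_k a_ik subject to a_i >= 0
    and sum_k a_ik = 1. With all gamma_k = 0 this is fully constrained
    least squares.
    """
    e = endmembers.spectra
    m = e.shape[0]
    if spectra.grid.n_bands != e.shape[1]:
        raise InvalidParameterError("spectra and endmembers disagree on bands")
    if np.linalg.matrix_rank(e) < m:
        raise DegenerateDataError("endmember matrix is rank-deficient")
    gamma = np.zeros(m) if sparsity_weights is None else np.asarray(
        sparsity_weights, dtype=float)
    if gamma.shape != (m,) or np.any(gamma < 0):
        raise InvalidParameterError("sparsity weights must be length M and >= 0")
    values = _solve_abundances_array(spectra.values, e, gamma)
    resid = _rss(spectra.values, values, e)
    return AbundanceResult(values=values, residual=resid)


def _solve_abundances_array(x: np.ndarray, e: np.ndarray,
                            gamma: np.ndarray) -> np.ndarray:
    g = e @ e.T
    c = x @ e.T - 0.5 * gamma[None, :]
    return _batch_simplex_qp(g, c)


def _rss(x: np.ndarray, a: np.ndarray, e: np.ndarray) -> np.ndarray:
    diff = x - a @ e
    return np.einsum("ij,ij->i", diff, diff)


def _dispersion(e: np.ndarray) -> float:
    """Sum of squared pairwise endmember distances."""
    m = e.shape[0]
    if m < 2:
        return 0.0
    gram = e @ e.T
    return float(m * np.trace(gram) - gram.sum())


def spice_fit(spectra: SpectraMatrix, params: Optional[SpiceParams] = None
              ) -> SpiceResult:
    """Alternating sparsity-promoting unmixing.

    Per iteration: (i) abundance QP with per-endmember penalties
    gamma_k = Gamma / (total abundance of k from the previous iterate,
    floored); (ii) prune endmembers whose mean abundance falls below the
    prune threshold; (iii) closed-form endmember update minimizing
    reconstruction plus the mu-weighted pairwise dispersion. Iterations are
    accepted only while the objective is non-increasing.
    """
    p = params or SpiceParams()
    x = spectra.values
    n, b = x.shape
    if n <= p.m0:
        raise InvalidParameterError("need more spectra than initial endmembers")
    rng = np.random.default_rng(p.seed)
    idx = rng.choice(n, size=p.m0, replace=False)
    scale = float(np.std(x)) or 1.0
    e = x[idx] + rng.normal(0.0, 1e-4 * scale, size=(p.m0, b))

    a = _solve_abundances_array(x, e, np.zeros(p.m0))
    totals = a.sum(axis=0)
    p_floor = 1e-6
    gammas = p.gamma / np.maximum(totals, p_floor)

    def objective(a_cur, e_cur, totals_cur, n_pruned):
        # log-penalized form: the Lyapunov function of the reweighted
        # linear penalty (gamma_k = Gamma / previous total of k). Pruned
        # endmembers stay at the floor as constants, so the logged value is
        # continuous across pruning events. Returns (full, active): the
        # active part omits that constant and sets the convergence scale.
        m_cur = e_cur.shape[0]
        lam = (n * p.mu / ((1.0 - p.mu) * m_cur * (m_cur - 1))
               ) if m_cur > 1 else 0.0
        active = (float(_rss(x, a_cur, e_cur).sum())
                  + lam * _dispersion(e_cur)
                  + p.gamma * float(
                      np.log(np.maximum(totals_cur, p_floor)).sum()))
        return active + p.gamma * n_pruned * float(np.log(p_floor)), active

    history: List[float] = []
    prev_obj = np.inf
    n_pruned = 0
    it = 0
    for it in range(1, p.max_iter + 1):
        prev_state = (e, a, gammas, n_pruned)
        a = _solve_abundances_array(x, e, gammas)
        totals = a.sum(axis=0)
        keep = totals / n >= p.prune_threshold
        if not keep.any():
            raise DegenerateDataError("all endmembers pruned; decrease gamma")
        if not keep.all():
            n_pruned += int((~keep).sum())
            e, a, gammas = e[keep], a[:, keep], gammas[keep]
            a /= a.sum(axis=1, keepdims=True)
            totals = a.sum(axis=0)
        m = e.shape[0]
        lam_e = (n * p.mu / ((1.0 - p.mu) * m * (m - 1))) if m > 1 else 0.0
        lhs = a.T @ a + lam_e * (m * np.eye(m) - np.ones((m, m)))
        lhs += 1e-10 * np.trace(lhs) / m * np.eye(m)
        e = np.linalg.solve(lhs, a.T @ x)

        obj, obj_active = objective(a, e, totals, n_pruned)
        if obj > prev_obj + 1e-9 * max(1.0, abs(prev_obj)):
            # reweighting overshoot: revert to the last accepted iterate
            log.debug("spice: objective increase at iteration %d", it)
            e, a, gammas, n_pruned = prev_state
            break
        history.append(obj)
        if np.isfinite(prev_obj) and abs(prev_obj - obj) <= p.tol * max(
                1.0, abs(obj_active)):
            prev_obj = obj
            break
        prev_obj = obj
        gammas = p.gamma / np.maximum(totals, p_floor)

    # final abundances for the fitted endmembers (pure FCLS residuals)
    a = _solve_abundances_array(x, e, gammas)
    a = np.clip(a, 0.0, 1.0)
    a /= a.sum(axis=1, keepdims=True)
    endmembers = EndmemberSet(spectra=e, grid=spectra.grid, gamma=p.gamma)
    result = AbundanceResult(values=a, residual=_rss(x, a, e))
    return SpiceResult(endmembers=endmembers, abundances=result,
                       objective_history=history, n_iterations=it)


def abundance_feature(ab: AbundanceResult, sample_id: str = "") -> FeatureVector:
    """Mean abundance per endmember over all pixels."""
    if ab.values.shape[0] == 0:
        raise InvalidParameterError("cannot average an empty abundance set")
    return FeatureVector(values=ab.values.mean(axis=0), sample_id=sample_id)


def match_endmembers(estimated: np.ndarray, reference: np.ndarray
                     ) -> List[Tuple[int, int, float]]:
    """Greedy spectral-angle matching between two endmember sets.

    Returns (estimated_index, reference_index, angle_radians) triples,
    one per matched pair, smallest angles first.
    """
    est = np.atleast_2d(estimated)
    ref = np.atleast_2d(reference)
    both = np.vstack([est, ref])
    angles = pairwise_spectral_angles(both)[: est.shape[0], est.shape[0]:]
    pairs = []
    angles = angles.copy()
    for _ in range(min(est.shape[0], ref.shape[0])):
        i, j = np.unravel_index(int(np.argmin(angles)), angles.shape)
        pairs.append((int(i), int(j), float(angles[i, j])))
        angles[i, :] = np.inf
        angles[:, j] = np.inf
    return pairs
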