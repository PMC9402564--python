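"""Independent verification machinery for the closed-form distribution.

Nothing here reuses the closed-form exponent: the state count is exact
big-integer combinatorics, and the constrained maximizer is a generic
primal-dual Newton method for equality-constrained concave maximization
working only from the entropy and constraint definitions. Agreement with
the closed form therefore certifies it rather than restating it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import reduce
from operator import mul

import numpy as np

from .model import (
    DispersionGeometry,
    ModelParams,
    dispersion_coefficients_closed_form,
    force_law,
)

__all__ = [
    "LagrangeMultipliers",
    "OracleResult",
    "exact_log_states",
    "lagrangian_value",
    "solve_beta",
    "stationarity_residual",
    "constrained_maximize",
]


def exact_log_states(n) -> float:
    """Exact ln of the multinomial state count W = N! / (n_1! ... n_m!).

    Number of distinguishable ways to partition N monomers into the given
    per-class counts, computed with exact big-integer factorials (no
    Stirling approximation anywhere). Serves as the ground truth against
    which the Stirling-form formation entropy is checked.
    """
    counts = []
    for v in np.atleast_1d(n):
        iv = int(v)
        if iv != v:
            raise ValueError(f"monomer counts must be integers, got {v!r}")
        if iv < 0:
            raise ValueError(f"monomer counts must be non-negative, got {iv}")
        counts.append(iv)
    if not counts:
        raise ValueError("empty count vector")
    N = sum(counts)
    denom = reduce(mul, (math.factorial(c) for c in counts), 1)
    W = math.factorial(N) // denom
    return float(math.log(W))


@dataclass(frozen=True)
class LagrangeMultipliers:
    """Multipliers of the constrained entropy maximization.

    ``alpha`` multiplies the expected-tension constraint (the closed form
    corresponds to alpha = V*lam/(2*T)); ``beta`` multiplies normalization.
    ``beta=None`` requests solving for the beta that minimizes the max
    stationarity residual (the paper-style derivation never reports beta).
    """

    alpha: float
    beta: float | None = None

    @classmethod
    def from_params(cls, params: ModelParams,
                    beta: float | None = None) -> "LagrangeMultipliers":
        return cls(alpha=params.force_multiplier, beta=beta)


def _entropy_terms(p: np.ndarray, params: ModelParams,
                   geom: DispersionGeometry) -> float:
    """S(p) in J/K for any non-negative p (feasibility not required)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    s_f = -params.kb * params.N * float(np.sum(nz * np.log(nz)))
    s_d = params.kb_prime * params.N * float(
        np.sum(geom.coverage_per_length() * p))
    return s_f + s_d


def lagrangian_value(p, mult: LagrangeMultipliers, params: ModelParams,
                     geom: DispersionGeometry, F_target: float) -> float:
    """L = S(p) - alpha*(sum p f - F_target) - beta*(sum p - 1), in J/K."""
    p = np.asarray(p, dtype=float)
    if len(p) != geom.m:
        raise ValueError("p and geometry have different lengths")
    beta = 0.0 if mult.beta is None else mult.beta
    lengths = np.arange(1, len(p) + 1)
    f = force_law(lengths, params)
    return (_entropy_terms(p, params, geom)
            - mult.alpha * (float(np.sum(p * f)) - F_target)
            - beta * (float(np.sum(p)) - 1.0))


def _gradient_components(log_p: np.ndarray, alpha: float,
                         params: ModelParams,
                         geom: DispersionGeometry) -> np.ndarray:
    """Per-class dL/dp_i before the -beta term, J/K."""
    lengths = np.arange(1, len(log_p) + 1)
    f = force_law(lengths, params)
    return (-params.kb * params.N * (log_p + 1.0)
            + params.kb_prime * params.N * geom.coverage_per_length()
            - alpha * f)


def solve_beta(p, alpha: float, params: ModelParams,
               geom: DispersionGeometry, log_p=None) -> float:
    """Beta minimizing the max-norm stationarity residual (midrange)."""
    if log_p is None:
        log_p = _safe_log(p)
    g = _gradient_components(np.asarray(log_p, dtype=float), alpha,
                             params, geom)
    return float(0.5 * (g.max() + g.min()))


def _safe_log(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError(
            "zero probabilities make the entropy gradient diverge; "
            "pass log_p explicitly for underflowed distributions"
        )
    return np.log(p)


def stationarity_residual(p, mult: LagrangeMultipliers, params: ModelParams,
                          geom: DispersionGeometry, *, log_p=None) -> float:
    """Max-norm of the Lagrangian gradient dL/dp_i at ``p`` (J/K).

    With alpha = V*lam/(2*T) this vanishes (up to rounding) exactly at the
    closed-form stationary distribution. Accepts ``log_p`` so that
    distributions whose tail underflows in double precision can still be
    checked.
    """
    if log_p is None:
        log_p = _safe_log(p)
    log_p = np.asarray(log_p, dtype=float)
    if len(log_p) != geom.m:
        raise ValueError("p and geometry have different lengths")
    g = _gradient_components(log_p, mult.alpha, params, geom)
    beta = solve_beta(None, mult.alpha, params, geom, log_p=log_p) \
        if mult.beta is None else mult.beta
    return float(np.max(np.abs(g - beta)))


@dataclass
class OracleResult:
    """Outcome of the independent constrained maximization."""

    p_opt: np.ndarray
    converged: bool
    max_gradient_residual: float  # J/K, max-norm of projected gradient
    objective_value: float        # S(p_opt), J/K
    alpha: float                  # recovered force-constraint multiplier, J/(K*N)
    beta: float                   # recovered normalization multiplier, J/K
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)


def _newton_kkt_np(c, g, r, Gt, p0, tol, max_iter, has_force):
    """Primal-dual Newton on the KKT system of the scaled problem.

    maximize  -sum p ln p + r sum c_i p_i
    s.t.      sum p = 1,  sum g_i p_i = Gt     (skipped if not has_force)

    Residuals: F1_i = -ln p_i - 1 + r c_i - alpha g_i - beta, F2 = sum p - 1,
    F3 = sum g p - Gt. The Hessian of the objective is diag(-1/p), so the
    Newton system reduces by block elimination to a 2x2 solve for the
    multiplier updates. A fraction-to-boundary rule keeps p strictly
    positive; strict concavity makes the maximizer unique.
    """
    p = p0.copy()
    alpha, beta = 0.0, 0.0
    one = np.ones_like(p)

    def residuals(p, alpha, beta):
        F1 = -np.log(p) - 1.0 + r * c - alpha * g - beta
        F2 = p.sum() - 1.0
        F3 = float(g @ p) - Gt if has_force else 0.0
        return F1, F2, F3

    F1, F2, F3 = residuals(p, alpha, beta)
    norm = max(np.max(np.abs(F1)), abs(F2), abs(F3))
    it = 0
    while norm > tol and it < max_iter:
        it += 1
        pg = p * g
        if has_force:
            M = np.array([[pg.sum(), p.sum()],
                          [float(pg @ g), pg.sum()]])
            rhs = np.array([float(p @ F1) + F2, float(pg @ F1) + F3])
            try:
                dalpha, dbeta = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                dalpha, dbeta = np.linalg.lstsq(M, rhs, rcond=None)[0]
        else:
            dalpha = 0.0
            dbeta = (float(p @ F1) + F2) / p.sum()
        dp = p * (F1 - g * dalpha - dbeta)
        # fraction-to-boundary: keep p strictly positive
        neg = dp < 0
        t = 1.0
        if np.any(neg):
            t = min(1.0, 0.995 * np.min(-p[neg] / dp[neg]))
        # backtracking on the KKT residual norm
        for _ in range(60):
            p_new = p + t * dp
            a_new = alpha + t * dalpha
            b_new = beta + t * dbeta
            F1n, F2n, F3n = residuals(p_new, a_new, b_new)
            norm_new = max(np.max(np.abs(F1n)), abs(F2n), abs(F3n))
            if norm_new <= (1.0 - 0.25 * t) * norm or norm_new < tol:
                break
            t *= 0.5
        p, alpha, beta = p_new, a_new, b_new
        F1, F2, F3 = F1n, F2n, F3n
        norm = norm_new
    return p, alpha, beta, norm, it


def _newton_kkt_mp(params, geom, F_target, p0, alpha0, beta0, dps,
                   max_iter, has_force):
    """Extended-precision polish of the Newton-KKT iteration (mpmath).

    The coverage ratios and the force law are rebuilt at working precision
    rather than converted from float64: when f0 is tiny, the force
    multiplier's contribution to the stationarity system sits far below
    double rounding noise in those vectors, so the inputs themselves must
    carry the full precision. ``F_target`` may arrive as an mpf.
    """
    import mpmath as mp

    with mp.workdps(dps):
        m = len(p0)
        c = [mp.mpf(int(geom.A[i - 1])) / i for i in range(1, m + 1)]
        f = [mp.mpf(params.f0) / (1 + mp.e**(mp.mpf(params.l0) - i))
             for i in range(1, m + 1)]
        r = mp.mpf(params.kb_ratio)
        if has_force:
            fscale = max(f)
            g = [fi / fscale for fi in f]
            Gt = mp.mpf(F_target) / fscale
        else:
            fscale = mp.mpf(1)
            g = [mp.mpf(0)] * m
            Gt = mp.mpf(0)
        p = [mp.mpf(x) for x in p0]
        alpha, beta = mp.mpf(alpha0), mp.mpf(beta0)
        tol = mp.mpf(10) ** (-(dps - 8))

        def residuals(p, alpha, beta):
            F1 = [-mp.log(p[i]) - 1 + r * c[i] - alpha * g[i] - beta
                  for i in range(m)]
            F2 = mp.fsum(p) - 1
            F3 = mp.fsum(g[i] * p[i] for i in range(m)) - Gt \
                if has_force else mp.mpf(0)
            return F1, F2, F3

        F1, F2, F3 = residuals(p, alpha, beta)
        norm = max(max(abs(x) for x in F1), abs(F2), abs(F3))
        it = 0
        while norm > tol and it < max_iter:
            it += 1
            pg = [p[i] * g[i] for i in range(m)]
            spg = mp.fsum(pg)
            sp = mp.fsum(p)
            if has_force:
                spgg = mp.fsum(pg[i] * g[i] for i in range(m))
                rhs1 = mp.fsum(p[i] * F1[i] for i in range(m)) + F2
                rhs2 = mp.fsum(pg[i] * F1[i] for i in range(m)) + F3
                det = spg * spg - sp * spgg
                dalpha = (rhs1 * spg - rhs2 * sp) / det
                dbeta = (rhs2 * spg - rhs1 * spgg) / det
            else:
                dalpha = mp.mpf(0)
                dbeta = (mp.fsum(p[i] * F1[i] for i in range(m)) + F2) / sp
            dp = [p[i] * (F1[i] - g[i] * dalpha - dbeta) for i in range(m)]
            t = mp.mpf(1)
            for i in range(m):
                if dp[i] < 0:
                    t = min(t, mp.mpf("0.995") * (-p[i] / dp[i]))
            for _ in range(80):
                p_new = [p[i] + t * dp[i] for i in range(m)]
                a_new = alpha + t * dalpha
                b_new = beta + t * dbeta
                F1n, F2n, F3n = residuals(p_new, a_new, b_new)
                norm_new = max(max(abs(x) for x in F1n), abs(F2n), abs(F3n))
                if norm_new <= (1 - t / 4) * norm or norm_new < tol:
                    break
                t /= 2
            p, alpha, beta = p_new, a_new, b_new
            F1, F2, F3 = F1n, F2n, F3n
            norm = norm_new
        return p, alpha, beta, norm, it, fscale


def constrained_maximize(params: ModelParams,
                         geom: DispersionGeometry | None = None,
                         F_target: float | None = None,
                         *,
                         n_starts: int = 1,
                         seed: int = 0,
                         tol: float = 1e-12,
                         max_iter: int = 300,
                         dps: int | None = None,
                         oracle_limit: int = 200) -> OracleResult:
    """Numerically maximize the overall entropy under both constraints.

    Works from the entropy/constraint definitions only (never the
    closed-form exponent). ``F_target`` defaults to the expected tension
    realized by the closed form, the conceptually fixed homeostatic value
    whose number is otherwise unspecified. With ``dps`` set, the converged
    double-precision solution is polished in mpmath extended precision —
    needed to resolve the force multiplier when f0 is so small that the
    tension constraint is numerically degenerate in float64.

    Returns the maximizer, recovered multipliers (``alpha`` comparable to
    V*lam/(2*T)) and the max-norm KKT residual in physical units (J/K).
    """
    if geom is None:
        geom = dispersion_coefficients_closed_form(params.a, params.m)
    m = params.m
    if m > oracle_limit:
        raise ValueError(
            f"m = {m} exceeds the oracle limit {oracle_limit}; the "
            "brute-force maximizer is meant for small problems"
        )
    lengths = np.arange(1, m + 1)
    f = force_law(lengths, params)
    c = geom.coverage_per_length()
    r = params.kb_ratio
    kbN = params.kb * params.N

    if m == 1:
        p1 = np.array([1.0])
        return OracleResult(p_opt=p1, converged=True,
                            max_gradient_residual=0.0,
                            objective_value=_entropy_terms(p1, params, geom),
                            alpha=0.0, beta=kbN * (r * c[0] - 1.0),
                            n_iter=0, diagnostics={"degenerate": "m=1"})

    if F_target is None:
        from .model import stationary_distribution
        F_target = float(
            np.sum(stationary_distribution(params, geom).p * f))

    fscale = float(f.max())
    has_force = fscale > 0.0
    F_float = float(F_target)
    if has_force:
        if not (f.min() < F_float < f.max()):
            raise ValueError(
                f"F_target = {F_float!r} is not strictly attainable: "
                f"force law spans ({f.min()!r}, {f.max()!r})"
            )
        g = f / fscale
        Gt = F_float / fscale
    else:
        g = np.zeros(m)
        Gt = 0.0

    rng = np.random.default_rng(seed)
    best = None
    start_seeds = []
    for k in range(n_starts):
        if k == 0:
            p0 = np.full(m, 1.0 / m)
        else:
            p0 = rng.dirichlet(np.ones(m))
            p0 = np.maximum(p0, 1e-12)
            p0 /= p0.sum()
        start_seeds.append(seed + k)
        p, alpha_g, beta_s, norm, it = _newton_kkt_np(
            c, g, r, Gt, p0, tol, max_iter, has_force)
        obj = -float(np.sum(p * np.log(p))) + r * float(c @ p)
        if best is None or obj > best[-1]:
            best = (p, alpha_g, beta_s, norm, it, obj)
    p, alpha_g, beta_s, norm, it = best[:5]

    if dps is not None:
        p_mp, alpha_mp, beta_mp, norm_mp, it_mp, fscale_mp = _newton_kkt_mp(
            params, geom, F_target, p, alpha_g, beta_s, dps, max_iter,
            has_force)
        import mpmath as mp
        with mp.workdps(dps):
            alpha_phys = alpha_mp * mp.mpf(kbN) / fscale_mp \
                if has_force else mp.mpf(0)
            result_alpha = float(alpha_phys)
            norm = float(norm_mp * kbN)
        p = np.array([float(x) for x in p_mp])
        beta_s = float(beta_mp)
        it += it_mp
        converged = norm_mp <= 10 ** (-(dps - 8))
    else:
        result_alpha = alpha_g * kbN / fscale if has_force else 0.0
        converged = norm <= tol
        norm = norm * kbN

    obj = _entropy_terms(p, params, geom)
    return OracleResult(
        p_opt=p,
        converged=bool(converged),
        max_gradient_residual=float(norm),
        objective_value=obj,
        alpha=float(result_alpha),
        beta=float(beta_s * kbN),
        n_iter=it,
        diagnostics={"start_seeds": start_seeds, "n_starts": n_starts,
                     "F_target": float(F_target), "dps": dps},
    )
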