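"""Self-verification suite tying the closed form to its independent oracles.

Each check recomputes a quantity two ways — closed form vs literal
enumeration, Stirling form vs exact state count, analytic distribution vs
numerical constrained maximizer — and reports (check_name, tolerance,
observed, status) rows suitable for the ``afhomeo verify`` subcommand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ModelParams,
    dispersion_coefficients_closed_form,
    dispersion_coefficients_literal_sum,
    formation_entropy,
    stationary_distribution,
    stationary_distribution_mp,
)
from .oracle import (
    LagrangeMultipliers,
    constrained_maximize,
    exact_log_states,
    stationarity_residual,
)

__all__ = ["VerificationCheck", "run_verification_suite"]


@dataclass(frozen=True)
class VerificationCheck:
    name: str
    tolerance: float
    observed: float
    passed: bool

    @property
    def status(self) -> str:
        return "pass" if self.passed else "FAIL"

    def as_row(self) -> str:
        return "\t".join([self.name, f"{self.tolerance:.3e}",
                          f"{self.observed:.6e}", self.status])


def _check(name: str, tolerance: float, observed: float) -> VerificationCheck:
    return VerificationCheck(name, tolerance, float(observed),
                             float(observed) <= tolerance)


def run_verification_suite(params: ModelParams | None = None,
                           seed: int = 0) -> list[VerificationCheck]:
    """Run every oracle cross-check and return the outcome rows."""
    params = params or ModelParams()
    checks: list[VerificationCheck] = []

    # 1. closed-form coverage coefficients vs literal block enumeration
    mism = 0
    for a in (1, 2, 3, 5, 10, 17):
        A1 = dispersion_coefficients_closed_form(a, 500).A
        A2 = dispersion_coefficients_literal_sum(a, 500).A
        mism += int(np.sum(A1 != A2))
    checks.append(_check("coefficients_closed_vs_literal", 0.0, mism))

    # 2. normalization of the stationary distribution
    dist = stationary_distribution(params)
    checks.append(_check("normalization_abs_error", 1e-12,
                         abs(dist.p.sum() - 1.0)))

    # 3. Lagrangian stationarity at the closed form (units of kb*N)
    geom = dispersion_coefficients_closed_form(params.a, params.m)
    res = stationarity_residual(dist.p, LagrangeMultipliers.from_params(params),
                                params, geom, log_p=dist.log_p)
    checks.append(_check("stationarity_residual_over_kbN", 1e-8,
                         res / (params.kb * params.N)))

    # 4. independent constrained maximizer recovers the closed form (m=50)
    p50 = params.with_(m=50)
    dist50 = stationary_distribution(p50)
    oracle = constrained_maximize(p50, seed=seed)
    rel = float(np.max(np.abs(oracle.p_opt / dist50.p - 1.0)))
    checks.append(_check("oracle_max_rel_error_m50", 1e-6, rel))

    # 5. force-constraint multiplier recovery (extended precision; the
    #    constraint is numerically degenerate in float64 at f0 = 1 pN)
    import mpmath as mp
    p_mp, f_mp = stationary_distribution_mp(p50, dps=50)
    with mp.workdps(50):
        F_mp = mp.fsum(pi * fi for pi, fi in zip(p_mp, f_mp))
    oracle_mp = constrained_maximize(p50, F_target=F_mp, seed=seed, dps=50)
    alpha_rel = abs(oracle_mp.alpha / p50.force_multiplier - 1.0)
    checks.append(_check("force_multiplier_rel_error", 1e-4, alpha_rel))

    # 6. coverage-efficiency limit A_m/l_m -> 1/a
    g1000 = dispersion_coefficients_closed_form(10, 1000)
    checks.append(_check("coverage_limit_error_a10_m1000", 2.0 / 1000,
                         abs(g1000.A[-1] / 1000.0 - 0.1)))

    # 7. Stirling-form formation entropy vs exact state count
    n = np.array([30000, 25000, 20000, 15000, 10000])
    N = int(n.sum())
    p_exact = n / N
    pN = ModelParams(N=N, m=len(n))
    lnW = exact_log_states(n)
    gap = abs(formation_entropy(p_exact, pN) / pN.kb - lnW) / lnW
    checks.append(_check("stirling_rel_gap_N1e5", 0.01, gap))

    return checks
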