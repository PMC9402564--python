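"""Core equations of the actin-filament length-distribution model.

A cell under tensional homeostasis is modelled as ``N`` actin monomers
partitioned into filament length classes ``i = 1..m`` (length ``l_i = i``
in monomer units). The stationary length distribution maximises the sum of

* a *formation* entropy ``S_f = -k_b N sum p_i ln p_i`` (the Stirling form
  of the multinomial state count of the monomer partition), and
* a *dispersion* entropy ``S_d = k_b' N sum (A_i / l_i) p_i`` measuring how
  many cytoplasmic compartments of size ``a`` the filament population can
  cover (``A_i`` is the maximum number of compartments one filament of
  class ``i`` can span),

subject to a fixed monomer count and a fixed expected filament tension
``F = sum p_i f_i`` with the sigmoidal force--length law
``f_i = f0 / (1 + exp(l0 - l_i))``. The maximiser is Boltzmann-like:

    p_i ∝ exp[(k_b' A_i/l_i − Vλ/(2TN) · f_i) / k_b]

where ``V``, ``λ`` and ``T`` are cell volume, prestrain and temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelParams",
    "LengthGrid",
    "DispersionGeometry",
    "LengthDistribution",
    "EntropyReport",
    "length_grid",
    "force_law",
    "force_law_eval",
    "dispersion_coefficients_closed_form",
    "dispersion_coefficients_literal_sum",
    "total_coverage",
    "formation_entropy",
    "dispersion_entropy",
    "expected_force",
    "total_entropy",
    "stationary_distribution",
    "stationary_distribution_mp",
]

#: Boltzmann constant as used throughout (J/K).
KB_DEFAULT = 1.38e-23

_PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the model.

    Defaults are the reference parameter set for a typical adherent
    vascular cell: N = 1000 monomers, T = 309.5 K, V = 6e-16 m^3,
    prestrain 0.2, compartment size a = 10 monomer lengths, maximum
    filament force 1 pN with sigmoid midpoint l0 = 80.

    Parameters
    ----------
    N : int
        Total number of actin monomers in the cell.
    T : float
        Cell temperature, kelvin.
    V : float
        Cell volume, m^3.
    lam : float
        Preexisting (homeostatic) strain, dimensionless.
    a : int
        Compartment size used to count spatial coverage, monomer lengths.
    f0 : float
        Maximum tension a single filament can bear, newtons.
    l0 : float
        Length at which the force--length sigmoid has maximum slope,
        monomer lengths.
    kb : float
        Boltzmann constant, J/K.
    kb_ratio : float
        Dimensionless ratio k_b'/k_b weighting dispersion entropy against
        formation entropy; k_b' is derived as ``kb_ratio * kb``.
    m : int or None
        Longest length class. ``None`` means ``m = N`` (a single filament
        containing every monomer is the longest conceivable class).
    """

    N: int = 1000
    T: float = 309.5
    V: float = 6e-16
    lam: float = 0.2
    a: int = 10
    f0: float = 1e-12
    l0: float = 80.0
    kb: float = KB_DEFAULT
    kb_ratio: float = 4.0
    m: int | None = None

    def __post_init__(self) -> None:
        if self.m is None:
            object.__setattr__(self, "m", int(self.N))
        for name in ("T", "V", "lam", "f0", "l0", "kb", "kb_ratio"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.N < 1 or int(self.N) != self.N:
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        if self.a < 1 or int(self.a) != self.a:
            raise ValueError(f"a must be a positive integer, got {self.a!r}")
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        if self.m > self.N:
            raise ValueError(
                f"m = {self.m} exceeds N = {self.N}: a filament cannot "
                "contain more monomers than exist"
            )
        if self.T <= 0 or self.V <= 0 or self.l0 <= 0 or self.kb <= 0:
            raise ValueError("T, V, l0 and kb must be positive")
        if self.lam < 0 or self.f0 < 0 or self.kb_ratio < 0:
            raise ValueError("lam, f0 and kb_ratio must be non-negative")

    @property
    def kb_prime(self) -> float:
        """Dispersion-entropy constant k_b' = kb_ratio * kb, J/K."""
        return self.kb_ratio * self.kb

    @property
    def force_multiplier(self) -> float:
        """Force-constraint Lagrange multiplier alpha = V*lam/(2*T), J/(K*N)."""
        return self.V * self.lam / (2.0 * self.T)

    @property
    def force_exponent_coeff(self) -> float:
        """Dimensionless coefficient V*lam/(2*T*N*kb) multiplying f_i in the
        stationary exponent (per newton)."""
        return self.V * self.lam / (2.0 * self.T * self.N * self.kb)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LengthGrid:
    """Integer filament lengths l_i = i for i = 1..m (monomer units)."""

    lengths: np.ndarray

    @classmethod
    def for_classes(cls, m: int) -> "LengthGrid":
        if m < 1:
            raise ValueError("m must be >= 1")
        return cls(lengths=np.arange(1, m + 1, dtype=np.int64))

    @property
    def m(self) -> int:
        return int(self.lengths[-1])


def length_grid(m: int) -> LengthGrid:
    """Length grid l_i = i for the first ``m`` length classes."""
    return LengthGrid.for_classes(m)


# ---------------------------------------------------------------------------
# Force--length law
# ---------------------------------------------------------------------------

def force_law(lengths: np.ndarray, params: ModelParams) -> np.ndarray:
    """Sigmoidal filament tension f_i = f0 / (1 + exp(l0 - l_i)), newtons.

    Short filaments barely engage the contractile meshwork (f -> 0) while
    long ones saturate at the maximal myosin-driven tension f0; the
    crossover sits at l0. Evaluated through the logistic function for
    overflow safety.
    """
    lengths = np.asarray(lengths, dtype=float)
    return params.f0 * expit(lengths - params.l0)


def force_law_eval(i: int, params: ModelParams) -> float:
    """Tension borne by one filament of length class ``i`` (newtons)."""
    if i < 1:
        raise ValueError(f"length class index must be >= 1, got {i}")
    return float(params.f0 * expit(float(i) - params.l0))


# ---------------------------------------------------------------------------
# Compartment-coverage (dispersion) combinatorics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionGeometry:
    """Compartment size ``a`` and per-class coverage coefficients ``A_i``.

    ``A_i`` is the maximum number of cytoplasmic compartments (each ``a``
    monomer lengths wide) that a single filament of length class ``i`` can
    touch: 1 for a monomer, 2 once the filament can straddle a compartment
    boundary, with one further compartment gained for every additional
    ``a`` monomers of length.
    """

    a: int
    A: np.ndarray

    @property
    def m(self) -> int:
        return len(self.A)

    def coverage_per_length(self) -> np.ndarray:
        """A_i / l_i — compartments covered per bound monomer.

        Decreases from 1 (free monomer) toward 1/a for long filaments.
        """
        lengths = np.arange(1, self.m + 1, dtype=float)
        return self.A / lengths


def dispersion_coefficients_closed_form(a: int, m: int) -> DispersionGeometry:
    """Coverage coefficients A_i in closed form.

    A_1 = 1; for i >= 2, A_i = floor((i - 2)/a) + 2: the coefficient steps
    up by exactly 1 every ``a`` length classes starting at i = 2.
    """
    _check_am(a, m)
    idx = np.arange(1, m + 1, dtype=np.int64)
    A = (idx - 2) // a + 2
    if m >= 1:
        A[0] = 1
    return DispersionGeometry(a=int(a), A=A)


def dispersion_coefficients_literal_sum(a: int, m: int) -> DispersionGeometry:
    """Coverage coefficients by literal enumeration of the block sums.

    Transcribes the nested-sum definition of the total coverage
    G = n1/l1 + sum_j sum_{i=2+a(j-1)}^{1+aj} (j+1) n_i/l_i term by term:
    block j (j = 1, 2, ...) assigns coefficient j + 1 to length classes
    2 + a(j-1) .. 1 + aj, truncated at m. Kept deliberately naive as an
    independent cross-check of the closed form.
    """
    _check_am(a, m)
    A = np.zeros(m, dtype=np.int64)
    A[0] = 1
    j = 1
    while 2 + a * (j - 1) <= m:
        lo = 2 + a * (j - 1)
        hi = min(1 + a * j, m)
        for i in range(lo, hi + 1):
            A[i - 1] = j + 1
        j += 1
    return DispersionGeometry(a=int(a), A=A)


def _check_am(a: int, m: int) -> None:
    if a < 1 or int(a) != a:
        raise ValueError(f"compartment size a must be a positive integer, got {a!r}")
    if m < 1 or int(m) != m:
        raise ValueError(f"m must be a positive integer, got {m!r}")


def total_coverage(n: np.ndarray, geom: DispersionGeometry,
                   grid: LengthGrid | None = None) -> float:
    """Total compartment coverage G = sum A_i * n_i / l_i.

    ``n_i / l_i`` is the number of filaments in class i, so G is the
    maximum number of compartments the whole filament population can
    occupy.
    """
    n = np.asarray(n, dtype=float)
    if len(n) != geom.m:
        raise ValueError(
            f"monomer-count vector has {len(n)} entries but geometry has {geom.m}"
        )
    if np.any(n < 0):
        raise ValueError("monomer counts must be non-negative")
    lengths = grid.lengths if grid is not None else np.arange(1, geom.m + 1)
    if len(lengths) != geom.m:
        raise ValueError("length grid does not match geometry")
    return float(np.sum(geom.A * n / lengths))


# ---------------------------------------------------------------------------
# Entropies and the expected tension
# ---------------------------------------------------------------------------

def _validate_probability(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-D probability vector")
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    s = p.sum()
    if abs(s - 1.0) > _PROB_SUM_TOL:
        raise ValueError(f"probabilities must sum to 1 (got {s!r})")
    return p


def formation_entropy(p: np.ndarray, params: ModelParams) -> float:
    """Formation entropy S_f = -kb * N * sum p_i ln p_i (J/K).

    Stirling-approximate entropy of the multinomial partition of the N
    monomers into length classes; zero entries contribute 0 (limit
    convention p ln p -> 0).
    """
    p = _validate_probability(p)
    nz = p[p > 0]
    return float(-params.kb * params.N * np.sum(nz * np.log(nz)))


def dispersion_entropy(p: np.ndarray, params: ModelParams,
                       geom: DispersionGeometry) -> float:
    """Dispersion entropy S_d = kb' * N * sum (A_i / l_i) p_i (J/K)."""
    p = _validate_probability(p)
    if len(p) != geom.m:
        raise ValueError("p and dispersion geometry have different lengths")
    return float(params.kb_prime * params.N
                 * np.sum(geom.coverage_per_length() * p))


def expected_force(p: np.ndarray, params: ModelParams) -> float:
    """Expected filament tension F = sum p_i f_i (newtons)."""
    p = _validate_probability(p)
    lengths = np.arange(1, len(p) + 1)
    return float(np.sum(p * force_law(lengths, params)))


@dataclass(frozen=True)
class EntropyReport:
    """Entropy decomposition and expected tension for one distribution."""

    S_f: float  # formation entropy, J/K
    S_d: float  # dispersion entropy, J/K
    S: float    # overall entropy S_f + S_d, J/K
    F: float    # expected filament tension, N


def total_entropy(p: np.ndarray, params: ModelParams,
                  geom: DispersionGeometry) -> EntropyReport:
    """Overall entropy S = S_f + S_d together with the expected tension."""
    S_f = formation_entropy(p, params)
    S_d = dispersion_entropy(p, params, geom)
    return EntropyReport(S_f=S_f, S_d=S_d, S=S_f + S_d,
                         F=expected_force(p, params))


# ---------------------------------------------------------------------------
# Stationary (maximum-entropy) distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthDistribution:
    """Stationary probability of monomer membership per length class.

    Attributes
    ----------
    p : ndarray
        p_i — probability that a monomer belongs to length class i.
    n : ndarray
        Expected monomer counts n_i = N * p_i (real-valued: the model is a
        continuum relaxation, filament counts n_i / l_i need not be whole).
    log_p : ndarray
        ln p_i, exact even where p underflows.
    log_partition : float
        Log of the normalising sum of exponentials.
    exponent_dispersion : ndarray
        Dimensionless dispersion term (kb'/kb) * A_i / l_i of the exponent.
    exponent_force : ndarray
        Dimensionless force term -V*lam/(2*T*N*kb) * f_i of the exponent.
    """

    p: np.ndarray
    n: np.ndarray
    log_p: np.ndarray
    log_partition: float
    exponent_dispersion: np.ndarray = field(repr=False, default=None)
    exponent_force: np.ndarray = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return len(self.p)

    def filament_counts(self) -> np.ndarray:
        """Expected filament counts n_i / l_i per class."""
        return self.n / np.arange(1, self.m + 1)


def stationary_exponent(params: ModelParams,
                        geom: DispersionGeometry | None = None) -> np.ndarray:
    """Dimensionless exponent (kb' A_i/l_i - Vλ/(2TN) f_i)/kb per class."""
    if geom is None:
        geom = dispersion_coefficients_closed_form(params.a, params.m)
    lengths = np.arange(1, params.m + 1)
    disp = params.kb_ratio * geom.coverage_per_length()
    frc = -params.force_exponent_coeff * force_law(lengths, params)
    return disp + frc


def stationary_distribution(params: ModelParams,
                            geom: DispersionGeometry | None = None
                            ) -> LengthDistribution:
    """Entropy-maximising length distribution in closed form.

    p_i ∝ exp[(kb' A_i/l_i − Vλ/(2TN) f_i)/kb], normalised over the m
    length classes. Evaluated in log space with max-exponent subtraction,
    so arbitrarily large user-supplied exponents cannot overflow.
    """
    if geom is None:
        geom = dispersion_coefficients_closed_form(params.a, params.m)
    if geom.m != params.m:
        raise ValueError("dispersion geometry does not match params.m")
    lengths = np.arange(1, params.m + 1)
    disp = params.kb_ratio * geom.coverage_per_length()
    frc = -params.force_exponent_coeff * force_law(lengths, params)
    expo = disp + frc
    if not np.all(np.isfinite(expo)):
        raise ValueError("non-finite exponent; check parameter values")
    shift = expo.max()
    w = np.exp(expo - shift)
    Z = w.sum()
    p = w / Z
    log_partition = float(np.log(Z) + shift)
    log_p = expo - log_partition
    return LengthDistribution(
        p=p,
        n=params.N * p,
        log_p=log_p,
        log_partition=log_partition,
        exponent_dispersion=disp,
        exponent_force=frc,
    )


def stationary_distribution_mp(params: ModelParams,
                               geom: DispersionGeometry | None = None,
                               dps: int = 50):
    """Closed-form distribution in arbitrary precision (mpmath).

    Returns ``(p, f)`` as lists of ``mpf`` — the probabilities and the
    per-class tensions — for cross-checks that exceed double precision
    (e.g. resolving the force multiplier when f0 is tiny).
    """
    import mpmath as mp

    if geom is None:
        geom = dispersion_coefficients_closed_form(params.a, params.m)
    with mp.workdps(dps):
        r = mp.mpf(params.kb_ratio)
        coeff = (mp.mpf(params.V) * mp.mpf(params.lam)
                 / (2 * mp.mpf(params.T) * params.N * mp.mpf(params.kb)))
        f = [mp.mpf(params.f0) / (1 + mp.e**(mp.mpf(params.l0) - i))
             for i in range(1, params.m + 1)]
        expo = [r * mp.mpf(int(geom.A[i - 1])) / i - coeff * f[i - 1]
                for i in range(1, params.m + 1)]
        shift = max(expo)
        w = [mp.e**(e - shift) for e in expo]
        Z = mp.fsum(w)
        p = [wi / Z for wi in w]
    return p, f
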