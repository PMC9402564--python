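# Methods

## Model

The cell is reduced to `N` identical actin monomers of unit length that
partition into filament length classes `i = 1..m` (`l_i = i`). Two
entropies drive the stationary length distribution `p`:

* **Formation entropy** `S_f = k_b ln W` with the multinomial state count
  `W = N!/(n_1!…n_m!)`, `n_i = N p_i`. In the Stirling limit this is the
  Shannon form `S_f = -k_b N Σ p_i ln p_i`. It rewards spreading monomers
  over many length classes (many microstates, robust to turnover
  fluctuations).
* **Dispersion entropy** `S_d = k_b' N Σ (A_i/l_i) p_i`, proportional to
  the maximum number of cytoplasmic compartments (width `a` monomer
  lengths) the filament population can cover. `A_i` is the per-filament
  coverage: `A_1 = 1`, and for `i ≥ 2` `A_i = floor((i-2)/a) + 2` — one
  extra compartment for every additional `a` monomers, because a filament
  only reaches a new compartment once it is long enough to straddle the
  boundary. `A_i/l_i` decreases from 1 to `1/a`: long filaments disperse
  monomers inefficiently. The weight `k_b'` (same units as `k_b`) sets the
  relative importance of dispersion vs formation; only the ratio
  `k_b'/k_b` enters the result, so the API exposes the ratio.

Maximizing `S = S_f + S_d` under `Σ p_i = 1` and a fixed expected
filament tension `F = Σ p_i f_i`, with the sigmoidal engagement law
`f_i = f0/(1 + exp(l0 - l_i))` (filaments much shorter than `l0` cannot
form force-bearing meshwork contacts; long ones saturate at `f0`), gives

    p_i ∝ exp[(k_b' A_i/l_i − Vλ/(2TN) f_i)/k_b],

where the force-constraint multiplier takes the value `α = Vλ/(2T)`
(cell volume `V`, prestrain `λ`, temperature `T`). The package treats
this closed form as the model's defining output and verifies it
numerically rather than re-deriving the thermodynamic identification of
`α`.

### Assumptions and known limitations

* Filaments are rigid 1-D rods; no bending, no 2-D/3-D packing, no
  excluded volume.
* `n_i = N p_i` is a continuum relaxation: filament counts `n_i/l_i` are
  not forced to be integers, matching the variational treatment that
  produces the closed form.
* No kinetics: the model is a stationary balance, not a
  polymerization/depolymerization process; no actin-binding proteins.
* With `k_b' = 0` the problem keeps a strictly concave objective and the
  closed form remains valid. The converse degeneration (`k_b → 0`,
  dispersion entropy alone) admits no interior stationary point — `S_d`
  is linear in `p`, so the Lagrange condition has no solution on the open
  simplex; `ModelParams` therefore requires `k_b > 0`.

## Parameters

| name | default | units | meaning |
|------|---------|-------|---------|
| `N` | 1000 | – | total monomers |
| `T` | 309.5 | K | cell temperature |
| `V` | 6e-16 | m³ | cell volume |
| `lam` | 0.2 | – | prestrain (typical of vascular cells) |
| `a` | 10 | monomer lengths | compartment size |
| `f0` | 1e-12 | N | maximal single-filament tension |
| `l0` | 80 | monomer lengths | force-sigmoid midpoint |
| `kb` | 1.38e-23 | J/K | Boltzmann constant |
| `kb_ratio` | 4 | – | dispersion weight k_b'/k_b |
| `m` | `N` | – | longest length class |

`kb_ratio = 4` is the package default because it is the mid-grid value
used for the reference force and prestrain analyses; the ratio sweeps
cover 1–10. `m` defaults to `N` — one filament containing every monomer
is the longest conceivable class — and is recorded in all sweep metadata
because the distribution tail depends on the truncation. When `m` falls
inside a coverage block, the block is simply truncated.

With the defaults the dimensionless exponent decomposes into a dispersion
part `(k_b'/k_b)·A_i/l_i` spanning `kb_ratio × (1 − 1/a)` and a force
part `−Vλ/(2TNk_b)·f_i ≈ −14.05·f_i/N(ewton)`; at `f0 = 1 pN` the force
part is ~1e-11 and the dispersion term dominates, at `f0 = 1 N` the force
part reaches −14 and carves a step at `l0`.

## Numerical choices

* **Normalization** is done in log space with max-exponent subtraction;
  `LengthDistribution` keeps `log_p` so distributions whose tail
  underflows in double precision can still be audited.
* **Zero convention**: `p ln p := 0` at `p = 0` in the formation entropy;
  the closed form itself never emits exact zeros analytically.
* **Coverage coefficients** exist twice on purpose: a closed form and a
  deliberately naive block enumeration; tests require exact elementwise
  equality.
* **Stationarity audits** report `max_i |∂L/∂p_i|` with
  `α = Vλ/(2T)` and `β` chosen as the midrange of the per-component
  gradients (the value that minimizes the max residual; at the closed
  form all components coincide, so the choice is immaterial there).
* **The independent maximizer** (`constrained_maximize`) is a primal-dual
  Newton iteration on the KKT system of the scaled problem
  `max −Σ p ln p + r Σ c_i p_i` s.t. `Σ p = 1`, `Σ g_i p_i = G`, with a
  fraction-to-boundary rule keeping `p > 0` and backtracking on the KKT
  residual norm. The objective Hessian is diagonal, so each step reduces
  to a 2×2 solve for the multiplier updates. Strict concavity makes the
  maximizer unique; multi-start runs are seeded and their seeds logged.
  It never touches the closed-form exponent code.
* **Extended precision**: with the default `f0 = 1 pN` and `m < l0` every
  class force is ≲1e-25 N, so the tension constraint is numerically
  degenerate in float64 — any multiplier in a huge range reproduces `p`
  to machine precision, and the force multiplier cannot be identified
  from double-precision arithmetic (the identification error is ~1e8
  relative). `constrained_maximize(dps=...)` therefore polishes the
  converged float64 solution in mpmath, rebuilding the force law and
  coverage ratios at working precision; the multiplier then matches
  `Vλ/(2T)` to far better than 1e-4. In well-conditioned regimes
  (`f0 = 1 N`, `m > l0`) float64 alone recovers it, which is unit-tested.
* **Degenerate inputs**: `m = 1` returns `p = [1]` everywhere;
  `F_target` outside the open interval `(min f, max f)` is rejected; the
  oracle refuses `m` above a configurable limit (default 200) to stay an
  honest brute-force check.
* **Determinism**: the closed form and all sweep outputs are
  deterministic; tables are written with 12 significant digits and
  period decimal separators so repeated runs are byte-identical
  (manifests carry SHA-256 checksums).

## Sweeps and trend checks

The model's published behaviour is qualitative, so the `sweeps` module
encodes it as machine-checkable assertions derived from the model's own
exponent arithmetic rather than from plot digitization:

* `kb_ratio ∈ {1,2,4,6,8,10}` (at `f0 = 1 pN`): `p_1` strictly increases;
  the spread obeys the exponent-range bound `p_max/p_min ≤ e^(r(1−1/a))`.
* `f0 ∈ {1e-12, 1e-6, 1e-4, 1e-2, 1}` N at `kb_ratio ∈ {0, 0.1, 4}`:
  classes above `l0` are suppressed at `f0 = 1 N`; with `kb_ratio = 0`
  the distribution shows two plateaus separated by a step at `l0`.
  Flatness at small `f0` is asserted against the exponent-spread bound
  `2·Vλ/(2TNk_b)·f0` (≈2.8e-3 at `f0 = 1e-4`, 2.8e-11 at 1e-12): the
  distribution is visually uniform at `f0 ≤ 1e-4` but only equal to
  uniform within ~1e-6 once `f0 ≲ 1e-7`.
* `l0 ∈ {20, 80}` at `kb_ratio = 0`, `f0 = 1 N`: the largest adjacent
  probability drop (the step detector) sits within ±2 classes of `l0`.
  The detector returns the class index maximizing `p_i/p_{i+1}`; the two
  indices adjacent to `l0` tie analytically, either is accepted.
* `λ ∈ {0.2, 0.8}` at `kb_ratio = 4`, `f0 = 1 pN`: distributions agree to
  <1e-6 relative (measured ~3.5e-11), because λ only scales the ~1e-11
  force exponent.
* `a ∈ {2, 5, 10, 20}`: `p_1` non-decreasing in `a`; companion tables
  document `A_i/l_i → 1/a`.

There is no synthetic data here in the usual sense — the model has no
data inputs — so passing tests demonstrate internal consistency and
faithfulness of the implementation to the model, not agreement with
measured filament-length distributions.

## Problem sizes

The verification suite and acceptance script use `m = 1000` (the default
`m = N`) for closed-form computations, `m = 50` for the oracle
equivalence runs, 20 randomized parameter sets for stationarity audits,
and `N = 10^5` for the exact-vs-Stirling comparison; everything completes
in seconds on one CPU.
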