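# Methods

## Model and assumptions

The sliding phase of facilitated target location is modeled as a
continuous-time Markov jump process on a 1D lattice of `N` base-pair
sites.  The protein starts at site 1 and is captured by a perfectly
absorbing trap at the target site; en route it may dissociate from the
DNA, which terminates that round of sliding (3D excursions after
dissociation are outside the model — a reacted walker simply leaves).

Assumptions baked into the model:

- **Uncorrelated quenched disorder.** Per-site binding free energies are
  iid Gaussian, `U_i ~ N(0, mu^2)` in `k_BT`, drawn once and held fixed.
  The zero mean is a convention: only energy *differences* enter the
  dynamics, so energies are measured relative to the nonspecific baseline.
  Sequence-specific energy inference (weight matrices, real genomes) and
  spatially correlated landscapes are out of scope.
- **Metropolis-capped Arrhenius hopping.** Per attempt time `1/nu` the hop
  probability across a bond is `alpha = (1/2) min{1, exp(-beta dU)}` with
  `dU` the destination-minus-current energy.  The `1/2` normalizes over
  the two directions, and the cap guarantees
  `alpha_right + alpha_left <= 1` at every site for arbitrary landscapes.
  The leftover `1 - alpha_right - alpha_left` is the sojourn probability.
- **Reaction through the sojourn channel only.** Dissociation fires with
  probability `sigma_i * sojourn_i` per attempt.  On a flat landscape the
  interior sojourn is exactly zero, so dissociation there can only occur
  at the origin (see boundary conventions below).
- **Uniform `sigma` by default.** The dissociation rate is argued to be
  dominated by the sequence-independent part of the binding energy, so a
  scalar `sigma` broadcast to all sites is the default; a truncated-
  Gaussian generator for site-dependent `sigma_i` (parameterized by mean
  and FWHM, resampled into (0,1)) is provided for sensitivity studies.
- **Dimensionless time.** All rates and times are in units of the attempt
  frequency `nu`; conversion to seconds happens only in the search-time
  arithmetic (`t = tau / nu`).

## Boundary conventions

The origin is reflecting: its left channel is deleted, and its reaction
rate uses its *actual* sojourn probability `1 - alpha_{2,1}` — a
consistent application of the reaction rule when one channel is absent.
Consequence: a flat landscape is not perfectly `sigma`-independent, because
the origin retains sojourn 1/2 there.  This convention is pinned down by
two closed forms that the tests enforce: the single-transient-site system
decays at rate `(1 + sigma)/2` (so `T_1/2 = 2 ln 2 /(1 + sigma)`), and the
three-site barrier system `U = (0, 1, 0)` with `sigma = 0.1` has a
conditioned mean of 7.2910227 steps.  The trap is perfectly absorbing: it
receives flux `alpha_{n,n-1} p_{n-1}` and has no outflux and no reaction.
The site adjacent to the trap keeps its full sojourn-weighted reaction
rate.  Both origin and near-trap choices affect observables at `O(1/N)`
for the 100-site systems studied.

## Numerical routes

- **Occupation probabilities**: stiff BDF integration of `dp/dt = Q p`
  with the constant Jacobian supplied, augmented with cumulative absorbed
  and reacted probabilities so conservation
  (`sum p + absorbed + reacted = 1`) is checkable on every grid point
  (defaults `rtol = 1e-8`, `atol = 1e-12`; tests verify agreement with a
  dense matrix-exponential oracle to `1e-8` per entry).  Integration stops
  at the horizon or when the transient mass falls below `1e-10`,
  whichever comes first (reported on the trajectory).
- **MFPT and reach probability**: resolvent moment method — two
  tridiagonal solves give `∫ p dt = (-Q)^{-1} p0` and
  `∫ t p dt = (-Q)^{-2} p0`, hence the reach probability
  `alpha_{n,n-1} [(-Q)^{-1} p0]_{n-1}` and the conditioned MFPT as a
  ratio, with no truncation-horizon bias.  The time-domain density is
  still produced for plotting and for the normalization check.  Because
  step times have unit mean, `-Q = I - P` for the discrete one-step matrix
  `P`, so the continuous-time conditioned means coincide exactly with the
  discrete-time (Monte Carlo) ones at every `sigma`; an independent
  h-transform oracle and a brute-force time-marching oracle confirm this
  in the tests.
- **Profiles** re-place the trap at each successive target site and
  re-solve, as the renormalization prescribes; `tau_1 = 0` by definition.
  Targets whose reach probability falls below `1e-12` are reported as
  gaps (NaN) — the conditioning is meaningless there — rather than
  failing a whole profile.
- **Survival and half-life**: the transient generator is a birth–death
  matrix, hence symmetrizable by the diagonal scaling
  `D_i = exp(-beta (U_i - U_1)/2)` (computed in log space).
  `eigh_tridiagonal` then gives `Sigma(t) = sum_k c_k exp(lambda_k t)` in
  closed form, and `T_1/2` is bracketed by doubling and polished with
  Brent's method (relative tolerance `1e-9`).  A trajectory-based route
  (monotone bracketing + log-linear interpolation on the solved grid)
  cross-checks the spectral one.
- **Monte Carlo (MCRW)**: strictly discrete time, one decision per
  attempt: a single uniform selects right/left/sojourn, and inside the
  sojourn branch a second uniform triggers reaction with probability
  `sigma_i` — reproducing the composite rule-iii probability exactly.  A
  run launches fresh trajectories from the origin until 1000 (by default)
  reach the trap.  Per-site means pool *all* trajectories that visited a
  site: any walker that reached a far site passed every nearer site
  first, and its first-visit times there are fixed before any later
  event, so the pooling is unbiased (verified empirically by moving the
  trap).  The inner loop is a numba kernel driven by one seeded stream
  per run; runs are bit-reproducible given the seed.
- **Power-law fits**: ordinary least squares in log10–log10 coordinates.
  Default windows: plateau `sigma in [1e-7, 1e-5]`, screening
  `sigma in [3e-4, 3e-2]`, log-uniform grids with at least 6 points per
  decade; both windows are plain function arguments.  The regime
  crossover is the closed-form intersection of the two fitted lines.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `mu` | 0.75 `k_BT` | landscape roughness (the biologically "optimal" value; `~k_BT` is the physiological scale) |
| `beta` | 1 | inverse temperature; energies are already in `k_BT` |
| `N` | 100 sites | twice the exploration length, long enough to bury origin effects |
| `sigma` | scan `1e-7..1e-1` | per-attempt dissociation probability scale |
| `nu` | `1e8` Hz | attempt frequency of the protein–DNA complex |
| `L` | `1e6` bases | searched sequence length (genome scale) |
| `Lambda` | 50 bases | exploration length per sliding round (restriction-enzyme estimate) |
| realizations | 20 (disorder averages), 10 (seed spread of headline numbers) | |
| MCRW successes | 1000 | termination rule of the validation protocol |

## What the generator emulates — and what it does not

The synthetic landscapes reproduce the Gaussian, spatially uncorrelated
statistics that genome-wide weight-matrix energies approximate for
bacterial transcription factors.  They do *not* contain sequence
correlations (AT/GC-rich isochores, curvature), a distinct target-site
energy well, nonspecific-energy offsets, or crowding; passing tests
therefore demonstrate the transport/first-passage machinery and its
internal consistency, not agreement with any particular genome.  The
search-time conversion inherits the strong assumptions `t_Lambda = t_3D`
and `t_Lambda = tau_50 / nu`; its output is a *minimum* search time.

## Design choices where the design was open

- The roughness estimator divides by `N` (population RMS): the roughness
  is defined as an ensemble-average fluctuation.  The convention is noted
  in landscape metadata.
- Site-dependent `sigma_i` are truncated-Gaussian by mean/FWHM with
  resampling, the simplest law matching the stated facts while keeping
  `sigma_i` a valid probability.
- Disorder-average sub-seeds come from `numpy.random.SeedSequence`
  spawned off the base seed (recorded per realization, kept below 2^31).
- The MCRW uses one seeded stream per run rather than per-trajectory
  substreams; trajectories are consumed sequentially, so this is equally
  reproducible and simpler.
- After a reaction the next Monte Carlo attempt is an independent
  trajectory (fresh walker at the origin), not a continuation of elapsed
  time; for per-site means the two readings are equivalent under the
  fixed-success termination rule.
- The roughness-trend property (disorder-averaged `tau_50` increasing in
  `mu`) is probed reaction-free: for `mu >= 2` and `sigma ~ 1e-3`
  essentially no walker survives 50 sites, so the conditioned MFPT is
  undefined there (reach probability underflows) and the trend is only
  well-posed at `sigma = 0`.

## Known limitations

- `Sigma(t)` excludes trap occupancy by design (a captured walker has
  left the search); with it included the curve would not decay at
  `sigma = 0`.
- The spectral half-life route assumes strictly positive hop rates
  (always true for the capped Arrhenius rule with finite energies) and
  dense eigensolves, fine for `N` up to a few thousand.
- Conditioned statistics degrade gracefully but inevitably as
  `reach -> 0`: below reach `1e-12` the package refuses to condition and
  reports a gap instead.
- The problem sizes of the shipped analyses (100 sites, 10–20
  realizations, 1000 Monte Carlo successes) are the study's own; all
  sweep functions accept larger grids and realization counts.
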