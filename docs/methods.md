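# Methods

## The physical model

Passive polystyrene beads (radius `a = 5 um`) suspended with swimming
*Chlamydomonas reinhardtii* in a quasi-2D channel of width `2W` move in two
modes: weak thermal diffusion with `D0 = kB T / (6 pi eta a) ~ 0.044
um^2/s` (Stokes–Einstein at 21 °C, `physics.stokes_einstein_diffusivity`),
and fast, nearly straight *jumps* caused by encounters with swimmers.
Because the algae themselves distribute and orient inhomogeneously near
walls, the jump process is space-dependent.  On the folded coordinate `y`
(distance to the nearest wall) it is characterised by three fields:

- `lambda(y)` — encounter (jump initiation) rate, 1/s;
- `L+(y)`, `L-(y)` — characteristic lengths (um) of the wall-normal jump
  projection `y_J`, away from and toward the wall.

The projection kernel is a two-sided exponential,

    q_y(y_J) = exp(-|y_J| / L±(y)) / (L+(y) + L-(y)),

with first and second moments `m1 = L+ - L-` and
`m2 = 2 (L+^3 + L-^3) / (L+ + L-)`.  All three fields are parametrised by
exponential relaxation from a wall value to a bulk value over decay
lengths `l+`, `l-`, `l_lambda`, offset by `y_col` (the closest wall
distance accessible to the bead centre, one radius by default).  The
packaged configuration `data/channel100_profile.cfg` carries the fitted
values for the 100 um-wide channel: `L_bulk = 3.70 um`, `l+ = 5.05 um`,
`l- = 10.8 um`, `lambda_wall = 0.237 /s`, `lambda_bulk = 0.315 /s`,
`l_lambda = 8.20 um`, with the wall length fixed at 0.375 um.

Because `l- > l+`, `L+ > L-` at intermediate distances: jumps have a net
outward bias there (`m1 > 0`), which is what depletes the 10–20 um band
while the small near-wall kernel plus the wall-stopping rule accumulate
beads at the boundary.

## Continuum description

The density `P_t(y)` obeys a nonlocal master equation: diffusion, loss of
probability by jumping away at rate `lambda(y)`, and gain by jumps
arriving from elsewhere with kernel `q` evaluated at the *origin* of the
jump.  `continuum.master_equation_propagate` integrates it explicitly on a
uniform grid; the jump redistribution matrix assigns kernel mass that
would land past a wall to the boundary cell (the stopping rule of the
stochastic scheme) and folds mass crossing the channel axis back by
symmetry.  Probability is conserved to round-off per step by
construction.

Truncating the Kramers–Moyal expansion of the master equation at second
order gives a drift-diffusion equation with

    D_eff(y) = D0 + lambda(y) m2(y) / 2
    V_eff(y) = lambda(y) m1(y) - 1/2 d/dy [lambda(y) m2(y)]

whose no-flux steady state is closed form:

    P(y) = B / D_eff(y) * exp( int^y lambda m1 / D_eff dy' ).

When `m1 = 0` this reduces to `P ~ 1/D_eff` (state-dependent diffusion in
the Itô convention), and to a uniform profile when `D_eff` is also
constant.  For this Fokker–Planck form the equivalent Itô SDE drift is
`b = V_eff + dD_eff/dy`, which simplifies exactly to `lambda(y) m1(y)`;
the mean-first-passage solver uses `b` in the standard double quadrature
with one absorbing and one reflecting end.

Validity: the truncation assumes jump sizes small compared to the scale
of the heterogeneity.  With the fitted field the ratio is ~`3.7/10`, not
asymptotically small, and the grid-converged total-variation distance
between the master-equation steady state and the closed form is ~0.014
(1 um bins), concentrated in the first ~2 um at the wall where the closed
form overshoots the boundary peak by ~20%.  With jump lengths scaled down
four-fold the same code gives TV ~0.001, confirming that the gap is
truncation error, not discretization.  The stochastic simulator and the
master equation agree closely (wall-bin mass 0.042 vs 0.041).

## Stochastic simulator

`simulator.simulate` implements the per-step acceptance–rejection scheme:
a uniform draw triggers a jump when it falls in the centred interval
`[(1 - lambda dt)/2, (1 + lambda dt)/2]` (probability `lambda(y) dt`,
implemented verbatim in its centred form), with the displacement drawn
from `q_y` by inverse transform; otherwise a Gaussian step of variance
`2 D0 dt`.  Jumps are instantaneous; a jump crossing a wall stops at one
radius from it, diffusive crossings reflect.  Defaults follow the
standard protocol: `dt = 0.1 s`, 100 trajectories of 10,000 steps,
burn-in one tenth of the run (the slowest relaxation time is ~50 s, so
500 discarded seconds is ample; the distribution comparisons in the test
suite use 2000 x 55,000-step runs with 5,000-step burn-in, i.e. 1e8
retained samples, for a TV noise floor of ~0.003).

Three ablations probe the ingredients: `const-rate` (`lambda := bulk`),
`no-diffusion` (`D0 = 0`), `homog-kernel` (isotropic bulk kernel
everywhere).  The homogeneous kernel removes the depletion band and
sharpens the boundary peak.  The other two change the distribution only
through the first 1-um bin, but not negligibly under the fitted kernels:
the exact (master-equation) systematics are TV = 0.023 and 0.024
respectively.  The `D0 = 0` case is dominated by a point mass pinned at
exactly `y = a`: with zero thermal motion, a bead stopped at the wall can
only detach through an away-jump of typical size 0.375 um, and toward-
jumps truncate to zero displacement.  Fitted kernels drop the
slower-than-exponential positive tails observed very close to the wall,
which would otherwise unpin this atom; this is a known limitation of the
exponential-kernel idealisation at the boundary.

## Synthetic trajectory generator

`synthetic.generate_channel_trajectories` emulates 10 fps tracking of
beads in the channel with ground-truth labels.  Free beads diffuse with
`D0` and initiate jumps with per-frame probability `lambda(y) dt`.  The
wall-normal jump component is drawn exactly from `q_y` at the starting
position; the wall-parallel component is an independent two-sided
exponential with the bulk length as scale, so jumps near the wall (small
`L±`) are automatically wall-parallel, as observed, while the y-marginal
— the only quantity the downstream analysis consumes — is exactly the
configured kernel.  Jumps are rendered as straight segments over
`max(2, ceil(length / (v_jump dt)))` frames with `v_jump = 30 um/s`; the
two-frame floor models the finite duration of an encounter and makes
events resolvable by correlation-based detection.  Jumps stop at the wall
offset; diffusive moves reflect.  Optional localization noise is off by
default (not quantified for the source data).

What the generator does *not* emulate: the short-time excess of waiting
times from rapid repeat encounters with the same swimmer (waits are
exactly geometric), the fat positive `y_J` tails next to the wall, curved
jump paths, and hindered near-wall diffusion.  Passing recovery tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to every feature of real microscopy data —
the `t_min` and `lim(y)` windows exist precisely for those features.

## Detection and estimation

`detection.detect_jumps` marks a displacement as a jump candidate when it
exceeds `k sqrt(4 D0 dt)` (`k = 3`) *and* its cosine with the previous or
next displacement exceeds 0.5; candidate runs separated by at most one
frame are merged and events shorter than two displacement frames are
discarded.  All four numbers are exposed parameters.  On labelled
synthetic data the defaults give recall 1.0 for jumps >= 4 um, ~0.97
overall in the bulk, and no false positives in a 10^4-second pure
Brownian control (the single-frame threshold crossing probability is
~1e-4 and the correlation gate removes those).

Waiting times are measured between the end of one detected jump and the
start of the next, positioned at the wall distance where the wait begins;
censored waits at trajectory ends are excluded.  Rates come from the
exponential tail (`t > t_min = 3 s`, below which repeat encounters
distort the distribution).  The default estimator regresses the log
empirical survival function: benchmarking against exact exponential
samples showed the log-histogram variant biased low by 8–20% at realistic
per-bin sample sizes (zero-truncated far-tail bins flatten the slope),
while the survival regression is unbiased; the histogram variant remains
available.  Reported rate SEs are floored at the asymptotic
`rate/sqrt(n_tail)` because survival-regression residuals are strongly
autocorrelated.

Jump lengths use affine fits to the log-histogram of each side of `y_J`
(1 um bins, Poisson-count weights — the proper GLS weighting for log
counts) inside `min_cut = 1 um < |y_J| < lim(y)`, with the per-bin window
schedule 7, 12, 12, 15, 15, 18, 20, 20 ... um.  Spatial bins are 10/3 um
wide starting at `y_col`, both walls folded together.

`fitting.fit_profiles` reduces the binned estimates to the relaxation
laws by weighted nonlinear least squares (`scipy.optimize`): `L+` and
`L-` jointly with a shared bulk length and the wall value fixed at
0.375 um, `lambda(y)` separately.  Starts are deterministic endpoint
heuristics (wall bin; mean of the outer three bins).  End to end
(generate → detect → bin → fit) at the study scale of 120 tracks x 600 s
(~20k events), the bulk rate is recovered within ~3% and the bulk length
within ~9% across seeds; the wall-side rate parameters are biased low by
~10% because sub-0.8-um jumps (common near the wall where the parallel
component dominates the magnitude) fall below the detection threshold.

## De-mixing kinetics

Two compartments (chamber ↔ side channels) exchange at rates `k_in`,
`k_out`; `demixing.kinetics_solution` gives the exact exponential
relaxation with time scale `1/(k_in + k_out)` and stationary fractions
`k_out/(k_in+k_out)`, `k_in/(k_in+k_out)`.  `fit_kinetics` fits `N_s(t)`
with the total fixed to its mean (and errors if the total drifts beyond
5%, since conservation is a model assumption); parameter SEs are inflated
by the AR(1) effective-sample-size factor `sqrt((1+rho)/(1-rho))` because
occupancy noise is a Markov process and iid errors understate the
uncertainty ~5-fold at typical sampling.  With the reference rates
`k_in = 7.8e-5 /s`, `k_out = 13.9e-5 /s` the derived observables are
`tau = 76.8 min` and chamber fraction 0.64.  `demixed_fraction` evaluates
the two-chamber design ratio `k_in/(k_in + k_ref)`.  The geometric
first-passage route to `k_in` (MFPT of the effective dynamics averaged
over the stationary density, times an entrance perimeter fraction) is
exposed through `continuum.mfpt` with the perimeter fraction as an
explicit parameter, since the side-channel geometry needed to fix it is
not part of this package's inputs.

## Numerical choices

- Steady-state exponent integral: cumulative trapezoid from the wall-side
  grid end; the reference point is absorbed into the normalisation.
- Flux diagnostic on the staggered midpoint grid (centred differences
  everywhere); one-sided edge stencils would dominate the residual inside
  the wall boundary layer.  At 1 nm-scale spacing the residual is < 1e-6
  of the peak advective flux.
- Master equation: explicit Euler, CFL guard `D0 dt / h^2 <= 0.5`,
  negative-mass guard at 1e-9; kernel rows integrate the exact two-sided
  exponential CDF over cells.
- Effective fields: analytic profile derivatives for parametric fields,
  centred differences (with a coarse-grid warning at spacing above a
  tenth of the shortest decay length) for tabulated ones.
- MFPT quadratures are exact for constant coefficients (trapezoid on
  linear integrands), matching `T(y) = (2Wy - y^2)/(2D)` to round-off.
- All randomness flows through explicit `numpy.random.Generator` seeds;
  identical seeds give bit-identical outputs, and every CLI run writes a
  manifest (config snapshot, seed, file digests, version).

## Known limitations

- The exponential-kernel idealisation at the wall (dropped fat positive
  tails) exaggerates boundary pinning when `D0 = 0` and is the main
  source of the residual simulator-vs-closed-form discrepancy.
- The drift-diffusion reduction is used at a jump-to-heterogeneity scale
  ratio of ~0.3; its boundary peak is ~20% high relative to the exact
  jump process.
- The 2D de-mixing chamber with discrete side channels is reduced to 1D
  effective dynamics; absolute `k_in` predictions require an external
  entrance-geometry factor.
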