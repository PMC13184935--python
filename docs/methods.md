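# Methods

## The three-state washout model

A single ligand species exchanges between three well-mixed pools: bound to
protein sites of total concentration `P_t`, free in the membrane (`M`), and
free in the aqueous bath. Association to the protein happens from the
membrane at rate `k_a·M` per free site; dissociation back into the membrane
at `k_-a`; membrane/water exchange at `k_lw` (exit) and `k_wl` (entry).
During drug application the bath is clamped at the perfusate concentration;
during washout it is clamped at zero, so `k_wl` is inactive. The observable
is fractional occupancy `b`, mapped linearly to current,
`I = I0·(1 + (fold − 1)·b)`; whether channel gating introduces a
nonlinearity between occupancy and current is unknown, and linearity is the
simplest defensible choice.

Two solvers are provided:

* **linear** (`washout_linear`): ignores site depletion (`dB/dt =
  k_a P_t M − k_-a B`), solved exactly by eigen-decomposition of the 2×2
  rate matrix, with an LSODA fallback for (near-)defective matrices. Valid
  below saturation; the trajectory container rejects occupancies outside
  [0, 1].
* **saturable** (`washout_saturable`, `clamped_water_trajectory`): full
  mass-action kinetics with site depletion. The quasi-equilibrium variant
  assumes instantaneous binding equilibrium (`k_a P_t ≫ k_lw`) and
  integrates one ODE for total ligand, `dL/dt = −k_lw·M(L)`, with `M(L)`
  from the binding isotherm; the full two-variable integration serves as
  its reference. Both use LSODA at rtol 1e-10.

### Limiting regimes and the 1.53 prefactor

With `k_lw ≫ k_a[P_t]` (fast membrane exit) protein dissociation is rate
limiting and `T = 1/k_-a`. With `k_a[P_t] ≫ k_lw` (fast rebinding) the decay
is not exponential; in the saturated limit `P_t ≫ K_d` with membrane load
small against the bound pool it collapses onto the parameter-free curve
`s(b) = ln(b0/b) − (b0 − b)` in scaled time `s = t·K_d·k_lw/P_t`. A
free-amplitude least-squares exponential fitted to this curve down to ~2% of
the initial occupancy gives `T = P_t/(1.53·K_d·k_lw)`. The constant is a
property of the fitting convention, not of the dynamics: it moves to ~1.57
for a 5% fit window and to ~1.46 for shallow initial occupancy (b0 ≈ 0.8).
`single_exp_prefactor_numeric` reconstructs it by direct integration under
frozen default conditions — `P_t = 1000·K_d`, `k_a·P_t = 1e5·k_lw`, start
from the steady state of a saturating bath (`M0 = 100·K_d`, `b0 = 0.990`),
fit to 2% — giving c = 1.5405 with quasi-equilibrium and full kinetics
agreeing to 1e-5. The regime classifier uses a factor-10 threshold for
"much greater than" (configurable).

## Synthetic traces

`generate_trace` concatenates baseline, drug and washout segments sampled at
500 Hz. Occupancy is integrated with the full saturable kinetics (loading
from zero, washout from the loaded end state). Noise is additive white
Gaussian with SD given relative to baseline current; each segment draws from
a substream of one `SeedSequence`, so a single integer seed fixes the whole
trace. An optional two-pass moving-average low-pass stands in for the
recording chain's anti-alias filter; it is off by default because it is
irrelevant for time constants well above 10 ms. Rundown, seal leak and
single-channel gating noise are deliberately absent — passing tests show the
estimators work on the model's own terms, not that they are robust to every
patch-clamp artifact.

Preset parameters (arbitrary concentration units, seconds):

* shared: `k_a = 10`, `k_-a = 1` (so `K_d = 0.1`), `k_wl = 1`, `P_t = 1` —
  protein–ligand affinity is taken to be R-group independent;
* per analog: `k_lw` from the logP scaling anchored at the isobutyl R group
  (logP 2.0, `k_lw = 1/s`): hexyl logP 3.0 → 0.316/s, decyl logP 5.0 →
  0.0316/s. These fragment-estimate logP defaults (~0.5 per CH2) are
  configurable inputs, not measured values. Fold-potentiations are the
  measured means (2.94, 1.74, 2.52); the NBD-labelled analog mirrors the
  parent's kinetics and fold, since it is only reported to wash out on the
  parent's time scale;
* default bath concentration 250 (= 2500·K_d): saturates occupancy to
  b ≈ 0.9996 so that noiseless plateau ratios recover the preset fold to
  three significant figures;
* `default_protocol` sets the drug phase to 12 membrane-exchange time
  constants (loading is bottlenecked by membrane entry at rate `k_lw`) and
  the washout to the reservoir-drain plateau plus six fast-rebinding decay
  constants.

All preset analogs sit in the fast-rebinding regime, and their washout
decays are visibly non-exponential: the loaded membrane (`M0` thousands of
`K_d`) first drains with occupancy pinned near 1, then occupancy decays.
Fitted time constants therefore exceed `P_t/(1.53·K_d·k_lw)` but scale with
`1/k_lw` and order strictly with chain length.

## Fitting conventions

* **Potentiation**: mean current over the final 25% of the drug segment
  divided by the same for baseline. The 25% plateau excludes equilibration
  transients without kinetic assumptions; both plateaus must span ≥ 1 s.
* **Washout fit**: `offset + amplitude·exp(−(t−t0)/tau)` by trust-region
  least squares (xtol 1e-8, ≤ 200 iterations, amplitude and tau bounded
  positive). The free offset absorbs residual baseline current. Initial
  guesses: offset and amplitude from endpoint means, tau from log-linear
  regression on the upper half of the decay. The window runs from washout
  start to the 5%-of-amplitude crossing, detected on a lightly smoothed copy
  so single noise samples cannot truncate it, or to segment end. The fit
  refuses decays smaller than 3× a robust noise estimate (median absolute
  first difference).
* **effective_tau** (occupancy level): same idea without the offset, on the
  normalized decay; window fraction exposed (5% default, 2% for the
  prefactor reconstruction). The free-offset and amplitude-only conventions
  agree to <1e-3 only where the decay is near-exponential; on saturated
  decays they differ by construction, which is why consistency is asserted
  in the fast-exit regime.
* **Replicates**: mean ± sample SD (n−1); a single replicate reports SD 0
  with a warning.

## The logP rate model

Predicted washout rate: `A·10^(−logP/2)`; pairwise `k_lw` ratios follow
`10^((logP2−logP1)/2)` independently of `A`. The prefactor is fitted by
minimizing `Σ_i (T̄_i/T̂_i − 1)²` over analogs (per-analog mean time
constants, one point per analog, matching how replicate SD bars are drawn),
which weighs analogs equally instead of favoring slow ones. The residual is
linear in `A`, so the minimizer is closed form (`A = Σu/Σu²`,
`u_i = T̄_i·10^(−logP_i/2)`); a log-ratio loss is available as an option.
r² is computed on per-analog mean rates about their grand mean, so a
perfect ratio fit with noisy replicates still reports r² < 1.

## Toy weighted-ensemble sampler

Overdamped Langevin dynamics `x ← x − D·U′(x)·dt + sqrt(2D·dt)·ξ` (kT = 1)
on named 1-D potentials (double well `h·(x²−1)²`, tilted, flat). Fixed bins
over the progress coordinate, target 4 walkers per bin; underpopulated bins
split their heaviest walker (weight halved), overpopulated bins merge the
two lightest (survivor drawn proportionally to weight; a deterministic mode
keeps the heavier for tests). Total weight is conserved to 1e-12 and checked
every round. Walkers crossing the recycle boundary are returned to the
source with weight intact; the recycled weight per round, averaged over the
second half of the history, divided by the round time, is the steady-state
rate estimate (Hill relation: equal to the inverse mean first-passage time).
Uncertainty comes from a block bootstrap with blocks of a tenth of the
retained history, long enough to span the slow weight-redistribution
correlations that dominate the flux signal. The timestep must keep the
per-step displacement SD under 10% of the smallest bin width; this is
validated when an ensemble is initialized, where both quantities are known.

The brute-force oracle runs independent first-passage events (vectorized,
with an optional reflecting wall behind the start) and reports
`1/mean(FPT)` with a delta-method SE. At the validation settings (double
well, barriers 4–6 kT, D = 1, dt = 2e-4, bins of 0.25 over [−1.25, 1],
round length 250 steps, 2400–3000 rounds) the WE estimate agrees with brute
force within two combined SD; runs of ~600 rounds are visibly still in the
flux build-up transient. This module validates the estimation methodology
at desk scale only; it deliberately replaces the all-atom protein/membrane
system, whose sampled energy profiles are far from converged, and its
simplified flux averaging is not a reimplementation of WESTPA's equilibrium
reweighting numerics.

## Problem sizes and determinism

The packaged test suite and the acceptance script run in a few minutes on
one core: the prefactor integration uses a 20 000-point grid; potentiation
round trips use the reported replicate counts (7/3/4) at 500 Hz;
tau-recovery checks use 100 seeded C3 traces; the scale-recovery study uses
500 trials of 4 analogs × 5 replicates with σ = 0.2 lognormal noise; WE
validation uses one 2400-round run against 100 brute-force events. Every
stochastic component takes an explicit integer seed; per-replicate seeds
derive from one root seed via `SeedSequence`, making pipeline outputs
byte-identical across runs.

## Known limitations

* Compartments are well mixed: no lateral diffusion in the membrane, no
  local depletion near the protein.
* Current is strictly proportional to occupancy; CFTR gating microstates
  are not modelled.
* The saturable model assumes one ligand per site and no cooperativity.
* R-group logP defaults are fragment estimates; measured partition
  coefficients should be supplied for real analyses, and absolute `k_lw`
  values are only defined up to the anchor choice.
* The reported 1.53-based time constant applies to the saturated
  fast-rebinding regime; intermediate regimes need the numerical model.
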