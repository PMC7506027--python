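# Methods

## Model

`einet` simulates a two-population Wilson–Cowan-type spiking network.
Population `n ∈ {e, i}` has `N_n` cells; cell `j` carries a dimensionless
membrane activity `u_j^n(t)` relaxing with rate constant `a_n` (Hz) toward
the sum of its inputs:

- recurrent input: the population-normalized, weighted count of spikes
  emitted in the previous integration step, `w^{en}·(E count)/N_e +
  w^{in}·(I count)/N_i`, with homogeneous all-to-all coupling
  (self-connections included — the `O(1/N)` self-term is negligible and
  keeps spiking and mean-field models exactly comparable);
- baseline drive `I^n`, plus a tonic drive `I_o(t)` to the excitatory
  population only (the control parameter of the seizure-like transition);
- a global stimulus `S(t)`, identical at every cell;
- intrinsic Gaussian white noise, independent per cell and step.

Spiking is a per-step Bernoulli draw with probability
`f[u] = (1 + exp(−β(u−h)))⁻¹` (gain `β = 300`, threshold `h = 0`), and a
spike contributes exactly 1 to the next step's synaptic count (a pulse is
"amplitude held for one step", not an impulse scaled by `1/dt`). Under this
convention the time-average of a cell's spike indicator equals the
time-average of `f[u]`, which is precisely the diffusion approximation the
mean-field reduction rests on — no extra constants appear anywhere in the
chain from spiking model to population equations. Bernoulli (at most one
spike per cell per step) rather than Poisson thinning keeps rates bounded
by `1/dt` and matches the raster semantics.

Reference parameters (the defaults of `NetworkParams`): `N_e = 800`,
`N_i = 200`, `a_e = 100` Hz, `a_i = 200` Hz, `w_ee = 1.60`, `w_ei = 3.00`,
`w_ie = −4.70`, `w_ii = −0.13` (inhibitory weights carry their sign),
`I_e = −0.25`, `I_i = −0.50`, `dt = 1` ms. Rate constants are specified in
Hz and `dt` in ms; all internal arithmetic converts to seconds once, at the
point of use.

## Noise calibration — the central convention

The simulator's membrane update is Euler–Maruyama:

    u ← u + a·dt·(−u + inputs) + σ·z,   σ² = 2·a·D·dt·(1 − a·dt/2)

so that the stationary variance of a decoupled cell's membrane is exactly
`D`, identically for both populations (the factor `(1 − a·dt/2)` removes
the finite-step bias of the plain Euler scheme, whose stationary variance
would be `D/(1 − a·dt/2)` — a +5%/+11% error at `dt = 1` ms). The
mean-field reduction consequently uses the deviation law `N(0, D̄)` with
intrinsic part `D̄ = D`.

This calibration — rather than the rate-scaled alternative `D̄ = a·D` — is
a deliberate design decision, and the single most consequential one in the
package. With `D̄ = a·D` the maximal slope of the smoothed transfer would
be `w_ee/√(2π·a_e·D) ≤ 0.90 < 1` for every `D ≥ 0.005`, making the reduced
system provably monostable at all drives: no folds, no multistability, no
abrupt transition for any parameter in the studied range. With `D̄ = D`
the model reproduces the entire phenomenology this package exists to
analyze, quantitatively:

- at `D = 0.005` a three-equilibria drive interval `[0.0101, 0.0729]`
  (midpoint ≈ 0.042, i.e. multistability for drives near 0.05), bounded by
  two saddle-node points;
- at `D = 0.01` a narrow interval `[0, 0.014]` — an abrupt uptick of the
  excitatory steady state as `I_o` passes ~0.01;
- no interval at `D = 0.025` or `0.05`;
- on the upper branch an unstable focus ringing at ≈ 93 Hz (gamma range);
- steady states shifting to lower `u_e` pointwise as `D` grows.

The rate-scaled form is still provided (`effective_noise_variance`) for
the white-noise-input convention where it is the correct stationary
variance; the equilibrium and stability machinery uses
`deviation_variance`, i.e. `D̄ = D + a·D_s·f_c/(a + f_c)`.

The extrinsic term is exact, not a convention: a global
Ornstein–Uhlenbeck stimulus of stationary variance `D_s·f_c` and cutoff
`f_c`, low-pass filtered by a membrane of rate `a`, contributes variance
`a·D_s·f_c/(a + f_c)` to the deviations. Its limits behave as expected:
`→ a·D_s` as `f_c → ∞` (white-noise ceiling), `→ 0` as `f_c → 0`.

## Mean-field reduction and stability

For a hard threshold the effective transfer is the Gaussian CDF
`F[u] = ½(1 + erf(u/√(2 D̄)))`, with slope `R[u]` the normal density. A
finite-gain oracle (`effective_transfer_quad`) integrates the `β = 300`
logistic against `N(0, D̄)` by composite Gauss–Legendre quadrature with
panels split at the sigmoid's transition layer; plain Gauss–Hermite is
avoided because the near-step integrand defeats its convergence (measured
sup error 3×10⁻² at 200 nodes versus ~10⁻⁵ for the panel-split rule). The
closed form and the oracle agree to better than 2×10⁻³ sup-norm for
`D̄ ≥ 0.05`.

Equilibria: for fixed `u_e` the inhibitory equation
`u_i − w_ii F_i[u_i] = w_ei F_e[u_e] + I_i` has a unique root whenever
`w_ii ≤ 0` (the left side is strictly increasing); it is solved by
vectorized Newton on dense grids and by Brent's method when polishing.
Substituting leaves a scalar residual in `u_e`, scanned on a bracketing
grid over `[I_e + I_o + min(w) − 6√D̄, I_e + I_o + max(w) + 6√D̄]` (the
transfer saturates outside a few standard deviations, bounding all fixed
points). The default grid of 20 000 points resolves root pairs down to a
few 10⁻⁴ in `u_e`, which matters near folds: a coarser scan silently
merges the colliding pair and misplaces the saddle-node by several 10⁻⁴
in drive. Residuals at returned points are below 10⁻¹⁰; duplicates within
10⁻⁶ are merged. An endpoint of the three-equilibria interval is refined
by bisection to 10⁻⁴ in `I_o`.

Stability: the rate-scaled Jacobian is

    J = [[a_e(−1 + w_ee R_e),  a_e w_ie R_i],
         [a_i w_ei R_e,        a_i(−1 + w_ii R_i)]]

with `R` evaluated at the equilibrium. Eigenvalues are computed twice —
closed form `λ± = G/2 ± √H/2` with `G = tr J` and `H = G² − 4 det J`
written out in the weight/slope symbols, and direct eigendecomposition —
and any disagreement beyond 10⁻⁹ relative is a hard error (a bug trap;
the two are mathematically identical). Damping is `Re λ` (1/s),
eigenfrequency `|Im λ|` reported in both rad/s and Hz; an equilibrium is
stable iff the leading damping is negative. Only the sign of the damping
and the saddle-node structure are classified; continuation of the limit
cycle beyond the fold is out of scope (oscillation properties are read
from simulations).

## Stimulation waveforms

Four families, all global:

- **pulse**: amplitude `S0` on one step per period; period realized as
  `round((1000/f_s)/dt)` steps (frequencies are taken from a discrete
  period grid, so no sub-step phase accumulation is attempted; sweeps
  report the realized frequency `1/(rounded period)`);
- **biphasic**: `+S0` at each period start, `−S0` exactly two steps later
  (2 ms at the default step) — net zero mean over whole periods;
- **sinusoid**: `S0·sin(2π f_s t)`;
- **ou_noise**: stationary Ornstein–Uhlenbeck process, mean 0, variance
  `D_s·f_c`, correlation time `τ = 1/f_c`, integrated by exact
  discretization (decay factor `e^{−dt/τ}` with the matching increment
  variance), so the stationary variance carries no step-size bias; a
  plain-Euler variant is kept as a cross-check.

Infeasible requests fail loudly: pulse periods shorter than `dt`, biphasic
periods too short to host both phases, OU steps `dt ≥ τ`.

## Metrics

**Spike coherence.** Spike trains are reduced to 20 ms indicator bins
(`1` if the cell fired in the bin); for a pair of cells

    C = Σ X_i X_j / √(Σ X_i² · Σ X_j²)

so identical binned trains give exactly 1 and bin-disjoint trains exactly
0 — the square-rooted (normalized cross-correlation) denominator is what
makes both calibration points hold. Note that for *dense* independent
trains `E[C]` is approximately the per-bin firing probability, not 0; the
package reports raw `C` without baseline subtraction, so coherence values
should be compared across conditions, not read as absolute synchrony.
Network coherence averages over randomly sampled excitatory pairs
(default 100, seeded); pairs in which either train is empty carry no
normalizable signal and are resampled.

**Firing rate.** Spikes per cell per second (Hz) over a window.

**Single-cell spectra.** For a decoupled cell driven by white noise of
flat spectral level `D` plus a stimulus, the power spectral density on the
grid `ω_n = 2πn/T` is the Lorentzian envelope `a²/(a² + ω²)` multiplying
`D` plus a family-specific term: flat `D_s` for white-limit noise, an
equidistant comb for pulse trains, an `n²`-weighted comb for biphasic
pairs (the `n²` growth is a known property of the idealized zero-width
pulse pair), and a single line at `f_s` for the sinusoid. Periodic
families require `f_s·T` to be an integer so lines land on grid points
(no leakage in analytic/empirical comparisons). The half-power frequency
of the noise-only envelope equals the rate constant `a` — hence
inhibitory cells (`a_i = 2 a_e`) pass a twice-wider band and show higher
power at every frequency, the single-cell explanation for their
preferential recruitment by stimulation. Empirical spectra are averaged
periodograms normalized as one-sided density per Hz (Parseval:
`Σ power · df = variance`); for the same process this is twice the
closed-form grid convention (`EMPIRICAL_TO_ANALYTIC = 2`). The
illustration parameters of the spectral comparison (`S0² = 0.5`,
`D = 200`, `D_s = 50`, `τ = 0.01` s, `f_s = 50` Hz, `T = 2` s) are on a
different scale from the network's noise levels and are used only there.

## Experiments and problem sizes

The drive-step ("transition") protocol runs 2 s at the reference 800+200
size: `I_o` steps from 0 to 0.1 at 1 s, any stimulus is applied
continuously before and after the step, a 500 ms burn-in is discarded,
and metrics use the final 800 ms of each epoch. These desk-scale defaults
keep a full amplitude×frequency heatmap in minutes on one CPU; a
ten-times-larger "paper" profile (8 000+2 000 cells, 10 replicates) is
available through the CLI. The stimulation period grid spans 1–200 Hz
non-uniformly (periods 1000, 500, 300:−25:100, 90:−10:50, 45:−5:30,
28:−2:20, 19:−1:5 ms). Oscillation presence is scored by post-step
coherence alone — simulations show synchronous spiking and oscillatory
population activity co-occur here — with no additional spectral peak
detection layered on top. Replicate seeds derive from
`sha256(base seed, grid indices)`, making sweeps reproducible and
order-independent; every run can emit a JSON manifest (full
parameters + config hash + package version) that reproduces its raster
bitwise.

At the 800+200 scale, finite-size fluctuations act as an extra noise
floor: the post-step coherence ordering across intrinsic noise levels
(0.506, 0.377, 0.352, 0.281 for `D` = 0.005, 0.01, 0.025, 0.05;
five-seed means) is robustly monotone, but the raw excitatory *rate
jump* is not monotone at the lowest `D`, because the pre-step baseline
rate itself grows steeply with noise (0.2 → 9.4 Hz from `D` = 0.005 to
0.01) and confounds the difference. Tests therefore assert the coherence
ordering — the operational definition of "less oscillatory" — plus rate
comparisons away from that confound.

## What the simulations do and do not show

All data are generated internally by the simulator; there is no recorded
data anywhere in the pipeline. The generated activity reproduces the
mechanistic claims — multistability and its noise-dependence, abrupt
synchronization at the drive step, differential E/I recruitment by
stimulation — under the model's idealizations: homogeneous all-to-all
coupling, no synaptic or conduction delays, no plasticity or adaptation,
no refractoriness, threshold-linear single-cell dynamics, and stationary
statistics within each epoch. Passing tests therefore validate the
mathematics and the implementation, not any claim about in vivo seizures;
real tissue adds heterogeneity, delays, and nonstationarity that this
model deliberately omits for tractability.

## Known limitations

- The drive grid of a bifurcation sweep must be fine enough to catch a
  narrow multistable interval in the first place (endpoint *refinement*
  is then bisective); the sweeps here use steps ≤ 10⁻³ against interval
  widths ≥ 10⁻².
- Coherence depends on the 20 ms bin: much finer bins drive all values
  toward 0, much coarser toward 1. All comparisons use the same bin.
- The biphasic analytic spectrum grows as `n²` along its comb by
  construction; it should not be integrated to a total power.
- Heatmap cells whose stimulation period is unrepresentable at the
  integration step are reported as missing (NaN), never silently
  dropped.
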