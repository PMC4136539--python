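# Methods

## Model

`groomsim` simulates action selection among *N* competing body-cleaning
modules as three layers. The **sensory layer** is a dust vector
`d ∈ [0, 1]^N`, initialized once to `dust_base + r` with
`r ~ U[0, dust_noise]` drawn independently per module (modules 1..N in
order from a single seeded stream); no further noise is injected during a
run, so the initial draw is the only stochastic element. The
**hierarchical layer** converts dust to activations `a`:

| mode | update | hierarchy source |
|------|--------|------------------|
| `flat` | `a = d` | none (control) |
| `sgm`  | `a = d ∘ wˢ` | strictly decreasing sensory gains `wˢ` |
| `uim`  | `a = d · W` | `W` unit diagonal, strict upper triangle = `w ≤ 0` |

The **winner-take-all layer** picks `ma = argmax(a)` and executes only
that module: `d_ma ← max(0, d_ma − dr)`. The winner-take-all circuit is
not simulated explicitly; selection is literally the maximum, with ties
broken toward the lowest (hierarchically superior) index. That tie-break
makes the noise-free flat model a deterministic round-robin starting at
module 1, and makes module 1 the perpetual "winner" after all dust is
exhausted — runs intended to measure steady-state statistics must
therefore end before exhaustion (see Study sizes) or discard the tail.

Under UIM, activations of strongly suppressed modules can be negative;
no floor is applied because the argmax is unaffected and negativity only
deepens suppression. Dust itself is always floored at zero and is
nonincreasing for unclamped modules.

### The UIM update: dust-driven vs literal recurrence

Two variants of the inhibition update are provided via
`uim_recurrence`. The default, `stateless`, recomputes `a = d · W` from
the *current* dust every iteration, so cleaning feeds back into the
competition — this reproduces the intended behavior in which a module
"deletes itself" by removing its own sensory drive. The `literal`
variant iterates `a ← a · W` seeded with the initial dust and never
re-reads dust. Because `W` is non-normal with spectral structure that
amplifies alternating-sign components, repeated application diverges:
subordinate modules' activations oscillate with growing magnitude and
eventually dominate regardless of dust, even against a clamped module.
It is retained for comparison only and excluded from the behavioral
guarantees; a unit test characterizes the divergence.

### Constitutive activation

Clamped modules have their dust reset to `clamp_value` after every
iteration (default: `dust_base + dust_noise`, i.e. the maximum of the
initial-dust distribution; scenarios with zero baseline dust set it to
1.0 explicitly). One consequence worth stating: with a mid-hierarchy
module clamped under UIM and full-body dust, the superior modules do
*not* clean to zero. Writing `s` for the summed dust of the modules
above clamp position *m* and `c` for the clamp value, the clamped
activation is `c − |w|·s` while the best superior activation is at most
`s`; once `s` falls below `c/(1+|w|)·…` (≈ 2c/3 at `w = −0.5`) the
clamped module becomes and stays the argmax, and because its dust never
changes the whole state freezes with residual dust on the superiors
(≈ 0.44 and 0.67 for modules 1 and 2 at default parameters). Inferior
modules are never selected at all. This frozen-competition outcome is a
genuine property of the model, verified against the independent
single-step oracle.

### Leg rubbing

With `legs_enabled`, two leg pairs carry dust `dl` (front, hind). Each
body-module win adds `leg_increment` to the pair that performs it
(front for module index ≤ `anterior_boundary`, default 3; hind
otherwise). Leg activation is `al = leg_gain · dl`. A pair wins the
iteration only if (1) `al ≥ leg_threshold`, (2) `al` exceeds every body
module's activation, and (3) `al` exceeds the other pair — so leg
rubbing competes inside the same hierarchy, re-evaluated every
iteration. A leg win removes `leg_dust_removal` from that pair, floored
at zero.

The canonical `leg_rubbing` scenario uses UIM with `w = −1.0`,
`dr = 0.02`, `leg_gain = 4`, threshold 0.8, and increment/removal 0.05.
The architecture choice is deliberate: under SGM, cleaning lowers only
the cleaner's own activation, so after a leg rub the argmax usually
belongs to a *different* body module and the
body<sub>k</sub> → leg → body<sub>k</sub> cycle rarely closes. Under
UIM, cleaning a superior module *releases* suppression of its juniors,
producing runs of repeated same-module selections; the stronger
inhibition and smaller `dr` lengthen those runs (≥ 11 consecutive-repeat
events per module without legs), which makes ≥ 3 same-body alternations
per module robust across seeds. The high leg gain reflects the modeling
premise that legs must out-compete body modules once sufficiently
dirty; at gain 1 a leg pair could never exceed a body activation that
reaches twice its dust.

### Free parameters and defaults

| parameter | default | unit | rationale |
|-----------|---------|------|-----------|
| `dust_base`, `dust_noise` | 0.9, 0.1 | dust fraction | canonical initial condition 0.9 + U[0, 0.1] |
| `dust_removal` (`dr`) | 0.05 | dust/iteration | ≈ 19–20 cleaning iterations per body part, giving ethogram lengths comparable to the canonical runs |
| `sensory_weights` (sgm) | linspace(2.0, 1.0, N) | — | weight gaps (0.25·dust ≈ 0.225 for N = 5) dominate the 0.1 dust noise, so the hierarchy order is deterministic across seeds |
| `inhibition_weight` (uim) | −0.5 | — | canonical value |
| `clamp_value` | dust_base + dust_noise | dust | "fully dirty after each cleaning round" |
| `leg_gain` | 1.0 | — | neutral proportionality `al = dl`; scenarios override |
| `leg_threshold` | 0.8 | activation | stationary threshold shared by both pairs |
| `leg_increment`, `leg_dust_removal` | 0.05 | dust/iteration | one rub cancels one body clean's transfer |
| `anterior_boundary` | 3 | module index | front legs serve modules 1–3, hind legs the rest |

Iterations are abstract timesteps; there is no convergence criterion.
`SimulationResult.time_to_clean()` reports the first iteration at which
all unclamped dust is zero.

## Behavioral statistics

A **bout** is a maximal run of one label; bouts reconstruct the ethogram
exactly. Bout frequency counts bout *starts*; the interval variant
assigns each bout to the bin containing its start timestep only.
Marginal probabilities are per-label bout counts over total bouts,
computed in rational arithmetic (their exact sum is 1); the cohort
variant averages per-subject fractions. Transition matrices count
bout-to-bout label changes (self-transitions impossible by maximality;
a raw-timestep mode including self-transitions is available behind
`unit="timestep"`). Populated probability rows sum to 1 within 1e-12;
a terminal label's row stays all-zero and is flagged rather than
renormalized. The graph-export display threshold (e.g. 0.05) masks edges
in the edge-list file only and never alters the matrix.

## Half-clearance (t50) fitting

`fit_t50` fits either `f0·exp(−kt)` (then `t50 = ln 2 / k`) or the
4-parameter logistic `floor + (ceiling − floor)/(1 + (t/mid)^slope)`
by unweighted least squares (`scipy.optimize.curve_fit`). t50 is defined
on the *fitted* curve as the time it crosses half the curve's own value
at t = 0 (for the logistic this is `ceiling/2`, solved in closed form;
with a zero floor, t50 equals the midpoint). If the optimizer fails or
the fitted curve never reaches half its initial value, a flagged
model-free fallback interpolates the raw data linearly at half the first
sample. Rising time courses are accepted with a warning.

## Dust maps

Images must be pre-registered: dimensions are compared exactly and
nothing is resampled. The in-memory convention is binary 0/1 (row-major,
origin top-left, 0-based); 8-bit 0/255 applies only when writing
rasters, and groomograms are additionally written as lossless CSV since
the 8-bit raster quantizes fractions. The groomogram is the per-pixel
mean of the binary stack — exactly the fraction of subjects dusted at
that coordinate. Region fractions are dust pixels over mask pixels.
Zero-time normalization divides each sample by the mean of its body
part's t = 0 samples (t = 0 group mean is exactly 1 by construction);
max-mean normalization divides by the maximum over time of the body
part's mean. The dust-positive color criterion of `binarize` is
caller-defined (channel + strict cutoff), and the operation is
idempotent on binary input. Map rendering is presentation-only and not
tested numerically.

## Synthetic data

The generators stand in for grooming videos and body-part photographs,
which cannot be redistributed. They emulate: first-order bout-and-
transition structure (Markov chains with zero-diagonal row-stochastic
matrices and geometric — memoryless — bout lengths, the minimal
assumption consistent with first-order analysis); independent per-pixel
dust (Bernoulli images whose groomogram expectation is the supplied
probability map); and smooth decay with additive Gaussian noise clipped
to [0, 1]. They do **not** emulate leg kinematics, video frames,
registration error, spatially correlated dust, scorer disagreement, or
heavy-tailed bout durations — so passing tests demonstrate correctness
of the estimators and simulator, not robustness to those features of
real data. All generators are seed-deterministic and return their
ground truth alongside the data.

## Numerical choices

- Dust-ledger equality (initial − final = dr × unclamped wins, with
  floor-at-zero correction) is asserted to 1e-9 absolute: sequential
  float subtraction cannot reproduce `dr × wins` bit-for-bit.
- The independent single-step oracle (straight-line plain-Python
  re-implementation of one iteration) is compared at 1e-12 absolute,
  allowing for summation-order differences against the vectorized path.
- Transition-row stochasticity is checked at 1e-12; row sums of
  generator inputs at 1e-9.
- `argmax` ties resolve to the first maximum (lowest module index).

## Study sizes

The verification suite and `scripts/acceptance.py` use these problem
sizes, chosen to make the measured quantities statistically stable:

- Flat-model symmetry: 20 seeds × 10,000 iterations with `dr = 4e-4`,
  sized so total dust (5 × ~0.95 / 4e-4 ≈ 11,900 removals) outlasts the
  horizon and the initial-noise equalization (~`dust_noise`/`dr` = 250
  iterations) is a small burn-in; window dominance uses 500-iteration
  windows after a 1,000-iteration burn-in. Shares come out at
  0.2 ± ~0.002.
- Hierarchy ordering and return cleaning: 100 seeds per architecture at
  400 iterations (all dust is removed by ≈ iteration 100).
- Ledger and oracle replay: 200 and 100 random configurations (1–6
  modules, random modes, clamps, leg settings, 10–80 iterations).
- Transition recovery: a random 4-label chain, max-absolute error at
  10,000 bouts plus medians over 50 seeds at 100/1,000/10,000 bouts.
- t50 recovery: 200 seeds, 8 timepoints uniform over four half-lives
  [0, 4·t50] — the standard design for decay-rate estimation — with
  absolute noise sd 0.05; median relative error ≈ 4.5%.

## Limitations

- The winner-take-all stage is a maximum function, not a dynamical
  inhibitory network; no continuous-time or spiking dynamics.
- Model parameters are not fitted to fly data; the package makes no
  claim about parameter values in real flies.
- The literal UIM recurrence diverges (see above) and is excluded from
  behavioral guarantees.
- Under constitutive activation with full-body dust, superior modules
  retain residual dust (frozen competition); tests assert the realized
  behavior, not full cleaning.
- Dust-map operations assume perfect registration and binary input; no
  color calibration or warping is provided.
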