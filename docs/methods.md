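# Methods

## Model and assumptions

The floral meristem's L1 layer is reduced to a fixed 1D transect of
`n_cells = 15` idealized cells of 4.4 μm (66 μm diameter).  Each cell
carries six continuous state variables: the protein levels of LFY, AP1,
AG, TFL1 and WUS, and a diffusible repressor signal *y*.  Assumptions
inherited from the modeling framework:

* no growth, division or geometry change during the 16.6 h simulated
  window; the lattice is static;
* exchange between cells happens only through LFY (coupling coefficient
  ε = D/Δx², default 5 s⁻¹) and *y* (coupling D_y), both with no-flux
  ends implemented as mirrored ghost cells, so pure coupling conserves
  total material exactly;
* AP1 and AG do not move between cells; their mutual exclusion is purely
  kinetic, expressed through the derived effective AP1 level
  `ap1_T = ap1·[1 − ag/(ag + β1)]`.  The `ap1` state variable itself
  evolves independently of AG;
* AG production is licensed by WUS and LFY, noncompetitively inhibited by
  AP1 through a `(β2 + β3·ap1)` denominator, and held at zero by an
  imposed unit step gate until 5 h — upstream flowering-time regulation is
  not modeled, only its timing consequence;
* the boundary signal `L` is imposed, not mechanistic: 1 in the three
  outermost cells at each end ("wide", the reference condition) or only
  in the two end cells ("narrow").

Initial conditions are spatially homogeneous for the regulators
(lfy = 1, ap1 = 0, ag = 0, tfl1 = 0.1, wus = 1 μM) with *y* starting on
the boundary profile.  All pattern is therefore generated, not assumed:
the only symmetry-breaking input is the boundary signal.

## The WUS repressor subsystem: three conventions

The subsystem that builds the WUS pre-pattern is adapted from a
connectionist repressor model and required three explicit conventions
where the source formulation is ambiguous; each is configurable on
`WusParams` and the defaults are motivated thus:

* **Sigmoid** (`sigmoid_variant="mjolsness"`, default):
  `g(u) = ½(1 + u/√(1+u²))` with `u = h_w + T_wy·y`.  With h_w = 2 and
  T_wy = −30 this gives the required on/off contrast (g ≈ 0.95 derepressed,
  g ≈ 3·10⁻⁴ repressed).  The two literal readings of the printed bracket,
  `(1+u)/(1+u²)` and `1 + u/(1+u²)`, are retained as options but produce
  weak or negative "activation" and cannot yield the on/off contrast.
* **Clock** (`time_scale=3600` s, default): the subsystem's rates
  (d_w = 1.75, d_y = 2, D_y = 0.1, k_y = 0.2) are interpreted per hour.
  Read per second, WUS would relax in ~0.6 s; per hour, the pre-pattern
  emerges over ~1 h, consistent with the phenomenology being modeled and
  with the source model's time scale.
* **Amplitude** (`amplitude_mode="normalized"`, default): the production
  constant is taken equal to d_w so the derepressed steady WUS level is
  ≈ g(h_w) ≈ 0.95 μM, commensurate with the O(1) initial condition and
  strong enough to flip the AG switch.  With the literal k17 = 0.05 the
  steady level is ≈ 0.027 μM, too small to matter given k9 ≤ 0.5.

Because the *y* equation is linear, its steady state has a closed form
(`(d_y·I − D_y·Lap) y = k_y·L`) and WUS follows pointwise; this direct
solve (`wus_steady_profile`) is used as an independent oracle against the
time-stepped subsystem (agreement required to 1e−6 μM).

## Ambiguity flags for the AG rate law

The AG equation admits several typographic readings; `ModelOptions` makes
each explicit.  Defaults: the step gate multiplies *all* production
(without it AG appears within a few integration steps, defeating the
gate's stated purpose) and the AP1-inhibition denominator divides the
*combined* WUS+LFY activation (noncompetitive inhibition of total
production).  AP1 feeds back on the other genes as the raw state variable;
the `effective` option substitutes `ap1_T`.  The raw default makes the
ε-invariance of the pattern exact: lfy, ap1 and tfl1 then stay spatially
uniform forever (their equations see only uniform inputs), the LFY
Laplacian is identically zero, and any ε — constant, time-varying or
per-cell — produces bit-identical patterns up to roundoff.  That exactness
is the mechanistic content of the claim that LFY diffusion is unnecessary,
and it is asserted at 1e−10 in the tests.

## Numerics

* **Scheme**: "Euler predictor–corrector" is implemented as Heun's method
  — forward-Euler predictor, trapezoidal corrector — the standard meaning
  of the phrase; plain forward Euler is available via `method="euler"`.
* **Step**: dt = 0.05 s for 1,200,000 steps (16.6 h).  The stiffest rate
  (k16 = 0.55 s⁻¹) gives λ·dt ≈ 0.03, far inside the stability region.
  Halving dt changes the final state by < 3·10⁻¹² μM.
* **Clipping**: every field is clipped at zero after the corrector (never
  mid-stage, so the predictor sees the raw dynamics).  Linear inhibition
  terms can push rates negative; concentrations are physical.  One visible
  consequence: at the t = 5 h sample AG is still exactly zero, because the
  corrector averages the pre-gate (negative) and post-gate rates and TFL1
  repression outweighs the fresh production for that single step; AG is
  positive from the next sample (5.03 h) on.
* **Sampling**: every 2,000 steps (100 s) by default, plus the exact final
  state.  Steady state is declared when every field's maximal per-cell
  change, relative to its overall scale, stays below 10⁻³ per simulated
  hour through the end of the run.
* **Ties**: profile peaks break toward the lowest index.  The step gate is
  right-continuous (equals 1 at exactly t = gate_time).
* **Instability**: non-finite values abort the run with the failing step
  index (relevant only for deliberately oversized steps).

The 1.2M-step loop is numba-compiled; a pure-numpy right-hand side
composed from the public per-field rate functions is kept as a reference
implementation and the test suite requires step-by-step agreement between
the two to 1e−12 relative.

## Fixed-point oracle

Before the gate opens (ag = 0) and with uniform fields, the LFY/AP1/TFL1
subsystem is linear; `uniform_fixed_point` solves the 3×3 balance system
directly, pinning any negative component at zero and re-solving (the
clipped dynamics cannot sustain negative concentrations).  With the
default rates the solution is (lfy*, ap1*, tfl1*) =
(1.5391, 2.8359, 1.2578) μM, and long simulations with the WUS subsystem
frozen must converge to it within 1e−6 μM.

A consequence of the same balance worth knowing: TFL1 relaxes on a ~2 s
time scale toward a quasi-steady level of ≈ 1.45 μM while LFY responds
~20× more slowly, so TFL1 transiently *exceeds* LFY during the first few
minutes of the run.  From ~10 minutes on, and at every displayed stage of
the patterning process, LFY dominates (1.54 vs 1.26 μM at steady state).
The wild-type experiment reports the transient overshoot as a metric
rather than asserting dominance through it.

## Zone classification

No numeric zone definition exists in the source phenomenology, so the
package uses half-max thresholding for scale invariance: C where
`ag ≥ ½·max(ag)`, A where not C and `ap1_T ≥ ½·max(ap1_T)`, B residual
("between" the two).  The threshold fraction is configurable.  Because the
repressor length scale √(D_y/d_y) ≈ 0.22 cells makes the WUS (and hence
AG) transition essentially one cell wide, the exclusive B label is empty
in the default run: the steady pattern is A(1–3) C(4–12) A(13–15), three
contiguous zones.  The B zone as an overlap of A and C territory is
available through `zone_membership` (non-exclusive booleans at a chosen
fraction).  Zone orderings are compared as run-length sequences with B
optional between A and C.

## Robustness scan and the k5 interval

`run_robustness_scan` re-runs the full model varying one rate constant at
a time, either redrawn uniformly within ±10% of its default (seeded) or at
both endpoints of the published robustness interval for each of k1…k16.  A
perturbed run counts as stable when its zone-label sequence and AG peak
cell match the unperturbed run.  The published k5 interval [0.9, 1.5]
excludes the published k5 value (0.09 μM/s) by a factor of ten and, taken
literally, collapses the pattern to all-C (AP1 production so strong that
TFL1 pins at zero and AG turns on everywhere).  The scan therefore
defaults to the decimal-consistent reading [0.09, 0.15] — the printed
endpoints divided by ten, containing the headline value with the same
relative width — under which all 32 endpoint runs are stable;
`k5_interval="literal"` evaluates the printed interval as-is and reports
it unstable.

## Synthetic conditions vs real meristems

The experiments simulate the printed study conditions exactly; they are
in-silico reproductions, not fits to expression data.  What passing tests
show: the five-gene kinetic mechanism, given a boundary-driven WUS
pre-pattern, robustly converts a homogeneous state into a centered,
mirror-symmetric three-zone pattern that is independent of LFY coupling
and of which of AG/WUS drives AP1 exclusion.  What they do not show:
anything about real gene-expression noise, growth, 3D geometry, the
molecular identity of the L/y signals, or floral organ identity proper
(which needs the full organ-specification network; no organ mutant
simulations are attempted here).  One published qualitative claim is not
reproducible in principle: the narrow-boundary pattern is reported as
asymmetric about cell 8, but the narrow configuration, equations and
initial state are all mirror-symmetric, so exact arithmetic preserves
symmetry (verified to 1e−10); the package reproduces the broadening
(13 vs 9 cells at AG half-max) and flags the asymmetry claim in the
experiment report instead of asserting it.

## Problem sizes

All simulations in the tests and the acceptance script use the full study
conditions — 15 cells × 6 fields × 1,200,000 steps — except short
structural tests of report plumbing (100 s runs with a proportionally
shortened gate and WUS clock).  The dt-halving check runs 2,400,000 steps
at dt = 0.025 s.  The complete suite performs ~45 full-length runs.
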