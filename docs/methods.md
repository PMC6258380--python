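# Methods

## Model

The network is `N` identical, all-to-all coupled populations.  Population
`j` carries three synaptic activities: fast excitatory `u_j` (AMPA,
timescale 1, the unit of time, read as 1 ms), inhibitory `v_j` (GABA,
timescale `τ_i`), and slow excitatory `n_j` (NMDA, timescale `τ_n`):

```
u_j' = −u_j + f(a_ee·ũ_j − a_ei·ṽ_j + a_en·ñ_j − θ_e + s_j(t))
τ_i v_j' = −v_j + f(a_ie·u_j − a_ii·v_j + a_in·n_j − θ_i)
τ_n n_j' = −n_j + a_n·u_j^p·(1 − n_j)
```

Interpopulation coupling acts only through the excitatory rate's argument,
via the normalised mixing `α̃_j = (α_j + c_z Σ_{k≠j} α_k)/(1 + c_z(N−1))`
with `c_z = c_e` for `u` and `n` and `c_z = c_ei` for `v`; the denominator
keeps the mixed field inside the convex hull of the inputs, so a uniform
(fully synchronous) network behaves exactly like a single population for
any coupling strength.  An optional E→I interpopulation coupling `c_ie`
(default 0) is implemented symmetrically in the inhibitory equation.

The firing rate is `f(x) = sqrt(x / (1 − e^(−βx)))`, a smooth
approximation of the f–I curve of a quadratic integrate-and-fire neuron
driven by noise: `≈ sqrt(x)` for strongly suprathreshold input,
exponentially small for strongly subthreshold input, and `sqrt(1/β)` at
threshold.  The sublinear gain at high drive is essential: with the strong
recurrent excitation `a_ee = 14` used here, an asymptotically linear rate
would make the excitatory upstroke outrun the slow inhibition
(`τ_i ≫ 1/(a_ee − 1)`) and every suprathreshold trajectory would diverge.
With the square-root rate, the spike self-limits, the inhibitory surge
terminates it, and the default parameter set produces exactly the published
operating point (period ≈ 50 ms with active/quiescent phases ≈ 22/28 ms,
inhibitory maxima ≈ 6.3, NMDA peaking at ≈ 0.99).

Default parameters (`preset("paper-default")`): `N = 5`, `τ_i = 12`,
`τ_n = 144`, `c_e = 0.001`, `c_ei = 0.03`, `c_ie = 0`, `a_ee = 14`,
`a_ei = 10`, `a_en = 4`, `θ_e = 6`, `a_ie = 20`, `a_ii = 8`, `a_in = 0.1`,
`θ_i = 5`, `a_n = 2`, `β = 1`, `p = 2`.  `τ_n > τ_i > 1` is the intended
regime (a warning, not an error, outside it).  The NMDA saturation at 1 and
`u > 0`, `v > 0` are dynamical invariants, checked on every trajectory.

## Numerics

The default integrator is an adaptive Dormand–Prince 5(4) kernel compiled
with numba (relative tolerance 1e−8, absolute 1e−10), with cubic-Hermite
dense output onto a fixed 0.1 ms grid.  The timescale span (1 to `τ_n`) is
mild enough for an explicit method at these tolerances, and the compiled
kernel makes the scan-heavy analyses (thousands of simulations) practical
on one CPU.  `solver="lsoda"` routes the identical problem through SciPy's
LSODA as an independent cross-check; the two paths agree to <1e−4 in state
and <0.1% in measured periods, and halving the tolerances moves periods by
<0.1%.  Integration restarts at every pulse edge so the square stimulus is
represented exactly, never smoothed.  NMDA values are clamped to [0, 1]
post-step; an excursion beyond 1e−6 raises an accuracy error (in practice
excursions are ≈ rounding level).

The baseline state is the uniform low fixed point, found by root-finding
from small positive seeds (residual < 1e−13); its `u` component `u*`
doubles as the active/quiescent threshold for duty-cycle measurements.

## Classification

Trajectories are summarised per population after discarding 500 ms past the
last stimulus: peak times (local maxima, quadratic sub-grid refinement),
period `T` (mean peak-to-peak interval; stationary if the dispersion
std/mean < 2%), active time `T_a` (time with `u > u*`, crossing-interpolated,
averaged over complete cycles) and `T_q = T − T_a`.  A population is
*active* when its mean peak height exceeds `u* + Δ` with `Δ = 1` (active
oscillations here have amplitudes ≈ 9 against a baseline ≈ 0.09, so the
threshold is uncritical over two orders of magnitude; it is a config knob).
Oscillation ranges above 0.25 but below the active threshold are flagged
`low_amplitude` — the small oscillation around the low state that coexists
with the others at the defaults — while the ≈0.05 ripple a quiescent
population receives through the coupled inhibition stays `quiescent`.

Active populations are grouped as synchronous when the median circular
peak-time offset is within the synchrony tolerance `η = 5 ms` (inside the
6–10 ms windows over which cortical neurons have been observed to
phase-lock, and below the 6 ms robustness grain so that grouping at
capacity, where separations are ≈ T/3 ≳ 16 ms, is unambiguous).  Grouping
is the transitive closure; if any between-group offset then fails to exceed
`η` (ties included) the pattern is reported `unresolved` rather than forced.
The median over cycles is used instead of the mean so one deformed cycle
cannot flip a label.  Frequencies are peak-interval based: population
frequency `1000/T` Hz, interpopulation frequency that times the number of
out-of-phase groups.

## Protocols, scans, thresholds

Stimulation outcomes are phase dependent, so operations are characterised
by scanning the pulse onset at 1 ms steps across one network period and
keeping outcomes stable over onset windows of at least 6 ms (windows
wrapping the period boundary are merged).  Five pulse classes, pinned once
by calibration scans at the defaults, cover the operation repertoire:
`weak` (1, 10 ms) never changes the pattern, `ignite` (2, 20 ms) activates
without quenching, `stagger` (3.5, 30 ms) interleaves a new item
out-of-phase, `bind` (12, 40 ms) re-times an active population onto a
partner (its windows are intrinsically narrow, 6–7 ms), `wts` (30, 50 ms)
quenches some active populations, and `wta` (30, 200 ms — same amplitude,
four times the width) leaves the stimulated population as the only active
one.

The scenario library pins one script per canonical regime, with the settled
label and measured robust window recorded next to each script.  Three
operations are genuinely phase-sensitive and sit on sub-6 ms windows:
sequential binding onto a running oscillation (≈4 ms), quench-exactly-one
at capacity (≈1–2 ms), and single-pair mixed-phase formation.  They are
kept as demonstrations with their windows documented; the operation atlas
itself only admits ≥6 ms outcomes.

Switching thresholds in the two-population circuit are bisected to 1%
relative tolerance on the amplitude of a 50 ms pulse, with "switched"
meaning the target is persistently active (mean late `u` above `u* + Δ`,
covering both oscillatory and steady up-state activity) and the source has
returned to baseline.  With no interpopulation inhibition the source can
never be quenched and the threshold is reported as infinite.

## Stability regions and capacity

Stability is operationalised as persistence under perturbation in direct
simulation rather than Floquet analysis: a state is built by its loading
protocol (M pulses staggered by the single-population period over M for
out-of-phase states; simultaneous pulses for synchronous ones), settled
4000 ms, perturbed by ±1e−3 per variable with a fixed sign pattern, and
integrated 2000 ms more; it persists when the canonical partition is
unchanged.  Because the loss of a synchronous state is transverse to the
synchronous manifold and can be arbitrarily slow near a boundary, the label
check alone would overshoot; synchronous persistence therefore additionally
requires a non-growing desynchronisation envelope, measured as the
exponential rate of the across-population spread of `u` sampled
stroboscopically at the group-mean peaks (fit over the late two-thirds of
the window so fast-decaying transverse modes die out first).  The sign of
this rate flips at the true boundary even when the rate is tiny, which is
what makes the interval endpoints reproducible to a few percent.

Boundaries in a parameter are located by solution-following continuation
(each step seeds from the previous converged state, so hysteresis near
folds is per-direction and the seeding direction is recorded) with
bisection to 0.05 in timescale units and 0.002 in coupling units; each
reported bound has a verified persisting probe on one side and a verified
non-persisting probe on the other.  Capacity probes M-out-of-phase states
upward from M = 1 and reports the last persisting M, together with the
ceiling `floor(T/η)`.

## Weak-coupling reduction

The single-population limit cycle is obtained by settling 3 s, then
refining the period with a Poincaré section (upward mid-level crossing of
`u`, bisected to 1e−10 ms); the orbit is resampled at 2048 points with
phase 0 at the `u` peak, and closes to <1e−6.  The adjoint solves
`Z' = −J(t)ᵀZ` backward (backward time makes the periodic adjoint
attracting) over 12 periods with the orbit interpolated at 16384 points;
`Z·X' = 1` is then enforced at every sample — the identity is conserved by
the exact flow, so this only removes slow numerical drift.  The adjoint is
validated against direct simulation: a 1e−4 impulse on `u` at phase φ
shifts the asymptotic phase by `1e−4·Z_u(φ)` to within 5% (typically <1%),
with the shift measured from mid-level crossing times, whose interpolation
bias is common to both trajectories and cancels.

Interaction functions average the first-order coupling perturbation against
the adjoint over one period; the mixing denominator is expanded to first
order in `c_z`, so the perturbation per partner is `c_z(α_k − α_j)` through
the rate nonlinearity.  Pathways: EE (`c_e`; partner `u` and `n` into the
excitatory rate), EI (`c_ei`; partner `v` into the excitatory rate), IE
(`c_ie`; partner `u` into the inhibitory rate, zero by default).  The total
`H` drives the phase-difference flow `ψ_j' = Σ_k H(θ_k−θ_j) − Σ_k H(θ_k)`;
its odd part predicts the drift of the full model's peak-time difference at
`c_ei = 1e−4` to within 10%.  Fixed points are found by dense seeding and
root polishing, classified by the numerically linearised flow; N = 3 basins
are rasterised at 101×101 on the (ψ₂, ψ₃) torus by Heun integration of the
magnitude-normalised flow.  At the defaults' coupling ratio the stable set
is the synchronous configuration, both splay orderings, and three
mixed-phase configurations, all with open basins; adding excitatory
coupling at a tenth of the inhibitory strength enlarges the synchronous
basin several-fold.

## Operation atlas

The atlas enumerates first-order operations among diads and triads of the
5-population network: for each of 11 representative (start pattern,
stimulated-role) pairs — covering each synchrony role and one inactive
population — all five pulse classes are onset-scanned at 1 ms; robust
(≥6 ms) outcomes that are again diads or triads become directed edges, and
the edge set is closed under joint relabeling of populations (uniform
connectivity makes this exact).  Outcomes where the stimulated population
ends inactive would contradict the excitatory nature of the stimulus and
are discarded as classification failures (none occur).  Operation order is
shortest-path length; the reported diameter is taken over the canonical
diad/triad patterns on populations 1–3, which cover every pattern class up
to relabeling (over all 70 labelled patterns of the 5-population network
the maximum rises to 4, because transforming between patterns on disjoint
population subsets costs an extra loading step).

## Synthetic-data scope

The package generates all of its own inputs: the stimulus scripts and scans
are the study conditions, not recorded data.  What passing tests show is
internal: that this idealised, noise-free, homogeneous all-to-all network
with square pulses reproduces the stated operating points and properties.
Real cortical data would add heterogeneity, conduction delays, background
noise and non-identical populations, none of which is modelled; the
synchrony tolerance η is the only concession to finite biological timing
precision.

## Problem sizes

Defaults were chosen so every analysis is desk-scale: classification
windows span ≥10 cycles; persistence probes integrate 6 s of model time;
the synchronous-interval continuation uses ≈40 probes; the atlas build is
55 onset scans (≈3000 simulations); basins are 101² rasters.  The full test
suite runs in ≈2 minutes warm (plus one-time JIT compilation), and the
acceptance script in ≈1 minute.

## Known limitations

- The firing rate is a reconstruction: the source text for this model
  prints an asymptotically linear expression that is provably inconsistent
  with the printed coupling constants (no bounded active state exists under
  it); the square-root form adopted here is the standard smooth noisy-QIF
  rate and reproduces the published operating points with all other
  constants unchanged.  Two published numbers remain marginally outside
  their bands under it: the period at `τ_i = 20` measures 79.6 ms
  (published ≈76) and the interpopulation frequency at `N = 20` measures
  42.2 Hz (published 39); both are honest computations of the settled
  attractor and scale-tweaks of the rate move them in opposite directions.
- Bifurcation *types* are not diagnosed; only existence boundaries are
  located, with the successor state's label recorded.
- Winner-take-some from a two-item state quenches either victim robustly,
  but the single-victim quench at capacity is phase-sensitive (1–2 ms
  windows) in this implementation.
- No delays, heterogeneous coupling, stimulus drive to inhibition, or
  spiking-level validation; basins are not rasterised beyond N = 3.
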