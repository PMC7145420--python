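# Methods

## Scope and model structure

The package links four stages into one forward model of evoked transmitter
release at the larval *Drosophila* NMJ:

1. a planar distribution of vesicle:Ca²⁺-channel coupling distances,
2. a buffered reaction–diffusion Ca²⁺ microdomain,
3. per-site vesicle-release kinetics (four variants), and
4. postsynaptic current synthesis and analysis.

Everything downstream of the distance distribution is conditional on it:
each release site sees the Ca²⁺ transient of its own radial distance, and
amplitudes, paired-pulse ratios (PPR) and variance–mean relations emerge
from summing over sites.

## Distance distribution

Cross-section distances are Rayleigh(σ) with σ = 76.5154 nm (the
maximum-likelihood scale of the docked-vesicle EM measurements, closed form
σ̂ = √(Σx²/2n)). Rotating the cross-section around the active-zone centre
weights each distance by circumference, giving the planar density
g(x) = √(2/π)·σ⁻³·x²·e^(−x²/2σ²) with mean 2√(2/π)·σ ≈ 122.1 nm, SD
σ√(3−8/π) ≈ 51.5 nm, and cdf G(x) = γ(3/2, x²/2σ²)/Γ(3/2). Sampling invert
the cdf through `gammaincinv`. The deterministic engine replaces sampling by
180 equiprobable quantile bins (midpoint rule); 180 bins reproduce the
distribution mean to <0.5%.

The image pipeline (peak detection → centre-of-mass alignment → pixel
averaging → radial intensity histogram) mirrors the analysis of
super-resolution active-zone images. Alignment shifts by whole pixels;
sub-pixel registration is deliberately out of scope. When two maxima violate
the minimum-separation rule the brighter one is kept, ties resolved in
row-major order. Inter-AZ spacing enters through the mean 1–4 nearest-
neighbour distance; a spacing of 1.106 µm fixes the equal-area cylinder
radius 1.106/√π = 0.624 µm.

## Ca²⁺ field

Free Ca²⁺, a slow-moving endogenous buffer (4 mM total, K_D 100 µM) and ATP
(650 µM total, K_D 200 µM) obey diffusion–reaction equations in an
axisymmetric cylinder (radius 624 nm, height 1 µm, 71×101 nodes) with
zero-flux boundaries. Influx is a Gaussian current (FWHM 0.36 ms, truncated
at ±1.5 ms) whose integral is Q = Q_max·[Ca]ext/(K_M+[Ca]ext), K_M =
2.679 mM; the charge is converted to ions (Q/2e) and injected into the
membrane-centre boundary cell. Resting Ca²⁺ follows the same saturation with
a 190 nM ceiling. Uptake (0.4 ms⁻¹) relaxes free Ca²⁺ toward the resting
value rather than zero, so the pre-stimulus state is a true steady state —
with no influx the field stays at rest to machine precision.

Numerics: finite volumes in (r, z); per step, an implicit local
reaction/uptake/source update (the buffer equations are eliminated
analytically and the remaining scalar solved by vectorised Newton, which
conserves Ca + bound-Ca exactly up to source and uptake), followed by
backward-Euler tridiagonal diffusion sweeps in r and z. Both free and bound
buffer forms share one diffusivity, so total buffer stays uniform and only
the bound form is evolved. Time steps: 5 µs inside the pulse windows, 50 µs
nearby, 250 µs in the tail (all configurable). A negative concentration
beyond −10⁻⁹ µM aborts with the offending time. The solver reproduces the
free-diffusion Green's function within 5% (buffers/uptake off), closes its
mass balance to ~10⁻¹³ of the influx, and doubling the grid moves the
122 nm peak readout by <3%. The residual-Ca²⁺ decay constant after a paired
pulse is ~109 ms on the production grid, matching the linearised prediction
(1+κ)/k_up ≈ 110.6 ms with κ = Σ K_D·B_tot/(K_D+Ca)².

The readout plane sits 10 nm above the membrane (an exact grid plane at the
default resolution; otherwise linearly interpolated). Queries in distance
and time are bilinear.

## Release models

All variants share the five-site fast sensor (k₁ = 1.4·10⁸ M⁻¹s⁻¹, k₋₁ =
4000 s⁻¹, cooperativity factor b_f = 0.5), basal fusion rate L₊ =
3.5·10⁻⁴ s⁻¹, fusion factor f = (k_f/L₊)^(1/5) with k_f = 6000 s⁻¹, and
Ca²⁺-independent replenishment of empty sites. Variant-specific parts:

* **dual sensor** — a membrane-anchored slow sensor (m_max = 2 by default,
  K_D = 1.5 µM) multiplying the fusion rate by s per bound ion; empty sites
  keep binding/unbinding Ca²⁺ on the slow sensor and replenish into R(0,m).
  The bookkeeping of fused vesicles is flux-consistent: the fused mass of
  slow-sensor state m enters empty state P_m.
* **unpriming** — occupied, Ca²⁺-free sites unprime at u·r(Ca),
  r = K_M^n/(Ca^n + K_M^n) with K_M,prim in nM and n = 5 (2 as an
  alternative); steady-state occupancy is k_rep/(k_rep + r·u·π₀₀) with π₀₀
  the resting probability of the Ca²⁺-free state.
* **site activation** — per-site gates I → D (rate α·Ca^n, α = 10⁶ s⁻¹ with
  Ca in µM — the concentration basis is isolated in `ModelSpec` since it is
  a unit convention, n = 5) → A (γ), with back rates β (D→I) and δ (A→D);
  fusion requires gate A. The D state delays activation past the first
  action potential.

Steady states use the closed-form binomial product weights (the basal fusion
leak is ignored, as its flux is ~10⁻⁶ of replenishment); the formula agrees
with the long-run ODE limit to <10⁻⁶ relative when the leak is suppressed.

**Deterministic engine.** Per distance bin the state master equation is
linear given Ca(t): dy/dt = (M₀ + Ca·M₁ + r(Ca)·M₂ + Ca^n·M₃)y. Fusion
exits (whose rates reach L₊f⁵s² ≈ 10⁹ s⁻¹ in the dual-sensor model) are
split off and applied exactly as exponential transfers around a classical
RK4 step of the remaining dynamics; the RK4 step subdivides itself whenever
the near-source transient pushes binding rates toward the stability bound
(substeps chosen so rate·h ≤ 1.5). Gate-activation rates are additionally
capped at 0.5/dt — at that point the transition is already instantaneous
relative to the 1 µs output sampling. Default step 2 µs (5–10 µs in the
scaled-down test configurations).

**Stochastic engine.** Exact SSA over per-site states with one
modification: when the sampled waiting time exceeds µ = 1 µs the clock
advances by µ, no reaction fires, and propensities are refreshed from the
Ca²⁺ lookup table — statistically valid because exponential waiting times
are memoryless. When the field is constant in time the capped stepping is
distributionally identical to plain SSA, and the kernel skips the cap (used
by constant-Ca oracles). Per-site propensities are decomposed as
c_A + c_B·Ca + c_U·r(Ca) + c_G·Ca^n with coefficients recomputed only when
a site's state changes; the inner loop is numba-compiled (~40 ms per
repetition for 216 sites over 22 ms). Each repetition draws fresh site
positions and uses the independent substream (seed, repetition), so results
are reproducible and independent of execution order. Fused sites replenish
in place; expected site counts are rounded to the nearest integer for
stochastic runs while the deterministic engine carries fractional
occupancies.

A two-site master-equation oracle (dense matrix exponential) and an
exponential fusion-time test pin the kernel against independent references;
the stochastic mean amplitudes agree with the deterministic engine within
0.5 nA (3·SEM at 200 repetitions).

## Postsynaptic currents

The mEJC kernel I(t) = A(1−e^(−t/τ_r))(B·e^(−t/τ_df)+(1−B)e^(−t/τ_ds)) uses
the recorded fit (A = 7.21 µA, B = 2.7·10⁻⁹, τ_r = 10.6928 s, τ_df = 1.5 ms,
τ_ds = 2.8 ms); τ_r is startlingly large but only this value reproduces the
~0.7 nA peak, so the rise is effectively linear. The kernel is rescaled to
the quantal size 0.6 nA and truncated below 10⁻⁶ of its peak (≈46 ms). The
fitted onset delay t₀ = 3 ms is an alignment artefact of the mini recordings
and is dropped in simulations, so responses start at the fusion time and
the 10 ms amplitude windows stay aligned with the stimuli. Traces are
1 µs-sampled; convolution takes a direct superposition path for sparse
fusion vectors and FFT otherwise. Currents are handled as positive
amplitudes (all reported comparisons are magnitudes); `inward=True` emits
negative traces.

eEJC₁ is the extremum within 10 ms of the first stimulus. A single
exponential a·e^(−t/τ)+c is fitted from the time the trace falls to 90% of
eEJC₁ until the second stimulus (τ initialised from the segment's
log-slope and bounded to [0.3, 60] ms, offset admitted); eEJC₂ is the
extremum within 10 ms of the second stimulus minus the extrapolated fit.
A zero-extremum trace yields amplitude 0 and an undefined (NaN) PPR; such
repetitions are excluded from PPR statistics and counted.

Variance–mean points are fitted by Var = a·I² + b·I (zero intercept, equal
weights); under a binomial reading N = 1/|a| (rounded) and q = b.

## Fitting

The cost is Σ_k[(A1ₛ−A1ₑ)²/A1ₑ + (A2ₛ−A2ₑ)²/A2ₑ] over the experimental
Ca²⁺ concentrations. Deterministic runs use a reference site count equal to
the number of distance bins; because amplitudes are linear in the site
count, the optimal scale has the closed form c* = Σa/Σ(a²/b), which a grid
search confirms to 10⁻⁶, and n_sites = round(180·c*). Never is the scaled
cost worse than the unscaled one. Nelder–Mead operates on log-transformed
parameters (all positive), initial simplex 10% of the start values, default
tolerances 10⁻³ relative; non-finite evaluations are penalised and logged
in the iteration trace. Ca²⁺ fields are cached by (Q_max, Ca_ext, ISI)
since the field depends on the release parameters only through Q_max. The
Hill fit of fluorescence saturation fixes the exponent at 2.43 by default
(the indicator's cooperativity) and recovers generator parameters to 10⁻⁶
relative on noiseless input.

## Synthetic data

The generators replace the original recordings with surrogates of known
ground truth: Rayleigh cross-section distances, planar distances via the
quantile transform, 51×51 px (10 nm/px) active-zone images with Gaussian
intensity clusters at planar-distribution radii around a jittered centre
(recorded spots are deconvolved to near-Gaussian blobs; only the
averaging/histogram pipeline is under test, not the optics), paired-pulse
datasets produced by the forward pipeline itself, and Hill fluorescence
curves. Dataset noise is multiplicative Gaussian on per-repetition
amplitudes (default CV 5%) — the recordings define no separate noise model,
so this term is a stand-in chosen because amplitude scatter scales with
response size. One global seed expands into fixed per-stage substreams
(`STAGE_STREAMS`), so stages rerun independently and reproducibly.

What passing tests on these surrogates do *not* show: robustness to
stimulation artefacts, baseline drift or run-down in real recordings, to
non-Gaussian STED point-spread functions, or to inter-animal variability —
none of which the generators emulate.

## Problem sizes used in the tests

The default production conditions are 180 distance bins, 71×101 field nodes,
1000 stochastic repetitions (200 in parameter grids) at five external Ca²⁺
concentrations. The test suite exercises the same code paths at reduced
sizes chosen once: coarse 26×41 or 36×51 field grids, 24–60 bins, 8–500
repetitions, and one to three concentrations per check; the residual-decay
and grid-refinement checks run on the full 71×101 grid. Statistical
assertions use fixed seeds and 3·SEM-style allowances so they are
deterministic in the suite.

## Known limitations

* Stochastic Ca²⁺-channel gating is excluded by design (clustered channels
  make its contribution small); the source is axisymmetric and
  deterministic.
* The field solver is first-order in time across the operator split;
  accuracy is controlled empirically by the refinement and Green's-function
  checks rather than by formal order.
* Exact reproduction of previously fitted parameter tables is not a goal:
  those depend on the original recordings and optimiser trajectory. The
  package reproduces the mechanistic behaviours (facilitation ordering,
  Jensen bias, variance–mean parabolas, steady-state occupancies).
* Nelder–Mead is local; multi-start orchestration is left to the caller.
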