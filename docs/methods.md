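# Methods

## Model and protocol

One simulation represents one cell: a 40 × 40 µm square membrane populated
uniformly at random with `round(density · L²)` fluorescent particles
(default 50 spots/µm² → 80,000 particles), each carrying `oligomer_size`
independent fluorophores (default 2, a dimer). Dynamics advance in steps of
τ seconds; per step every particle moves exactly `√(4Dτ)` along one of the
four axis directions chosen uniformly, and a step that would leave the cell
is replaced by its reverse (each particle walks its own offset square
lattice). τ defaults to 0.0125 s for D ≤ 0.1 µm²/s and 0.005 s for faster
diffusion — inside the customary 0.004–0.016 s range, chosen so the step
length stays below ~0.1 µm **and** the 20 Hz camera frame (0.05 s) is an
integer number of steps.

The protocol of a gated (PhotoGate) run is:

1. **Pre-bleach** (t = 0): every fluorophore inside the ROI disc is bleached
   deterministically, an idealisation of an exhaustive spiral pre-bleach.
   (A stochastic multi-pass mode is available via `prebleach_passes`.)
2. **Dark delay** (default 2 s for gated runs, as in the experimental
   protocol): no illumination; a small number of unbleached molecules
   diffuse in past the ROI boundary. This entry phase is what sets the
   interior single-molecule density — with the gate active from t = 0 the
   ROI would simply stay empty.
3. **Imaging** : the TIRF beam (uniform flux, default 2,000 photons s⁻¹ per
   fluorophore, restricted to the ROI) is on until the end of the run; the
   gate fires at the gating frequency, first sweep at the start of imaging.

The ungated (TOCCSL-style) protocol is the same with no gate, no dark delay,
and whole-cell TIRF illumination (consistent with the observation that the
ungated experiment rapidly photobleaches molecules outside the ROI).

**Photobleaching** uses the memoryless photon-budget law: a fluorophore
exposed to intensity *I* for Δt bleaches with probability
`p = 1 − exp(−I·Δt/B)` (B = 5 × 10⁵ photons), drawn independently per
fluorophore. For uniform whole-cell illumination the per-frame Bernoulli
chain is sampled as its exact geometric equivalent once up front (a pure
speed optimisation; the law is identical). Random draws are consumed only
where intensity is non-zero, which makes a zero-amplitude gate bit-identical
to an absent gate at a fixed seed — a tested invariant.

**Gate dose.** One 200 ms sweep is applied as an instantaneous dose
`I(d) · sweep_duration` at each gate event, where `I(d)` is the
sweep-averaged ring intensity (circular average of the Gaussian spot,
evaluated by adaptive quadrature, tabulated on a radial grid for the inner
loop, and verified against the `e^(−κ)I₀(κ)` Bessel closed form to 10⁻⁶).
The sweep is short relative to diffusion across the beam width
(√(4Dτ_sweep) ≈ 0.28 µm ≈ half the beam FWHM at D = 0.1), so intra-sweep
beam motion is not resolved.

## Gate-beam amplitude (the one calibrated parameter)

The gate width (c = 0.42 µm, i.e. 1 µm FWHM), ring radius (= ROI radius)
and sweep time (0.2 s) are instrument values. The beam *amplitude* in
emission-equivalent units is not published. Physically it lies in the
1e7–1e9 photons/s range (a ~MW/cm² focused beam against a ~10 W/cm² TIRF
field exciting 2,000 photons/s). Within that range the package calibrates
it **once** so the gated reference condition (D = 0.1 µm²/s, 0.5 Hz,
14 µm ROI) holds the ROI at its design operating point of ~1 fluorescent
spot/µm², the single-molecule detection limit; the frozen default is
1.7 × 10⁸ photons/s.

At this amplitude one sweep deposits ~1 photon budget at the ring peak
(the sweep-averaged peak intensity is only `i0e(R²/c²)` ≈ 2.4% of the
stationary amplitude), so each pass bleaches *most but not all* of the
fluorophores on the ring. This partial transmission is essential: a
near-perfect absorber ring (e.g. 20 budgets/sweep) both blocks entry *and*
drains the interior, collapsing the ROI density to ~0.05 µm⁻² — and it
kills the frequency/radius dependence of the steady-state density, which
relies on between-sweep crossings of the kill band. The calibrated gate
reproduces the qualitative design rules: 0.5 Hz suffices to hold
D = 0.1 µm²/s below the detection limit, faster diffusion needs ~3 Hz, and
smaller ROIs run at higher effective density.

## Trajectory analysis

A particle is *trackable* in a frame when it has ≥1 alive fluorophore, lies
inside the ROI disc, and its nearest *visible* neighbour is farther than
0.5 µm (twice the diffraction limit). Visible neighbours are alive
particles under illumination — everything in whole-cell mode, only in-ROI
particles in ROI-restricted mode (unilluminated molecules emit nothing);
the strict "all unbleached particles" reading is available via
`neighbor_visibility="all_alive"`. Neighbour queries use a per-frame
`cKDTree` (verified against an O(n²) oracle).

Trackability is assessed at **camera frames** — every
`round(0.05 s / τ)`-th simulation step, the 20 Hz imaging rate of the
reference protocol — because interruptions shorter than one frame are
invisible to the camera; frames during the dark delay are likewise
unobservable. Maximal runs of consecutive trackable camera frames form
trajectories (minimum length one frame; an n-frame trajectory lasts
n × 0.05 s). The end reason is the first condition violated at the next
camera frame: `photobleached` (all fluorophores dead — only these
trajectories are eligible for subunit counting), `proximity`, `roi_exit`,
or `sim_end`. A terminal bleaching event is attributed to the trajectory's
final frame, so a dimer whose two fluorophores die at separate observed
frames of one segment counts as a two-step trajectory. Two-step *fractions*
are reported against both denominators (photobleach-terminated trajectories,
the primary one, and all trajectories), since the reference leaves this
ambiguous.

The gate-escape probability is estimated empirically: a crossing is a
consecutive-frame transition from outside to inside the ring by an alive
particle, and it *escapes* if the particle is still fluorescent after the
next sweep. The estimate is escapes/crossings (0 when no crossings are
observed, with the count reported); it is 1 at zero amplitude, decreases
monotonically with amplitude, and requires a record whose stored region
extends beyond the ring.

## What the simulation does and does not emulate

The generator reproduces the *study conditions*: geometry, density, photon
budget, flux, gating schedules, dimer independence and the trackability
rule. It does not model localisation noise at the tracking layer
(trajectories are ground-truth positions; noise lives in the imaging
module), blinking/triplet states, anisotropic or heterogeneous membranes,
inter-particle interactions, the evanescent-field depth, or the spiral
path of the pre-bleach. Passing tests therefore demonstrate correctness of
the simulation and analysis machinery under these idealisations, not
fidelity to any particular cell type.

**Known systematic differences from the reference statistics.** With the
published parameters taken literally (flux 2,000 s⁻¹, budget 5 × 10⁵ →
fluorophore lifetime 250 s), the reproduced comparison matches the
reference in its headline structure — long-trajectory counts per cell
(~117 vs 120 ± 11 gated, ~9 vs 7 ± 11 ungated), zero >5 s ungated
trajectories at fast diffusion, and the sustained ~1 µm⁻² density plateau —
but three families of numbers deviate beyond their printed uncertainties
and resisted every protocol variant we tried (minimum trajectory lengths
1–8 frames, camera rates 10–62.5 Hz, gate ring at or outside the ROI edge,
fluorophore-vs-spot density readings, restricted neighbour visibility,
bleach-rate rescalings):

* *Mean trackable durations* come out ~1.2–4× shorter (e.g. 0.16 s vs
  0.192 s ungated; 0.26 s vs 0.83 s gated) with correspondingly more short
  segments. The printed means and trajectory counts jointly imply that only
  ~13% of in-ROI spots were trackable at the ~1 µm⁻² plateau, whereas a
  Poisson spatial pattern at that density gives ~42% under the 0.5 µm rule;
  the printed density, counts and means cannot all hold for a spatially
  uniform interior.
* *Ungated two-step bleaching counts* (11.4 ± 4.4 per cell) require
  trajectories to end by photobleaching on a ~0.2 s timescale, which is
  impossible at the 250 s lifetime implied by the printed flux and budget
  (expected in-track double bleaches ≈ 0.01 per cell). The package exposes
  an `emission_factor` to explore the alternative detected-vs-emitted
  reading (factor 25 → 10 s lifetime, matching the measured ~10 s
  photobleaching-limited tracking lifetime of mNeonGreen), but that regime
  degrades the long-trajectory statistics and is off by default.
* *Gated two-step counts* land ~25% high (~110 vs 87.3 ± 7.1) with the
  two-step fraction ~24% vs 31%.

All of these are reported as computed; none of the defaults were moved to
chase individual statistics beyond the single amplitude calibration above.

## Numerical choices

* Quadrature: `scipy.integrate.quad` (rel. tol 10⁻¹⁰) for scalar ring
  intensities; 200-node Gauss–Legendre for the tabulated radial profile
  (agreement ~10⁻¹³); linear interpolation on a 4096-point grid inside the
  simulation loop.
* Frame records store ids/positions/alive counts of fluorescent particles
  within `record_radius` (default ROI + 0.6 µm — the ROI plus the exclusion
  radius) as float32/int32; full-cell storage at reference scale would be
  several GB.
* Mixture fitting: hand-written 1-D EM on raw values with deterministic
  quantile initialisation, σ floor 10⁻⁹, convergence on relative
  log-likelihood change < 10⁻¹⁰; monotone log-likelihood is exposed and
  tested, and the solution is cross-checked against an independent EM
  implementation on separated mixtures.
* Exponential dwell CI: profile likelihood inverted with `brentq`
  (χ²₁-based); FRAP CI: large-sample normal from the least-squares
  covariance. FRAP→D uses the circular-spot half-time relation
  `D = 0.224 r²/t½`, `t½ = τ_rec ln 2`.
* MSD fits: unweighted least squares; default max lag = ¼ of the trajectory
  length; motion classes α ∈ [0.8, 1.2] Brownian, ≥1.6 directed, <0.8
  confined (configurable); the quality filter rejects R² ≤ 0.95 or negative
  intercepts (with a 10⁻⁹ relative tolerance so an exact zero intercept
  passes).
* Pause detection: rolling windows of `window/Δt` steps via cumulative
  sums; positional s.d. = √(var x + var y) about the window mean; merged
  qualifying windows must exceed the window length.
* Spot fitting: pixel-integrated Gaussians (erf differences) for rendering;
  point-sampled Gaussian least squares for fitting (symmetric, hence
  unbiased for the centre); intensity = Gaussian volume 2πAσ².

## Problem sizes

The test suite runs reduced-scale cells (12–20 µm, 2–20 s) for machinery
tests and three full-scale cells per protocol for the comparison
statistics; `scripts/acceptance.py` uses five cells per condition (two for
the fast ungated mean, whose pooled s.e.m. is already far below the
tolerance). One full-scale gated cell (80 s, 80,000 particles, 6,400 steps)
simulates in ~10 s and extracts in ~5 s on one CPU.
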