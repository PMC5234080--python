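# photogate

Monte Carlo simulation and analysis of **gated single-particle tracking**
experiments on crowded cell membranes.

Single-particle tracking (SPT) breaks down when fluorescent molecules are
packed more densely than ~1 spot/µm²: point spread functions overlap and
individual molecules cannot be followed. The *PhotoGate* approach
pre-bleaches a circular region of interest (ROI) and then repeatedly sweeps a
focused "gate" laser beam around the ROI perimeter, photobleaching most
molecules that try to diffuse in. The interior stays at single-molecule
density indefinitely, so individual molecules can be tracked until they
photobleach — unlike TOCCSL-style recovery imaging, where the ROI is overrun
by unbleached molecules within seconds. This package simulates both
protocols from first principles and implements the accompanying SPT analysis
toolkit, so imaging conditions (ROI size, gating frequency, laser flux) can
be optimized *in silico* for a given density, diffusion constant and
oligomeric state.

## Model

* **Diffusion** — each particle (an oligomer carrying `m` fluorophores)
  performs a fixed-step random walk on the bottom membrane of a
  40 × 40 µm cell: per time step τ it moves `√(4Dτ)` along one of the four
  axis directions; steps leaving the cell are reversed.
* **Illumination** — the TIRF imaging beam is a uniform disc of flux *I*
  (photons per fluorophore per second), either restricted to the ROI
  (gated protocol) or covering the whole cell (recovery protocol). The gate
  is a Gaussian spot of amplitude *a* and width *c* swept around a circle of
  radius *R*; its sweep-averaged intensity at distance *d* from the centre is

      I(d) = (a/2π) ∫₀²π exp(−(d² + R² − 2dR·cosθ)/(2c²)) dθ
           = a · exp(−(d−R)²/(2c²)) · e^(−κ) I₀(κ),   κ = dR/c²,

  evaluated by quadrature and verified against the Bessel closed form.
* **Photobleaching** — every alive fluorophore independently bleaches with
  per-exposure probability `p = 1 − exp(−I·Δt/B)`, the memoryless law for a
  mean photon budget *B* (default 5 × 10⁵ photons at a flux of 2,000 s⁻¹).
* **Trackability** — a particle is trackable in a camera frame (20 Hz) when
  it is fluorescent, inside the ROI, and >0.5 µm (twice the diffraction
  limit) from every other visible fluorescent particle. Maximal runs of
  trackable frames are trajectories; those terminated by complete
  photobleaching are usable for subunit counting via discrete bleaching
  steps.

The analysis layer adds MSD computation and fitting (`MSD = 4Dt + b`, or
`4Dt^α` with α-based motion classification), pause detection, maximum-
likelihood Gaussian-mixture fitting of diffusion-constant histograms,
exponential dwell-time and FRAP-recovery fits (`D = 0.224·r²/t½`), a
log-space binomial colocalization test, and synthetic TIRF frame rendering
with 2D Gaussian spot fitting.

## Worked example

A reduced-scale gated experiment (20 µm cell, 10 µm ROI, 20 s — the
full-scale defaults are 40 µm / 14 µm / 80 s):

```python
import photogate as pg

cfg = pg.photogate_config(cell_size=20.0, density=50.0, D=0.1, duration=20.0,
                          roi_radius=5.0, gate_frequency=0.5, seed=1)
record = pg.run_experiment(cfg)
trajs = pg.extract_trajectories(record)
stats = pg.tracking_time_stats(trajs, thresholds=(3.0,))
dens = pg.roi_density(record)
print(f"trajectories: {stats.n_trajectories}")
print(f"mean tracking time: {stats.mean_duration:.3f} +/- {stats.sem_duration:.3f} s")
print(f"tracked > 3 s: {stats.threshold_counts[3.0]}")
print(f"two-step bleaching: {stats.n_two_step} of {stats.n_photobleached} "
      f"photobleach-ended tracks ({100*stats.two_step_fraction:.0f}%)")
print(f"ROI density at t = 10-20 s: {dens.mean_between(10, 20):.2f} spots/um^2")
```

prints

```
trajectories: 2831
mean tracking time: 0.212 +/- 0.008 s
tracked > 3 s: 5
two-step bleaching: 25 of 76 photobleach-ended tracks (33%)
ROI density at t = 10-20 s: 1.13 spots/um^2
```

The gate holds the ROI at ~1 fluorescent spot/µm² — the single-molecule
detection limit — while molecules keep being tracked throughout the run;
a third of the fully-photobleached dimer trajectories show both bleaching
steps, the signature used for subunit counting. Setting
`gate_frequency=None` (or `pg.toccsl_config(...)`) runs the matched
recovery experiment, whose ROI density instead climbs past the detection
limit within seconds.

The same experiments are available from the shell:

```bash
photogate preset fig5a-slow --seed 1 --out out/        # gated vs ungated pair
photogate simulate --diffusion 0.5 --gate-freq 3 --out out/fast
photogate sweep --axis gate_frequency --values 0.25,0.5,1,2,3 --out out/sweep
photogate analyze out/fast/trajectories.csv --frame-interval 0.05
```

Presets `fig5a-slow`, `fig5a-fast`, `fig5b` … `fig5f` bundle the standard
comparison conditions (tracking-time distributions, bleach-step counts,
density vs flux / gating frequency / ROI radius).

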