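# mtlk — microtubule lumen toolkit

Quantification pipelines for experiments on microtubule-stabilizing proteins
that act from the lumen of the microtubule, written for in vitro
reconstitution and structural labs. The package covers the analysis chain
such studies need end to end:

- **Kymograph dynamics** (`mtlk.dynamics`) — classify traced tip
  trajectories into growth / pause / shrinkage events with the standard
  velocity cutoff (0.24 µm/min) and inclusion filters (growth > 0.40 µm,
  pauses > 20 s), and compute the six transition frequencies
  (count of s→t transitions ÷ total time in state s), state time fractions,
  and seed-survival percentages.
- **MINFLUX filament width** (`mtlk.minflux`) — separate two-channel
  localizations by fitting a two-Gaussian mixture to the detector channel
  ratio (channel 1: dcr ∈ [0, µ₁ + 0.5σ₁]; channel 2: [µ₂ − 0.5σ₂, 1]),
  render density maps (1-nm voxels), extract filament centerlines by ridge
  filtering and skeletonization, and measure each filament's width as the
  FWHM of its summed perpendicular intensity profile. A filament labeled on
  its axis at localization precision σ measures ≈ 2√(2 ln 2)·σ ≈ 8.2 nm at
  σ = 3.5 nm; labeling on the 12.5-nm-radius outer surface projects to a
  ring-edge profile ≈ 30 nm wide — the discrimination behind
  luminal-vs-external localization calls.
- **Single-molecule stoichiometry** (`mtlk.stoichiometry`) — lognormal
  brightness calibration (mode = exp(µ − σ²)), molecules per 8 nm of
  accumulation, one-phase association kinetics
  I(t) = I₀ + (plateau − I₀)(1 − e^(−kt)), and Hill-fit half-maximum
  alignment and averaging of intensity build-up profiles with AUC.
- **Protofilament flare geometry** (`mtlk.flares`) — first deflection
  points of manually traced protofilaments (sustained radial excess beyond
  the lattice radius), flare length and curvature (degrees per 8 nm of
  arc), end raggedness (SD of deflection points' axial coordinates), and
  per-tomogram defect densities / intraluminal-particle fractions.
- **EB-comet counting** (`mtlk.comets`) — rolling-ball background
  subtraction (radius 10 px), Kapur maximum-entropy thresholding,
  8-connected particle analysis with a 0.10 µm² cutoff, densities per
  100 µm².
- **Synthetic data** (`mtlk.simulate`) — generators with known ground
  truth for every input above: a three-state continuous-time Markov tip
  simulator, MINFLUX localization tables (axial / surface / outside
  labeling, dcr mixtures, trace grouping), stepwise-arrival intensity
  traces, protofilament flares on a cylinder, and comet images. Every
  analysis here is validated by round-trip against these generators.

## Worked example

Simulate 50 dynamic microtubules under a paused-growth regime and recover
the dynamics parameters:

```python
from mtlk.simulate import DynamicsConfig, simulate_many
from mtlk.dynamics import Thresholds, analyze_trajectory, summarize_dynamics

cfg = DynamicsConfig(
    v_growth=2.0, v_shrink=30.0,           # µm/min
    growth_to_shrinkage=0.004,             # catastrophe rate, 1/s
    shrinkage_to_growth=0.02,              # rescue rate, 1/s
    growth_to_pause=0.01, pause_to_growth=0.01,
    duration=600.0, dt=0.5, rng_seed=0,
)
trajectories = simulate_many(cfg, 50)
tables = [analyze_trajectory(t, Thresholds()) for t in trajectories]
summary = summarize_dynamics(tables)
```

This prints (via the `DynamicsSummary` fields):

```
growth rate: 1.99 ± 0.00 µm/min (n = 211 events)
pause duration: 95.7 ± 7.1 s (n = 120)
state fractions: {'growth': 0.596, 'pause': 0.387, 'shrinkage': 0.017}
catastrophe frequency: 0.0030 /s (53 events)
```

The recovered growth rate matches the configured 2 µm/min; the measured
catastrophe frequency (0.0030/s) sits below the configured hazard (0.004/s)
because the default kymograph filters absorb short events — run with
`Thresholds(min_growth_length=1e-6, min_pause_duration=1e-6)` for unbiased
rate recovery, as the acceptance script does.

A command-line interface mirrors the library
(`mtlk simulate {dynamics,minflux,intensity,flares,comets}` and
`mtlk analyze {dynamics,minflux,stoichiometry,flares,comets}`); see
`mtlk --help`.

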