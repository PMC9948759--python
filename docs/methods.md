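# Methods

This note documents the models behind each pipeline, the defaults and why
they were chosen, the numerical decisions that matter, and what the
synthetic generators do and do not emulate.

## Dynamic instability model and event analysis

Tip dynamics are modelled as a continuous-time Markov chain over three
states — growth (+v_g), pause (0), shrinkage (−v_s) — with six independent
transition rates (1/s) and exponential dwell times. Exponential dwells are
the minimal model consistent with reporting transition *frequencies*
(events ÷ time at risk); no claim is made about real dwell-time shapes, and
non-exponential pausing would require a semi-Markov extension. The tip
position is floored at the seed (position 0): on a stabilized seed a
shrinkage excursion reaching 0 re-enters growth ("reset"); in "stop" mode
the record ends there (a depolymerizing seed, used for seed-survival
assays). Trajectories carry both the exact continuous segment record and a
dt-sampled polyline with per-sample state labels.

The classifier mirrors manual kymograph tracing: velocities are computed
between polyline vertices, classified with a strict cutoff (default
0.24 µm/min — a segment at exactly the cutoff is a pause), and merged into
events. Inclusion filters (growth/shrinkage longer than 0.40 µm, pauses
longer than 20 s, both strict) flag sub-threshold events, which are
*absorbed into the preceding included event* to keep the timeline
contiguous; leading sub-threshold events join the first included one, and a
trace with no included event collapses to the state of its longest raw
event. Whether the original tracing conventions absorbed such events
forward, backward, or dropped them from denominators is not documentable
from published descriptions; the backward-absorption rule here is a
package decision, chosen so every second of the record has a well-defined
state and frequency denominators are conservative.

Transition frequency for s→t is count(s→t) ÷ total time in state s (time in
the source state, the time the transition "could have occurred"; a
configurable alternative divides by total observation time). Two details
make simulator round-trips exact in expectation:

- **Boundary censoring.** A shrinkage exit at the seed is a geometric
  artifact, not a stochastic rescue. Such transitions are excluded from the
  counts while the (censored) shrinkage time stays in the denominator —
  the maximum-likelihood estimator for a censored exponential. The
  at-seed test uses a position tolerance (default 0.02 µm) covering one
  sampling interval of regrowth.
- **Filter bias.** The 0.40 µm / 20 s filters censor short true events and
  bias recovered frequencies (≈ +17% on a 0.01/s pause exit rate at a 20-s
  cutoff), which is why rate-recovery validation runs with negligible
  filter thresholds while worked-example tests exercise the defaults.

Growth-rate and pause-duration statistics pool included raw events (mean ±
SEM, sample SD with ddof = 1, flagged undefined at n = 1); state fractions
and frequencies use the absorbed timeline, pooled across microtubules
before division.

## MINFLUX width measurement

Channel separation fits a two-component 1D Gaussian mixture to the dcr
values by EM with a deterministic initialization (median split; means/SDs
of the halves; equal weights) so results are reproducible without a seed;
convergence at |Δ log-likelihood| < 1e-8 or 500 iterations, variances
floored at 1e-8, components reported sorted by mean. Channel 1 is the
closed interval [0, µ₁ + 0.5σ₁], channel 2 is [µ₂ − 0.5σ₂, 1]; overlapping
intervals raise an error rather than guessing. Localization precision QC
uses runs of >4 consecutive localizations sharing a trace id; per-axis
sample SDs are histogrammed (0.25-nm bins) and the modal bin center
reported.

Density maps are count histograms with floor((coord − origin)/voxel)
indexing (1-nm default voxels in 2D, 4 nm in 3D; cross-section views of 3D
maps are maximum projections over an 800-nm along-axis window). Centerlines
are extracted by Gaussian smoothing (σ = scale/3), a curvilinear tubeness
(Sato) filter at the expected filament half-width (scale 15 nm),
thresholding, skeletonization, and a tree-diameter longest-path prune.
Two numerical choices deviate from the most obvious defaults, both because
per-filament localization statistics are clustered (≈ 250 fluorophores per
2000 localizations, 8 localizations each):

- **Threshold.** A fixed image quantile is fragile when the map is cropped
  tightly around the filament (the "background" pixel mass varies with the
  crop), so the default threshold is a fraction (0.08) of the maximum ridge
  response; a quantile mode is available.
- **Centerline regularization.** The raw skeleton wanders a few nm toward
  individual fluorophore clusters, which systematically distorts
  perpendicular profiles (it converts the double-peaked surface-label
  profile into a spuriously narrow unimodal one). The skeleton is therefore
  smoothed and refitted as a cubic polynomial in its own principal frame —
  flexible enough for gently curved filaments, too stiff to chase clusters.

The width profile bins signed perpendicular distances of map voxels (or raw
localizations) to the centerline, within 50 nm, excluding points that
project beyond the centerline span (end-flare guard), and sums along the
filament. The FWHM estimator addresses two failure modes of naive
half-maximum reading on noisy binned profiles: (i) the *envelope* crossing
rule takes the outermost half-maximum crossings, bridging brief sampling
dips — without it, one third of surface-labeled filaments collapse to a
single ring edge (the projected-ring dip sits at 0.72 of the peak, within
sampling noise of 0.5); (ii) the half-maximum *level* is taken from a
Savitzky–Golay smoothed profile whose window scales with a first-pass width
estimate (0.75×width, 5–21 bins), removing the upward bias of the maximum
of a noisy profile without flattening narrow peaks. Validated against
independent oracles, the pipeline measures axially labeled filaments at
+2% of 2√(2 ln 2)·σ and surface-labeled filaments at −2% of the
projected-ring ⊛ Gaussian quadrature oracle; the raw nearest-crossing
variant remains available (`crossing="nearest"`, `smooth=None`).

## Stoichiometry

Single-fluorophore brightness is calibrated by closed-form lognormal MLE on
log intensities; the mode exp(µ − σ²) is the one-molecule reference
(histogram least-squares would fit the same model less stably). Molecules
per 8 nm = (integrated ÷ mean single intensity) × (8 ÷ length). The TIRF
z-attenuation of filament-bound fluorophores (≈ 0.8) is an optional
multiplicative correction, off by default, since it is an interpretation
rather than a calibrated constant. One-phase association fits use
least squares with k bounded positive. Profile alignment normalizes each
profile to its maximum, fits a Hill curve anchored at the profile's own
start time (making the reference shift-equivariant, hence alignment
idempotent), and uses t½ = K as the reference; a generic logistic is
available where the Hill form is inappropriate. AUC is trapezoidal on the
native grid.

## Flare geometry

The deflection point is the first trace point whose radial distance from
the microtubule axis exceeds lattice_radius + tol (default 12.5 + 1.5 nm)
and stays beyond it for the rest of the trace; a trace that never leaves
the cylinder deflects at its last point (blunt). The reported axial
coordinate interpolates the radial crossing between the deflection point
and its predecessor, removing the trace-spacing quantization. The axis for
one end is either supplied or estimated in two passes: pooled PCA, then the
*average of per-protofilament lattice-line directions* with an
equal-weight-per-protofilament centroid origin. The averaged-directions
step matters: ragged ends correlate axial extent with azimuth and tilt a
pooled PCA axis by a fraction of a degree, which the shallow radial-excess
slope at the deflection point amplifies several-fold into tens of nm of
axial error.

Flare metrics: length is the 3D arc length from deflection to tip; total
curvature is the sum of turning angles between consecutive segments;
terminal curvature is the turning accumulated over the final 24 nm of arc
(a configurable window — the original window length is not documentable),
per 8 nm of arc (the tubulin-dimer repeat). Raggedness is the sample SD
(ddof = 1) of deflection axial coordinates, undefined below two
protofilaments. Lattice annotations (defect counts, intraluminal-particle
flags) are inputs — defect identification is visual — and are summarized
per tomogram (Σ defects ÷ Σ length; % flagged) with mean ± SD across
tomograms.

## Comet counting

Rolling-ball background subtraction uses the classical ball-opening
algorithm (scikit-image); exact ImageJ pixel parity is not promised —
correctness is asserted against morphological properties (offset
invariance, constant-image null, peak preservation). The Kapur
maximum-entropy threshold maximizes the summed Shannon entropies of the
two histogram classes over 256 bins spanning the image min–max; ties take
the lowest split, candidate splits leaving an empty class are skipped, and
the returned threshold is the upper edge of the last background bin
(foreground = strictly above). It is tested against an O(L²) brute-force
enumeration. Particle analysis uses 8-connectivity (configurable) and keeps
components ≥ 0.10 µm²; densities are per 100 µm² of supplied cell area. A
featureless (constant) image counts zero by definition; note that
maximum-entropy thresholding of a pure-noise image will, like any
parameter-free threshold, "find" structure — blank-field control images
should be handled upstream.

## Synthetic generators: what they emulate, and what not

All generators are seeded (`numpy.random.default_rng`, one stream per
call) and byte-reproducible. Defaults encode the study conditions used
throughout the tests: growth 2 µm/min, shrinkage 30 µm/min, catastrophe
0.004/s, rescue 0.02/s, growth↔pause 0.01/s; localization σ = 3.5 nm
(within the 3.0–4.3 nm precision regime of MINFLUX acquisitions) on a
12.5-nm-radius lattice with ~8 localizations per fluorophore; lognormal
brightness σ = 0.35 with plateau 2 molecules at k = 0.1/s; 13
protofilaments with 12-nm end raggedness, 40 ± 10 nm flares at
4.58 ± 1°/8 nm curvature on 100-nm lattice stubs sampled every 4 nm.

Deliberate simplifications: dcr is independent of position (no spectral
cross-talk gradients); no blinking, bleaching, or drift in localization
data; surface labeling projects the cylinder to the imaging plane (full 3D
sampling only when σ_z > 0); comets are discs, not elongated comet shapes,
because area-threshold counting is shape-insensitive; intensity traces have
Gaussian camera noise only. Passing round-trips therefore demonstrate
estimator correctness under the stated statistical structure, not
robustness to drift, bleaching, or segmentation failure modes of real
acquisitions.

## Problem sizes

The test suite runs in about a minute: round-trip checks use 50–200
simulated microtubules, 3–50 filaments per labeling mode, 10³–10⁴ sample
draws, 60–100 simulated ends. `scripts/acceptance.py` re-runs the
acceptance-scale versions (200 MTs × 600 s; 50 + 50 filaments × 2000
localizations; 10⁴-sample mixtures; 2000 association traces; 100 ends; a
35-blob comet field) in under a minute on one CPU.
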