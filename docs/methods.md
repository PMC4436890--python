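# Methods

This note documents the models, conventions and numerical choices behind
`retmap`: what the synthetic study emulates, how each analysis stage is
defined, and where a genuinely open design decision was resolved.

## The synthetic study

Real phase-encoded retinotopy acquisitions of this kind are not publicly
available, so the study conditions are generated. The defaults are the
acquisition and stimulation parameters of a typical 3 T protocol:
stimulation period 32 s for both rings and wedges, TR 2 s, ring eccentricity
0.2°–3.0°, two wedges with a 180° phase lag, 3 mm isotropic voxels. The run
length defaults to 224 volumes — 14 whole stimulation cycles — so the
stimulation frequency falls on an exact DFT bin and the noiseless limit is
machine-exact; runs with a non-integer cycle count (e.g. 235 volumes) are
supported because the analysis evaluates the Fourier coefficient at the
exact stimulation frequency rather than the nearest FFT bin (identical to
the FFT bin when cycles are integer, free of leakage bias when not).

**The patch.** A 60 × 62 mm regular grid at 1 mm spacing (3843 vertices,
7440 triangles), triangulated with consistent orientation. Flat 2-D
coordinates are authoritative for all intrinsic geometry; a low-amplitude
sinusoidal height field lifts the patch into 3-D so that the volume/surface
plumbing is genuinely exercised. No folded-cortex generation, segmentation
or flattening is attempted.

**The layout.** Six bands stacked along the flat y axis in the order
V3d–V2d–V1–V2v–V3v–V4, widths 8/8/16/8/8/14 mm. Eccentricity runs along x
with the exponential law ε(x) = ε_min·exp[(x/W)·ln(ε_max/ε_min)] — the
constant-cortical-speed form implied by a ring whose speed grows linearly
with eccentricity under exponential cortical magnification. Polar angle runs
along y within each band: V1 and V4 span the full contralateral hemifield
[−π/2, +π/2], V2 and V3 span quarterfields folding back at the horizontal
meridian, and the angle gradient flips sign at every border — which *is* the
field-sign alternation (V1 +1, V2 −1, V3 +1, V4 −1 in this hemisphere
convention). Band widths were chosen so the polar-angle slope magnitude
matches across borders (quarter-field bands half the width of V1): with
matched slopes the zero-gradient ridge produced by Gaussian smoothing stays
on the true border instead of migrating into the shallower band. V1 is
strictly the widest band, as required for the V1-largest selection rule to
be satisfiable; bands are half-open toward the next band (a border vertex
row belongs to the band above), with the far edge of V4 inclusive.

**The signal.** Per vertex, the forward run is
A·cos(2πt/T − φ_coord − φ_h) and the backward run
A·cos(2πt/T + φ_coord − φ_h), with hemodynamic delay phase
φ_h = 2π·delay/T (default delay 5 s), plus an optional linear drift ramp and
i.i.d. Gaussian noise. The real acquisitions' noise spectrum is unknown;
white noise with an adjustable standard deviation is a stand-in that lets
tests sweep SNR, not a claim about the scanner. `noise_sd_for_snr` inverts
the SNR statistic's white-noise expectation (a noise bin's amplitude is
Rayleigh with mean sd·√(π/N)), so studies can be parameterized directly by
target per-voxel SNR: SNR ≈ 3 corresponds to noise sd ≈ 2.81 at unit
amplitude.

**Activation clusters.** Disc-shaped vertex clusters (default four, radius
3 mm) placed wholly inside V4 or wholly inside V2v/V3v with disjoint
supports, so a requested V4 fraction is realized to within one cluster's
vertex count. Real color-responsive clusters need not respect areal borders;
pure placement is deliberate, because it makes the V4-fraction statistic's
construction checkable exactly.

What passing tests on this generator do **not** show: robustness to
physiological noise structure (cardiac/respiratory aliasing, motion),
to distortions of a real flattened reconstruction, or to deviations of real
retinotopy from the idealized band model (e.g. foveal confluence).

## Phase analysis

* **SNR definition.** "Signal-to-noise ratio at the stimulation frequency"
  is implemented as stimulation-frequency amplitude divided by the mean
  amplitude over the noise band — all rFFT bins except DC, bins at or below
  the detrend cutoff (default 2 cycles/run), and bins within half a
  cycle/run of the stimulation frequency and its 2nd–3rd harmonics. This is
  the standard definition for phase-encoded designs and makes the
  assignment (SNR > 2) and delineation (SNR > 3) thresholds meaningful on
  synthetic data. In the noiseless limit the measured noise floor is the
  float64 rounding floor, so SNR is astronomically large rather than
  infinite in practice; infinities that do occur are capped at the largest
  finite value whenever SNRs are used as weights.
* **Delay cancellation (phase combination).** Stimulus phase
  (φ_bwd−φ_fwd)/2, delay −(φ_fwd+φ_bwd)/2. Half-angles are defined modulo π;
  the branch is chosen so the implied delay falls in a physiological window,
  default [0, T/2] = [0, 16 s]. If both branches fall inside (only possible
  at the window edges), the smaller delay wins; if neither does, the
  location is flagged unresolved rather than raising. A 1e−9 rad guard keeps
  a delay of −0.0 from wrapping to 2π.
* **Reverse-and-average.** out[t] = (fwd[t] + bwd[N−1−t])/2. Reversing a
  sampled cosine about its last sample introduces the fixed offset
  C = 2πf·TR·(N−1); the averaged pair is cos(φ_h − C/2)·cos(ωt − (φ + C/2)),
  so the operation reports the delay-independent offset C/2, which the
  decoder subtracts. Two consequences worth knowing: the route's amplitude
  is attenuated by cos(φ_h − C/2) (≈ 0.38 at the 5 s default), which makes
  its per-voxel phase noisier than the phase-combination route at equal
  input SNR; and when that factor changes sign as a function of delay
  (between 5 s and 8 s under the defaults) the combined phase flips by π.
  Phases are delay-invariant only within one attenuation-sign regime.
  Because both chains smooth before delineating, the operative comparison
  between routes is on the 2.5 mm-smoothed surface maps, where their median
  disagreement at per-voxel SNR ≈ 3 is ≈ 0.04 rad.
* **Correlation fit.** Pearson correlation against cos(2πft − kΔ) for
  k = 0..15, Δ = 0.2 rad, threshold r = 0.2 — implemented exactly as those
  defaults state even though 16 × 0.2 rad spans only 3.2 rad < 2π; both
  parameters can be overridden. Constant series have undefined r and are
  flagged undefined.

## Surface operations

* **Volume→surface assignment.** Candidates are voxels whose centers lie
  within 3 mm of the vertex (3-D Euclidean distance) with SNR > 2. A
  "linear combination of phases" is ill-posed for circular data, so the
  vertex phase is the argument of the candidates' unit-phasor sum weighted
  by snr·(1 − d/d_max) (triangular taper); for tight phase clusters this
  reduces to a weighted linear combination of the angles. The resulting
  phase always lies in the circular convex hull of its candidates.
* **Smoothing.** Gaussian kernel over flat-geodesic distances approximated
  by shortest paths on the mesh edge graph, truncated at 3σ; the stated
  2.5 mm is taken as σ (the σ-vs-FWHM convention is not fixed by the
  phrase "2.5 mm Gaussian filter"; σ is exposed as a parameter). Neighbor
  weights are Gaussian × neighbor SNR; undefined neighbors are excluded;
  the SNR field is smoothed with the same weights. The sparse weight
  matrix is precomputed once per (mesh, kernel) in `SurfaceSmoother` and
  reused across maps and replicates.
* **Decoding.** Phases are taken modulo 2π (each stimulus sweeps its
  coordinate exactly once per cycle, so the phase→coordinate map is
  injective on [0, 2π)); eccentricity by the exponential law's inverse,
  polar angle linearly. The exact phase 2π is identified with 0 — the ring
  at maximal eccentricity is replaced by one at minimal eccentricity — so
  the single vertex column encoding exactly ε_max is recovered through its
  smoothed neighborhood rather than the raw wrap.
* **Label back-projection.** Each voxel center within 3 mm of a labeled
  vertex takes the nearest labeled vertex's label, distance ties to the
  smaller label code. At 3 mm voxels over 8 mm bands the
  surface→volume→surface round trip reproduces ≈ 92% of vertex labels;
  the ≈ 8% loss is boundary quantization of about half a voxel per border,
  intrinsic to the resolution ratio.

## Delineation

Per triangle the VFR is the ratio of the signed area of the triangle's image
in Cartesianized field coordinates (ε·cosθ, ε·sinθ) to its signed flat area
(a (ln ε, θ) field space is available as an option). Scaling flat
coordinates by c scales VFR by 1/c²; scaling the field by c scales it by c².

Eligible vertices have both smoothed SNR maps above 3 and decoded
eccentricity inside the stimulated window (0.2°–3.0°, inclusive with a
relative 1e−9 guard). Triangles whose neighbor-averaged |VFR| falls below
2% of the median |VFR| (one face-adjacency averaging pass; the tolerance is
a free parameter, no canonical value exists) form the zero-VFR border
contour; remaining eligible triangles are partitioned into edge-connected
components of uniform VFR sign. The largest component by vertex count is V1.
Adjacency walks along the band axis label the rest: on each side of V1's
centroid the nearest opposite-sign component becomes V2d/V2v, the next
V3d/V3v, and ventrally one more step reaches V4; components not reached
within three steps stay unlabeled, and a distance tie goes to the larger
component (logged). Vertices incident to several components take the
majority component, ties to the more ventral one — mirroring the
ground-truth convention that a border row belongs to the band above.
An empty eligible set yields an empty labeling, never an exception. V3A and
more anterior maps are never labeled. Delineation is deterministic given its
inputs.

**Emulated manual delineation.** `perturb_labeling` displaces each
inter-area border along the band axis by a smooth low-order sinusoid mixture
in x with RMS amplitude equal to the requested shift, reassigning labels
column-wise while keeping the labeled vertex set fixed. It emulates the
hand-drawn borders of an interactive chain for agreement studies; it assumes
the labeling is a band layout along y (true for ground truth and for its
perturbations).

## Agreement statistics

Per-area overlap is the Jaccard percentage on vertex sets (vertices, not
flat-map pixels). An area absent from both labelings is *missing* — group
tables report reduced n rather than imputing a score — while an area present
in exactly one labeling scores 0. The V4 activation fraction uses
ventral = {V2v, V3v, V4} by default and is missing when no activation falls
ventrally; it is invariant to activation outside the ventral union. Group
reports give per-area mean and sample SD (ddof 1) over defined cases;
between-chain agreement is the Pearson correlation over cases with both
values present (≥ 3 required; zero variance → undefined).

## Problem sizes and tolerances

The default study (3843 vertices, 224 volumes) runs each full
simulate-to-delineate pass in well under a second once the smoother is
built, so the test suite sweeps 5 noise levels × 20 replicates and the
acceptance script repeats the noisy route comparison 20 times at full size.
Noiseless identities are asserted at 1e−6 rad (they hold to ~1e−14);
brute-force oracle comparisons at 1e−9; Monte-Carlo quantities at ±3
standard errors. Noise levels for sweeps ({0, 1, 2.81, 5.63, 11.25} at unit
amplitude) correspond to per-voxel SNR {∞, 8.4, 3, 1.5, 0.75}, bracketing
the delineation threshold.

## File formats

GIfTI for surfaces and per-vertex data (float32, as the GIfTI standard
requires — integer labels survive exactly), uncompressed NIfTI-1 for
volumes (float64 payloads round-trip to 1e−12), a plain-text OFF-like
format for full-precision meshes, TSV for reports and label legends, YAML
for configuration. The pipeline writes a manifest of SHA-256 checksums;
identical configuration and seeds reproduce identical checksums.

## Known limitations

- The band model has no foveal confluence, no eccentricity-dependent band
  curvature, and no dropout/veins; delineation accuracy on real data will
  be lower than the synthetic figures.
- The reverse-average route's π ambiguity at attenuation sign changes is
  inherent to that route; the phase-combination route with its delay window
  has no such ambiguity inside the window.
- `perturb_labeling` requires a band-structured labeling; it is not a
  general boundary perturbation on arbitrary label maps.
- The correlation fit's printed 16 × 0.2 rad grid does not span a full
  cycle; phases outside [0, 3.0] rad are only reachable by overriding the
  grid parameters.
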