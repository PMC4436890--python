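# retmap — phase-encoded retinotopic mapping and automatic V1–V4 delineation

`retmap` is a tested, end-to-end pipeline for **phase-encoded retinotopy**:
the fMRI technique in which a slowly expanding/contracting ring and a pair of
rotating wedges convert a voxel's preferred visual-field position
(eccentricity ε, polar angle θ) into the *temporal phase* of its BOLD
response. The package analyzes such recordings, projects the results onto a
flattened cortical surface patch, delineates the early visual areas
V1, V2d/v, V3d/v and V4 automatically from the visual field sign, and
quantifies the agreement between delineations. Because no public dataset
accompanies this class of acquisition, the package ships a first-class
synthetic-data module that generates a flat occipital patch with a known
ground-truth retinotopic layout, so every stage is validated against truth.

It is aimed at visual-neuroscience methods work: comparing automatic vs
manual delineation chains, benchmarking projection/smoothing choices, and
teaching the traveling-wave analysis.

## The method

**Encoding.** Stimulation is periodic (period `T = 32 s`, TR 2 s, 224
volumes). The ring's eccentricity grows exponentially in time so the cortical
activation wave travels at constant speed under exponential cortical
magnification; response phase is therefore proportional to log-eccentricity:

    φ_e = 2π · ln(ε/ε_min) / ln(ε_max/ε_min),   ε ∈ [0.2°, 3.0°]

Two wedges 180° apart encode polar angle; within one hemisphere a single
response cycle spans the contralateral hemifield:

    φ_p = 2π · (θ + π/2) / π,   θ ∈ [−π/2, +π/2]

**Analysis.** Each voxel's complex Fourier coefficient at the stimulation
frequency gives response phase and amplitude; SNR is the amplitude divided by
the mean amplitude of the non-stimulus frequency band. The hemodynamic delay
φ_h is cancelled by combining runs with opposite stimulus direction: with
forward phase −(φ+φ_h) and backward phase (φ−φ_h), the stimulus phase is the
circular half-difference (φ_bwd−φ_fwd)/2 and the delay is −(φ_fwd+φ_bwd)/2,
with the half-angle branch fixed by a physiological delay window. An
alternative route averages the forward run with the time-reversed backward
run; a correlation fit against 16 phase-lagged sinusoids (Δ = 0.2 rad,
r ≥ 0.2) is also provided.

**Delineation.** Volume phases are assigned to mesh vertices from voxels
within 3 mm with SNR > 2, smoothed on the surface with a 2.5 mm Gaussian
kernel, and decoded back to (ε, θ). The **Visual Field Ratio** (VFR) — the
signed area of a triangle's image in the visual field divided by its flat
cortical area, a discrete Jacobian — changes sign at every border between
adjacent visual areas. Vertices with SNR > 3 and ε inside the stimulated
range are partitioned into sign-consistent components bounded by the
zero-VFR contour; the largest component is V1 and adjacency walks label
V2d/V3d dorsally and V2v/V3v/V4 ventrally.

**Agreement statistics.** Two delineations of the same surface are compared
per area with the intersection-over-union percentage
`100·|A∩B|/|A∪B|`; activation patterns are summarized by the V4 fraction
`100·|active∩V4|/|active∩ventral|` with ventral = V2v∪V3v∪V4.

## Worked example

```python
import numpy as np
from retmap import synth, phase, surface, fieldsign, evaluate as ev
from retmap.types import StimulusParams, BAND_ORDER

stim = StimulusParams()                      # 32 s period, TR 2 s, 224 vols
mesh = synth.build_flat_patch(60, 62, 1)     # 3843-vertex flat patch
vf, truth = synth.synthesize_ground_truth(mesh, None, stim)
runs = synth.simulate_runs(vf, stim, noise_sd=1.0, seed=0)

smoother = surface.SurfaceSmoother(mesh, kernel_mm=2.5)
maps = {}
for coord in ("eccentricity", "polar"):
    fwd = phase.dft_phase_snr(runs[(coord, "forward")])
    bwd = phase.dft_phase_snr(runs[(coord, "backward")])
    combined, delay = phase.combine_opposite_directions(fwd, bwd, stim.period_s)
    maps[coord] = smoother.smooth_map(combined)

decoded = surface.decode_visual_coordinates(maps["eccentricity"], maps["polar"], stim)
fsm = fieldsign.compute_vfr(mesh, decoded)
auto = fieldsign.label_areas(mesh, fsm, maps["eccentricity"], maps["polar"], decoded)
for area in BAND_ORDER:
    print(f"{area:4s} overlap with truth: {ev.overlap_score(auto, truth, area):5.1f}%")
```

prints (at noise_sd 1.0, i.e. per-voxel SNR ≈ 8):

```
V3d  overlap with truth:  99.4%
V2d  overlap with truth:  99.0%
V1   overlap with truth:  99.5%
V2v  overlap with truth:  99.0%
V3v  overlap with truth:  99.2%
V4   overlap with truth:  99.9%
```

i.e. the automatic delineation reproduces the ground-truth area layout to
within the one-triangle uncertainty at the zero-VFR borders. The recovered
`delay` map is spatially constant at the injected 5 s hemodynamic delay.

## Command line and analysis scripts

`retmap run-all --config cfg.yaml --out out/ --seed 0` executes
simulate → analyze → project → delineate → evaluate, writing GIfTI surfaces,
NIfTI volumes, TSV reports and a `manifest.json` with SHA-256 checksums
(bit-identical across reruns of the same config and seed). Individual stages
are available as subcommands; `retmap init-config cfg.yaml` writes the
defaults.

The `analysis/` scripts are narrative drivers over the library:
`01_simulate.py` (study conditions), `02_phase_analysis.py` (phase recovery
and route agreement), `03_delineate.py` (delineation accuracy vs noise),
`04_agreement.py` (per-area mean±SD overlap table and between-chain V4
correlation). Each writes its tables under `results/`.

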