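"""Synthetic phase-encoded retinotopy data with known ground truth.

Generates everything a desk-scale study needs: a flat occipital-like
patch, a ground-truth retinotopic layout of cortical bands
V3d-V2d-V1-V2v-V3v-V4 with alternating visual field sign, the four
phase-encoded BOLD runs (ring expand/contract, wedge CW/CCW), voxelized
volume versions of surface data, and compact activation clusters in the
ventral bands for the V4-overlap statistic.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import coding
from .types import (
    AREA_CODES,
    BAND_ORDER,
    ActivationMask,
    AreaLabeling,
    ParameterError,
    RunTimeSeries,
    StimulusParams,
    SurfaceMesh,
    VisualFieldMap,
    VolumeGrid,
)

__all__ = [
    "BandLayout",
    "build_flat_patch",
    "synthesize_ground_truth",
    "simulate_runs",
    "noise_sd_for_snr",
    "rasterize_to_volume",
    "make_activation_clusters",
]

#: Polar angle at the (dorsal edge, ventral edge) of each band.  The
#: values follow from meridian continuity: area borders sit on vertical
#: or horizontal meridians, quarter-field areas (V2, V3) fold back at
#: the horizontal meridian, and V1 and V4 each span a full hemifield.
#: Traversing dorsal -> ventral the angle gradient flips sign at every
#: border, which is exactly the field-sign alternation.
_BAND_THETA = {
    "V3d": (-np.pi / 2, 0.0),
    "V2d": (0.0, -np.pi / 2),
    "V1": (-np.pi / 2, np.pi / 2),
    "V2v": (np.pi / 2, 0.0),
    "V3v": (0.0, np.pi / 2),
    "V4": (np.pi / 2, -np.pi / 2),
}


@dataclass(frozen=True)
class BandLayout:
    """Widths (mm, along the flat y axis) of the six cortical bands.

    Defaults give quarter-field bands half the width of full-hemifield
    V1 so the polar-angle gradient magnitude matches across borders;
    V4 is slightly narrower than V1 (V1 must be the widest band for the
    V1-largest selection heuristic to be satisfiable).
    """

    band_widths_mm: dict[str, float] = field(
        default_factory=lambda: {
            "V3d": 8.0,
            "V2d": 8.0,
            "V1": 16.0,
            "V2v": 8.0,
            "V3v": 8.0,
            "V4": 14.0,
        }
    )

    def __post_init__(self) -> None:
        for name, w in self.band_widths_mm.items():
            if name not in BAND_ORDER:
                raise ParameterError(f"unknown band name: {name!r}")
            if w <= 0:
                raise ParameterError("band widths must be positive")
        if set(self.band_widths_mm) != set(BAND_ORDER):
            raise ParameterError("layout must specify all six bands")
        w1 = self.band_widths_mm["V1"]
        others = [w for n, w in self.band_widths_mm.items() if n != "V1"]
        if w1 <= max(others):
            raise ParameterError("V1 must be strictly the widest band")

    @property
    def total_height_mm(self) -> float:
        return float(sum(self.band_widths_mm[b] for b in BAND_ORDER))

    def band_edges(self) -> np.ndarray:
        """Cumulative band boundaries from the dorsal edge, length 7."""
        widths = [self.band_widths_mm[b] for b in BAND_ORDER]
        return np.concatenate([[0.0], np.cumsum(widths)])


def build_flat_patch(
    width_mm: float,
    height_mm: float,
    spacing_mm: float,
    hemisphere: str = "left",
) -> SurfaceMesh:
    """Regular triangulated grid patch with a smooth 3-D lift.

    The flat coordinates are the grid positions; the 3-D coordinates
    add a low-amplitude sinusoidal height field so that the 3-D and
    flat embeddings are not trivially identical.
    """
    if spacing_mm <= 0:
        raise ParameterError("spacing_mm must be positive")
    if width_mm < 2 * spacing_mm or height_mm < 2 * spacing_mm:
        raise ParameterError("patch extent must be at least twice the spacing")
    nx = int(round(width_mm / spacing_mm)) + 1
    ny = int(round(height_mm / spacing_mm)) + 1
    xs = np.arange(nx, dtype=float) * float(spacing_mm)
    ys = np.arange(ny, dtype=float) * float(spacing_mm)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")  # row-major over y
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    z = 2.0 * np.sin(2 * np.pi * flat[:, 0] / max(width_mm, 1.0)) * np.cos(
        2 * np.pi * flat[:, 1] / max(height_mm, 1.0)
    )
    xyz = np.column_stack([flat, z])
    # two CCW triangles per grid cell
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="xy")
    v00 = (j * nx + i).ravel()
    v10 = v00 + 1
    v01 = v00 + nx
    v11 = v01 + 1
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    mesh = SurfaceMesh(
        vertex_xyz=xyz, vertex_flat=flat, faces=faces, hemisphere=hemisphere
    )
    mesh.validate()
    return mesh


def synthesize_ground_truth(
    mesh: SurfaceMesh,
    layout: BandLayout | None = None,
    stim: StimulusParams | None = None,
) -> tuple[VisualFieldMap, AreaLabeling]:
    """Ground-truth retinotopy on a flat patch.

    Eccentricity runs along the flat x axis with the exponential law
    eps(x) = ecc_min * exp((x/W) * ln(ecc_max/ecc_min)) (constant
    cortical speed of the ring-driven activation wave under exponential
    magnification).  Polar angle runs along y, band by band, with the
    meridian layout of `_BAND_THETA`.  Vertices beyond the stacked
    bands are marked invalid and unlabeled.
    """
    layout = layout or BandLayout()
    stim = stim or StimulusParams()
    x = mesh.vertex_flat[:, 0]
    y = mesh.vertex_flat[:, 1]
    x0, width = x.min(), x.max() - x.min()
    if width <= 0:
        raise ParameterError("mesh has no extent along the eccentricity axis")
    ecc = stim.ecc_min_deg * np.exp(
        (x - x0) / width * np.log(stim.ecc_max_deg / stim.ecc_min_deg)
    )

    edges = layout.band_edges() + y.min()
    tol = 1e-9 * max(1.0, layout.total_height_mm)
    yy = np.minimum(y, edges[-1] - tol)  # top edge belongs to the last band
    band_idx = np.searchsorted(edges, yy, side="right") - 1
    valid = (y >= edges[0] - tol) & (y <= edges[-1] + tol)

    theta = np.full(mesh.n_vertices, np.nan)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    sign = np.zeros(mesh.n_vertices, dtype=int)
    for k, name in enumerate(BAND_ORDER):
        sel = valid & (band_idx == k)
        lo, hi = edges[k], edges[k + 1]
        t0, t1 = _BAND_THETA[name]
        frac = (y[sel] - lo) / (hi - lo)
        theta[sel] = t0 + frac * (t1 - t0)
        labels[sel] = AREA_CODES[name]
        sign[sel] = 1 if t1 > t0 else -1
    theta = np.clip(theta, -np.pi / 2, np.pi / 2)

    vf = VisualFieldMap(eccentricity=ecc, polar_angle=theta, valid=valid)
    vf.validate(stim.ecc_min_deg, stim.ecc_max_deg)
    truth = AreaLabeling(labels=labels, sign=sign, provenance="ground_truth")
    return vf, truth


def simulate_runs(
    truth: VisualFieldMap,
    stim: StimulusParams | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    drift_per_run: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, str], RunTimeSeries]:
    """The four phase-encoded runs as noisy sampled cosines.

    Forward runs (ring expansion / clockwise wedge):
        A * cos(2*pi*t/period - phi_coord - phi_h)
    Backward runs:
        A * cos(2*pi*t/period + phi_coord - phi_h)
    with phi_h = 2*pi*hemo_delay_s/period.  A linear drift ramp of total
    excursion ``drift_per_run`` and i.i.d. Gaussian noise of standard
    deviation ``noise_sd`` are added.  Invalid vertices carry drift and
    noise but no stimulus-locked signal.

    Returns a dict keyed by (coordinate, direction); same seed implies
    bit-identical output.
    """
    stim = stim or StimulusParams()
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    n = truth.eccentricity.shape[0]
    t = stim.times_s
    omega_t = 2.0 * np.pi * t / stim.period_s
    phi_h = 2.0 * np.pi * stim.hemo_delay_s / stim.period_s
    drift = drift_per_run * (t / stim.run_duration_s - 0.5)

    phases = {
        "eccentricity": coding.eccentricity_to_phase(truth.eccentricity, stim),
        "polar": coding.polar_to_phase(truth.polar_angle, stim),
    }
    rng = np.random.default_rng(seed)
    runs: dict[tuple[str, str], RunTimeSeries] = {}
    for coordinate in ("eccentricity", "polar"):
        phi = np.where(truth.valid, phases[coordinate], 0.0)
        amp = np.where(truth.valid, amplitude, 0.0)
        for direction, s in (("forward", -1.0), ("backward", +1.0)):
            signal = amp[:, None] * np.cos(
                omega_t[None, :] + s * phi[:, None] - phi_h
            )
            series = signal + drift[None, :]
            if noise_sd > 0:
                series = series + rng.normal(0.0, noise_sd, size=series.shape)
            runs[(coordinate, direction)] = RunTimeSeries(
                series=series,
                coordinate=coordinate,
                direction=direction,
                params=stim,
                locations=np.arange(n),
            )
    return runs


def noise_sd_for_snr(
    target_snr: float, amplitude: float = 1.0, stim: StimulusParams | None = None
) -> float:
    """White-noise standard deviation that yields a given expected SNR.

    Inverts the SNR statistic's white-noise expectation: a noise bin's
    scaled amplitude is Rayleigh with mean sd*sqrt(pi/N), so
    sd = amplitude * sqrt(N/pi) / target_snr.
    """
    stim = stim or StimulusParams()
    if target_snr <= 0:
        raise ParameterError("target_snr must be positive")
    return amplitude * np.sqrt(stim.n_volumes / np.pi) / target_snr


def rasterize_to_volume(
    mesh: SurfaceMesh,
    values: np.ndarray,
    voxel_size_mm: float = 3.0,
    circular: bool = False,
) -> VolumeGrid:
    """Voxelize a per-vertex payload onto an isotropic grid.

    Each voxel containing at least one vertex (half-open cells over the
    3-D coordinates) receives the mean of its vertices' values —
    circular (unit-phasor) mean for phases, arithmetic otherwise.
    Empty voxels are flagged invalid.  ``values`` may be (n,) or
    (n, T) for time series.
    """
    if voxel_size_mm <= 0:
        raise ParameterError("voxel_size_mm must be positive")
    values = np.asarray(values, dtype=float)
    if values.shape[0] != mesh.n_vertices:
        raise ParameterError("payload must be defined on mesh vertices")
    pts = mesh.vertex_xyz
    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / voxel_size_mm).astype(int)
    dims = tuple(idx.max(axis=0) + 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = origin + 0.5 * voxel_size_mm

    lin = np.ravel_multi_index(tuple(idx.T), dims)
    nvox = int(np.prod(dims))
    counts = np.bincount(lin, minlength=nvox).astype(float)
    valid = counts > 0

    def _mean(v: np.ndarray) -> np.ndarray:
        acc = np.bincount(lin, weights=v, minlength=nvox)
        with np.errstate(invalid="ignore"):
            return np.where(valid, acc / np.maximum(counts, 1), np.nan)

    trailing = values.shape[1:] if values.ndim > 1 else ()
    if circular:
        z = np.exp(1j * values)
        out = np.angle(_mean(z.real) + 1j * _mean(z.imag))
        out = np.where(valid, out, np.nan)
    elif trailing:
        cols = [_mean(values[:, k]) for k in range(values.shape[1])]
        out = np.stack(cols, axis=-1)
    else:
        out = _mean(values)
    out = out.reshape(dims + trailing)
    return VolumeGrid(
        dims=dims,
        voxel_size_mm=float(voxel_size_mm),
        affine=affine,
        values=out,
        valid=valid.reshape(dims),
    )


def make_activation_clusters(
    mesh: SurfaceMesh,
    labeling: AreaLabeling,
    n_clusters: int = 4,
    fraction_in_v4: float = 0.5,
    cluster_radius_mm: float = 3.0,
    seed: int = 0,
) -> ActivationMask:
    """Compact disc-shaped activation clusters in the ventral bands.

    ``round(fraction_in_v4 * n_clusters)`` clusters are placed wholly
    inside V4 and the rest wholly inside V2v/V3v, so the realized
    fraction of active vertices inside V4 is within one cluster's
    vertex count of the request.  Clusters are pairwise disjoint.
    """
    if not (0.0 <= fraction_in_v4 <= 1.0):
        raise ParameterError("fraction_in_v4 must lie in [0, 1]")
    if n_clusters < 1:
        raise ParameterError("need at least one cluster")
    if cluster_radius_mm <= 0:
        raise ParameterError("cluster_radius_mm must be positive")
    flat = mesh.vertex_flat
    tree = cKDTree(flat)
    in_v4 = labeling.labels == AREA_CODES["V4"]
    in_other_ventral = np.isin(
        labeling.labels, [AREA_CODES["V2v"], AREA_CODES["V3v"]]
    )
    if not in_v4.any() or not in_other_ventral.any():
        raise ParameterError("labeling must contain V4 and other ventral areas")

    # candidate centers whose whole disc stays inside the target region
    neighbor_lists = tree.query_ball_point(flat, cluster_radius_mm)

    def _pure_centers(region: np.ndarray) -> np.ndarray:
        cand = []
        for v in np.flatnonzero(region):
            nb = neighbor_lists[v]
            if region[nb].all():
                cand.append(v)
        return np.asarray(cand, dtype=int)

    k_v4 = int(round(fraction_in_v4 * n_clusters))
    rng = np.random.default_rng(seed)
    centers: list[int] = []
    min_sep = 2.0 * cluster_radius_mm + 1e-9
    for region, want in ((in_v4, k_v4), (in_other_ventral, n_clusters - k_v4)):
        if want == 0:
            continue
        cand = _pure_centers(region)
        rng.shuffle(cand)
        placed = 0
        for c in cand:
            if all(
                np.linalg.norm(flat[c] - flat[p]) > min_sep for p in centers
            ):
                centers.append(int(c))
                placed += 1
                if placed == want:
                    break
        if placed < want:
            raise ParameterError(
                f"cannot place {want} disjoint clusters of radius "
                f"{cluster_radius_mm} mm in the requested region"
            )

    members: list[np.ndarray] = []
    sizes: list[int] = []
    for c in centers:
        ids = np.asarray(sorted(neighbor_lists[c]), dtype=int)
        members.append(ids)
        sizes.append(ids.size)
    all_ids = np.unique(np.concatenate(members))
    mask = ActivationMask(
        member_ids=all_ids, space="surface", cluster_sizes=np.asarray(sizes)
    )
    mask.validate(mesh.n_vertices)
    return mask
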