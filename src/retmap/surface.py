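"""Volume <-> surface transfer and on-surface processing of phase maps.

Volume phase/SNR data are assigned to mesh vertices from nearby,
sufficiently reliable voxels (default: centers within 3 mm, SNR > 2);
phase fields are then smoothed on the surface with a Gaussian kernel
over flat-geodesic distances (default 2.5 mm, taken as sigma) and
decoded back into eccentricity / polar angle.  Labelings drawn on the
surface can be back-projected into the volume for export.

Phases are circular quantities: every combination is a weighted mean
of unit phasors, never of raw angles, so values near the wrap behave
correctly.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from . import coding
from .types import (
    AreaLabeling,
    ParameterError,
    PhaseSNRMap,
    StimulusParams,
    SurfaceMesh,
    VisualFieldMap,
    VolumeGrid,
    wrap_phase,
)

__all__ = [
    "assign_volume_phases_to_mesh",
    "SurfaceSmoother",
    "smooth_phase_on_surface",
    "decode_visual_coordinates",
    "project_labels_to_volume",
]


def _finite_snr(snr: np.ndarray) -> np.ndarray:
    """Replace infinite SNRs (noiseless data) by a finite weight.

    All-infinite inputs collapse to equal weights; mixed inputs cap the
    infinities at the largest finite value so they stay dominant
    without poisoning the weighted means.
    """
    snr = np.asarray(snr, dtype=float)
    if not np.any(np.isinf(snr)):
        return snr
    finite = snr[np.isfinite(snr)]
    cap = finite.max() if finite.size and finite.max() > 0 else 1.0
    return np.where(np.isinf(snr), cap, snr)


def assign_volume_phases_to_mesh(
    vol: PhaseSNRMap,
    mesh: SurfaceMesh,
    max_dist_mm: float = 3.0,
    snr_min: float = 2.0,
) -> PhaseSNRMap:
    """Assign volume phases to mesh vertices.

    Candidate voxels for a vertex have their center within
    ``max_dist_mm`` of the vertex (3-D coordinates) and SNR strictly
    greater than ``snr_min``.  The vertex phase is the argument of the
    candidates' unit-phasor mean weighted by snr times a triangular
    distance taper (1 - d/max_dist); the vertex SNR is the weighted
    mean of candidate SNRs.  Vertices with no candidates are undefined.
    """
    if vol.space != "volume" or vol.grid is None:
        raise ParameterError("input map must be in volume space with a grid")
    if max_dist_mm <= 0:
        raise ParameterError("max_dist_mm must be positive")
    grid = vol.grid
    centers = grid.voxel_centers_mm().reshape(-1, 3)
    phase = vol.phase.reshape(-1)
    snr = vol.snr.reshape(-1)
    defined = vol.defined.reshape(-1) & grid.valid.reshape(-1)
    usable = defined & (snr > snr_min)

    n = mesh.n_vertices
    out_phase = np.full(n, np.nan)
    out_amp = np.zeros(n)
    out_snr = np.zeros(n)
    out_def = np.zeros(n, dtype=bool)
    if usable.any():
        cand_idx = np.flatnonzero(usable)
        tree = cKDTree(centers[cand_idx])
        w_snr = _finite_snr(snr[cand_idx])
        amp = vol.amplitude.reshape(-1)[cand_idx]
        phasor = np.exp(1j * phase[cand_idx])
        for v in range(n):
            nb = tree.query_ball_point(mesh.vertex_xyz[v], max_dist_mm)
            if not nb:
                continue
            nb = np.asarray(nb)
            d = np.linalg.norm(centers[cand_idx[nb]] - mesh.vertex_xyz[v], axis=1)
            w = w_snr[nb] * (1.0 - d / max_dist_mm)
            wsum = w.sum()
            if wsum <= 0:
                continue
            out_phase[v] = np.angle(np.sum(w * phasor[nb]))
            out_snr[v] = float(np.sum(w * snr[cand_idx[nb]]) / wsum)
            out_amp[v] = float(np.sum(w * amp[nb]) / wsum)
            out_def[v] = True
    out = PhaseSNRMap(
        phase=wrap_phase(np.where(out_def, out_phase, np.nan)),
        amplitude=out_amp,
        snr=out_snr,
        coordinate=vol.coordinate,
        space="surface",
        defined=out_def,
    )
    out.validate()
    return out


class SurfaceSmoother:
    """Precomputed Gaussian smoothing weights on a mesh.

    Distances are geodesic in the flat embedding, approximated by
    shortest paths on the mesh edge graph; the kernel is
    exp(-d^2 / (2*kernel_mm^2)) truncated at 3*kernel_mm.  Building the
    sparse weight matrix is the expensive part, so one smoother can be
    reused across many maps on the same mesh.
    """

    def __init__(self, mesh: SurfaceMesh, kernel_mm: float = 2.5):
        if kernel_mm <= 0:
            raise ParameterError("kernel_mm must be positive")
        self.kernel_mm = float(kernel_mm)
        n = mesh.n_vertices
        edges = mesh.edge_list()
        lengths = np.linalg.norm(
            mesh.vertex_flat[edges[:, 0]] - mesh.vertex_flat[edges[:, 1]], axis=1
        )
        graph = sparse.csr_matrix(
            (
                np.concatenate([lengths, lengths]),
                (
                    np.concatenate([edges[:, 0], edges[:, 1]]),
                    np.concatenate([edges[:, 1], edges[:, 0]]),
                ),
            ),
            shape=(n, n),
        )
        limit = 3.0 * self.kernel_mm
        rows, cols, w = [], [], []
        chunk = 512
        for start in range(0, n, chunk):
            idx = np.arange(start, min(start + chunk, n))
            d = dijkstra(graph, directed=False, indices=idx, limit=limit)
            r, c = np.nonzero(np.isfinite(d))
            rows.append(idx[r])
            cols.append(c)
            w.append(np.exp(-d[r, c] ** 2 / (2.0 * self.kernel_mm**2)))
        self.weights = sparse.csr_matrix(
            (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )

    def smooth_map(self, m: PhaseSNRMap) -> PhaseSNRMap:
        snr_w = np.where(m.defined, _finite_snr(m.snr), 0.0)
        phasor = np.where(m.defined, np.exp(1j * np.nan_to_num(m.phase)), 0.0)
        num = self.weights @ (snr_w * phasor)
        den = self.weights @ snr_w
        defined = den > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            phase = np.where(defined, np.angle(num), np.nan)
            snr_num = self.weights @ (snr_w * np.where(m.defined, m.snr, 0.0))
            snr_out = np.where(defined, snr_num / np.where(defined, den, 1.0), 0.0)
            amp_num = self.weights @ (snr_w * np.where(m.defined, m.amplitude, 0.0))
            amp_out = np.where(defined, amp_num / np.where(defined, den, 1.0), 0.0)
        out = PhaseSNRMap(
            phase=wrap_phase(np.where(defined, phase, np.nan)),
            amplitude=amp_out,
            snr=snr_out,
            coordinate=m.coordinate,
            space="surface",
            defined=defined,
        )
        out.validate()
        return out


def smooth_phase_on_surface(
    m: PhaseSNRMap,
    mesh: SurfaceMesh,
    kernel_mm: float = 2.5,
    smoother: SurfaceSmoother | None = None,
) -> PhaseSNRMap:
    """Gaussian-weighted circular smoothing of a surface phase map.

    Per vertex, the circular mean of neighbors' phases within
    3*kernel_mm flat-geodesic distance, Gaussian distance weights times
    each neighbor's SNR; undefined neighbors are excluded.  The SNR
    field is smoothed with the same weights.  Pass a prebuilt
    :class:`SurfaceSmoother` to amortize the distance computation.
    """
    if m.space != "surface":
        raise ParameterError("smoothing operates on surface maps")
    if smoother is None:
        smoother = SurfaceSmoother(mesh, kernel_mm)
    return smoother.smooth_map(m)


def decode_visual_coordinates(
    ecc_map: PhaseSNRMap,
    pol_map: PhaseSNRMap,
    stim: StimulusParams | None = None,
) -> VisualFieldMap:
    """Decode stimulus phases into eccentricity and polar angle.

    Phases are unwrapped to [0, 2*pi) (the stimulus sweeps each
    coordinate exactly once per cycle, so the mapping is injective);
    eccentricity follows the exponential law, polar angle the linear
    hemifield law.  Valid only where both phases are defined.
    """
    stim = stim or StimulusParams()
    if ecc_map.phase.shape != pol_map.phase.shape:
        raise ParameterError("eccentricity and polar maps must share the mesh")
    valid = ecc_map.defined & pol_map.defined
    ecc = np.where(
        valid, coding.phase_to_eccentricity(np.nan_to_num(ecc_map.phase), stim), np.nan
    )
    theta = np.where(
        valid, coding.phase_to_polar(np.nan_to_num(pol_map.phase), stim), np.nan
    )
    return VisualFieldMap(eccentricity=ecc, polar_angle=theta, valid=valid)


def project_labels_to_volume(
    labeling: AreaLabeling,
    mesh: SurfaceMesh,
    grid: VolumeGrid,
    max_dist_mm: float = 3.0,
) -> VolumeGrid:
    """Back-project surface labels into a voxel grid.

    Every voxel whose center lies within ``max_dist_mm`` of a labeled
    vertex receives the label of its nearest labeled vertex; distance
    ties go to the smaller label code.  Other voxels stay unlabeled (0).
    """
    labeled = np.flatnonzero(labeling.labels > 0)
    out = np.zeros(grid.dims, dtype=int)
    valid = np.zeros(grid.dims, dtype=bool)
    if labeled.size:
        centers = grid.voxel_centers_mm().reshape(-1, 3)
        tree = cKDTree(mesh.vertex_xyz[labeled])
        k = min(8, labeled.size)
        d, nn = tree.query(centers, k=k)
        d = np.atleast_2d(d.T).T
        nn = np.atleast_2d(nn.T).T
        within = d[:, 0] <= max_dist_mm
        codes = labeling.labels[labeled[nn]]
        # among neighbors tied with the closest (within 1e-9), smallest code
        tied = d <= d[:, [0]] + 1e-9
        codes_tied = np.where(tied, codes, np.iinfo(int).max)
        chosen = codes_tied.min(axis=1)
        flat_out = np.where(within, chosen, 0)
        out = flat_out.reshape(grid.dims)
        valid = within.reshape(grid.dims)
    return VolumeGrid(
        dims=grid.dims,
        voxel_size_mm=grid.voxel_size_mm,
        affine=grid.affine.copy(),
        values=out,
        valid=valid,
    )
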