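"""Core data containers for phase-encoded retinotopic mapping.

The pipeline moves data between three spaces: a triangulated cortical
patch (`SurfaceMesh`, with both a 3-D and a flat 2-D embedding), a voxel
grid (`VolumeGrid`), and the visual field itself (`VisualFieldMap`,
eccentricity/polar-angle per vertex).  Per-location responses at the
stimulation frequency live in `PhaseSNRMap`; per-triangle field-sign
information in `FieldSignMap`; per-vertex visual-area assignments in
`AreaLabeling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ParameterError",
    "AREA_CODES",
    "AREA_NAMES",
    "BAND_ORDER",
    "SurfaceMesh",
    "VisualFieldMap",
    "StimulusParams",
    "RunTimeSeries",
    "VolumeGrid",
    "ActivationMask",
    "PhaseSNRMap",
    "FieldSignMap",
    "AreaLabeling",
    "wrap_phase",
]


class ParameterError(ValueError):
    """Raised when an operation's parameters violate its preconditions."""


#: Integer codes for visual-area labels. 0 is "no label".
AREA_CODES: dict[str, int] = {
    "none": 0,
    "V1": 1,
    "V2d": 2,
    "V2v": 3,
    "V3d": 4,
    "V3v": 5,
    "V4": 6,
}
AREA_NAMES: dict[int, str] = {v: k for k, v in AREA_CODES.items()}

#: Order of the cortical bands along the flat y axis (dorsal to ventral).
BAND_ORDER: tuple[str, ...] = ("V3d", "V2d", "V1", "V2v", "V3v", "V4")


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class SurfaceMesh:
    """Triangulated cortical patch with a flat 2-D embedding.

    The flat coordinates are authoritative for all intrinsic geometry
    (distances, areas, the field-sign Jacobian); the 3-D coordinates are
    what volume data are matched against.
    """

    vertex_xyz: np.ndarray  # (n, 3) float, mm
    vertex_flat: np.ndarray  # (n, 2) float, mm
    faces: np.ndarray  # (m, 3) int
    hemisphere: Literal["left", "right"] = "left"

    @property
    def n_vertices(self) -> int:
        return self.vertex_xyz.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self) -> None:
        n = self.n_vertices
        if self.vertex_xyz.shape != (n, 3) or self.vertex_flat.shape != (n, 2):
            raise ParameterError("inconsistent vertex array shapes")
        f = self.faces
        if f.ndim != 2 or f.shape[1] != 3:
            raise ParameterError("faces must be (m, 3)")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= n:
            raise ParameterError("face vertex index out of range")
        if np.any(f[:, 0] == f[:, 1]) or np.any(f[:, 1] == f[:, 2]) or np.any(f[:, 0] == f[:, 2]):
            raise ParameterError("degenerate face with repeated vertex")
        if np.any(np.abs(self.flat_signed_areas()) < 1e-12):
            raise ParameterError("zero-area triangle in the flat embedding")
        # manifold patch: every edge shared by at most 2 faces
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise ParameterError("non-manifold edge (shared by >2 faces)")

    def flat_signed_areas(self) -> np.ndarray:
        """Signed area of every triangle in the flat embedding (mm^2)."""
        p = self.vertex_flat[self.faces]
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])

    def edge_list(self) -> np.ndarray:
        """Unique undirected edges, (k, 2) sorted vertex index pairs."""
        f = self.faces
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        return np.unique(edges, axis=0)


@dataclass
class VisualFieldMap:
    """Per-vertex visual-field coordinates.

    ``polar_angle`` covers the contralateral hemifield of one hemisphere:
    0 is the horizontal meridian and the sign distinguishes the dorsal
    (negative, lower field) from the ventral (positive, upper field)
    representation, so valid values lie in [-pi/2, +pi/2].
    """

    eccentricity: np.ndarray  # (n,) deg
    polar_angle: np.ndarray  # (n,) rad
    valid: np.ndarray  # (n,) bool

    def validate(self, ecc_min: float, ecc_max: float, rtol: float = 1e-9) -> None:
        v = self.valid
        ecc = self.eccentricity[v]
        if ecc.size and (
            ecc.min() < ecc_min * (1 - rtol) - rtol or ecc.max() > ecc_max * (1 + rtol) + rtol
        ):
            raise ParameterError("eccentricity outside stimulus range where valid")
        th = self.polar_angle[v]
        if th.size and (th.min() < -np.pi / 2 - 1e-9 or th.max() > np.pi / 2 + 1e-9):
            raise ParameterError("polar angle outside hemifield where valid")


@dataclass(frozen=True)
class StimulusParams:
    """Timing and geometry of the periodic retinotopic stimulation.

    Defaults: 32 s period sampled at TR 2 s for 224 volumes (14 whole
    cycles), rings sweeping 0.2-3.0 deg of eccentricity, two wedges
    180 deg apart, and a 5 s hemodynamic delay in the simulator.
    """

    period_s: float = 32.0
    tr_s: float = 2.0
    n_volumes: int = 224
    ecc_min_deg: float = 0.2
    ecc_max_deg: float = 3.0
    n_wedges: int = 2
    hemo_delay_s: float = 5.0

    def __post_init__(self) -> None:
        if self.period_s <= 0 or self.tr_s <= 0:
            raise ParameterError("period_s and tr_s must be positive")
        if self.n_volumes < 2 * self.period_s / self.tr_s:
            raise ParameterError("need at least two stimulation cycles per run")
        if not (0 < self.ecc_min_deg < self.ecc_max_deg):
            raise ParameterError("need 0 < ecc_min_deg < ecc_max_deg")

    @property
    def stim_frequency_hz(self) -> float:
        return 1.0 / self.period_s

    @property
    def run_duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def cycles_per_run(self) -> float:
        return self.run_duration_s / self.period_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass
class RunTimeSeries:
    """BOLD-like time series for one phase-encoded run.

    ``series`` is (n_locations, n_volumes); ``locations`` indexes into
    whatever space the run lives in (mesh vertices or flattened voxels).
    """

    series: np.ndarray
    coordinate: Literal["eccentricity", "polar"]
    direction: Literal["forward", "backward", "combined"]
    params: StimulusParams
    locations: np.ndarray | None = None

    def validate(self) -> None:
        if self.series.ndim != 2 or self.series.shape[1] != self.params.n_volumes:
            raise ParameterError("series must be (n_locations, n_volumes)")


@dataclass
class VolumeGrid:
    """Axis-aligned voxel grid with an invertible voxel-to-mm affine.

    ``values`` has shape ``dims`` (+ optional trailing axes, e.g. time);
    ``valid`` flags voxels that actually carry data.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: float
    affine: np.ndarray  # (4, 4)
    values: np.ndarray
    valid: np.ndarray  # bool, shape dims

    def voxel_centers_mm(self) -> np.ndarray:
        """mm coordinates of every voxel center, shape dims + (3,)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(d) for d in self.dims], indexing="ij"), axis=-1
        ).astype(float)
        homo = np.concatenate([idx, np.ones(idx.shape[:-1] + (1,))], axis=-1)
        return homo @ self.affine.T[:, :3]

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map mm positions to integer voxel indices (half-open cells)."""
        inv = np.linalg.inv(self.affine)
        homo = np.concatenate(
            [points_mm, np.ones(points_mm.shape[:-1] + (1,))], axis=-1
        )
        # affine maps index -> cell center, so the cell is [i-0.5, i+0.5)
        return np.floor(homo @ inv.T[:, :3] + 0.5).astype(int)


@dataclass
class ActivationMask:
    """Set of active voxel or vertex indices (e.g. a color-responsive cluster)."""

    member_ids: np.ndarray  # (k,) int, unique
    space: Literal["volume", "surface"]
    cluster_sizes: np.ndarray | None = None  # per-cluster vertex counts

    def validate(self, n_total: int) -> None:
        ids = self.member_ids
        if ids.size != np.unique(ids).size:
            raise ParameterError("activation member ids must be unique")
        if ids.size and (ids.min() < 0 or ids.max() >= n_total):
            raise ParameterError("activation member id out of range")


@dataclass
class PhaseSNRMap:
    """Phase and signal-to-noise ratio at the stimulation frequency.

    Phases are wrapped to [-pi, pi).  ``defined`` is False where no
    response could be measured (zero amplitude, no candidate voxels, or
    an unresolved delay branch); phase is NaN there.  In volume space
    the arrays are flattened over ``grid.dims`` in C order.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    snr: np.ndarray
    coordinate: Literal["eccentricity", "polar"]
    space: Literal["volume", "surface"]
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]
    grid: "VolumeGrid | None" = None

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = np.isfinite(self.phase)

    def validate(self) -> None:
        d = self.defined
        ph = self.phase[d]
        if ph.size and (ph.min() < -np.pi or ph.max() >= np.pi):
            raise ParameterError("phase not wrapped to [-pi, pi)")
        if np.any(self.snr[d] < 0):
            raise ParameterError("snr must be non-negative")


@dataclass
class FieldSignMap:
    """Per-triangle Visual Field Ratio (discrete Jacobian) and its sign."""

    vfr: np.ndarray  # (m,) float
    sign: np.ndarray  # (m,) int in {-1, 0, +1}
    defined: np.ndarray  # (m,) bool


@dataclass
class AreaLabeling:
    """Per-vertex visual-area labels and field signs.

    ``labels`` holds `AREA_CODES` values; ``sign`` is the field sign of
    the labeled vertex (0 where unlabeled).
    """

    labels: np.ndarray  # (n,) int
    sign: np.ndarray  # (n,) int
    provenance: Literal["ground_truth", "automatic", "perturbed"]

    def vertices_of(self, area: str | int) -> np.ndarray:
        code = AREA_CODES[area] if isinstance(area, str) else int(area)
        return np.flatnonzero(self.labels == code)

    def present_areas(self) -> list[str]:
        return [a for a in BAND_ORDER if np.any(self.labels == AREA_CODES[a])]

    def copy(self) -> "AreaLabeling":
        return replace(self, labels=self.labels.copy(), sign=self.sign.copy())


@dataclass
class OverlapReport:
    """Per-area agreement scores across cases, with summary moments.

    ``scores[area]`` is one value per case, NaN where the area was
    missing from both labelings of that case (reported as missing, the
    way unavailable areas appear as reduced n in group tables).
    """

    scores: dict[str, np.ndarray]
    space: Literal["surface", "volume"] = "surface"

    def mean_per_area(self) -> dict[str, float]:
        return {a: float(np.nanmean(s)) if np.any(np.isfinite(s)) else float("nan")
                for a, s in self.scores.items()}

    def sd_per_area(self) -> dict[str, float]:
        out = {}
        for a, s in self.scores.items():
            v = s[np.isfinite(s)]
            out[a] = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
        return out

    def grand_mean(self) -> float:
        allv = np.concatenate([s[np.isfinite(s)] for s in self.scores.values()])
        return float(allv.mean()) if allv.size else float("nan")
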