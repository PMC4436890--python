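"""Pipeline configuration.

One structured YAML file drives the whole pipeline.  Every constant of
the method is a named, defaulted field: stimulation timing (32 s
period, TR 2 s, 224 volumes, 0.2-3.0 deg rings, two wedges), the
volume-to-surface assignment rules (3 mm, SNR > 2), the delineation
thresholds (SNR > 3, 0.2-3.0 deg eccentricity window, 2.5 mm smoothing
kernel) and the simulator's noise model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synth import BandLayout
from .types import ParameterError, StimulusParams

__all__ = ["PipelineConfig", "load_config", "save_config"]

_METHODS = ("phase-combine", "reverse-average", "correlation")


@dataclass
class PipelineConfig:
    # stimulus / acquisition
    period_s: float = 32.0
    tr_s: float = 2.0
    n_volumes: int = 224
    ecc_min_deg: float = 0.2
    ecc_max_deg: float = 3.0
    n_wedges: int = 2
    hemo_delay_s: float = 5.0
    # mesh geometry
    patch_width_mm: float = 60.0
    patch_height_mm: float | None = None  # default: total band height
    spacing_mm: float = 1.0
    hemisphere: str = "left"
    band_widths_mm: dict[str, float] = field(
        default_factory=lambda: dict(BandLayout().band_widths_mm)
    )
    # simulation
    amplitude: float = 1.0
    noise_sd: float = 0.0
    drift_per_run: float = 0.0
    seed: int = 0
    # activation clusters
    n_clusters: int = 4
    fraction_in_v4: float = 0.5
    cluster_radius_mm: float = 3.0
    # analysis
    method: str = "phase-combine"
    detrend_cutoff_cycles: float = 2.0
    voxel_size_mm: float = 3.0
    # projection / delineation thresholds
    max_dist_mm: float = 3.0
    snr_assign: float = 2.0
    snr_delineate: float = 3.0
    kernel_mm: float = 2.5
    vfr_tol: float = 0.02
    ecc_bounds: tuple[float, float] = (0.2, 3.0)
    # evaluation
    boundary_shift_mm: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.method not in _METHODS:
            raise ParameterError(f"method must be one of {_METHODS}")
        for name in (
            "max_dist_mm",
            "snr_assign",
            "snr_delineate",
            "kernel_mm",
            "vfr_tol",
            "voxel_size_mm",
            "spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.noise_sd < 0 or self.boundary_shift_mm < 0:
            raise ParameterError("noise_sd and boundary_shift_mm must be >= 0")
        lo, hi = self.ecc_bounds
        if not (0 < lo < hi):
            raise ParameterError("ecc_bounds must satisfy 0 < lo < hi")
        self.stimulus()  # raises on invalid timing
        self.layout()

    def stimulus(self) -> StimulusParams:
        return StimulusParams(
            period_s=self.period_s,
            tr_s=self.tr_s,
            n_volumes=self.n_volumes,
            ecc_min_deg=self.ecc_min_deg,
            ecc_max_deg=self.ecc_max_deg,
            n_wedges=self.n_wedges,
            hemo_delay_s=self.hemo_delay_s,
        )

    def layout(self) -> BandLayout:
        return BandLayout(band_widths_mm=dict(self.band_widths_mm))

    @property
    def height_mm(self) -> float:
        return (
            self.patch_height_mm
            if self.patch_height_mm is not None
            else self.layout().total_height_mm
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ecc_bounds"] = list(self.ecc_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ecc_bounds" in d:
            d["ecc_bounds"] = tuple(d["ecc_bounds"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
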