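"""Shared fixtures: the default synthetic study, computed once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retmap import fieldsign, phase, surface, synth
from retmap.types import StimulusParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stim() -> StimulusParams:
    return StimulusParams()


@pytest.fixture(scope="session")
def default_mesh():
    return synth.build_flat_patch(60.0, 62.0, 1.0)


@pytest.fixture(scope="session")
def ground_truth(default_mesh, stim):
    """(VisualFieldMap, AreaLabeling) for the default layout."""
    return synth.synthesize_ground_truth(default_mesh, None, stim)


@pytest.fixture(scope="session")
def smoother(default_mesh):
    return surface.SurfaceSmoother(default_mesh, 2.5)


@pytest.fixture(scope="session")
def small_mesh():
    """36-vertex patch for brute-force oracle comparisons."""
    return synth.build_flat_patch(10.0, 10.0, 2.0)


def delineate_from_runs(mesh, runs, stim, smoother):
    """Full surface-route delineation: dft -> combine -> smooth -> decode
    -> VFR -> label.  Returns (labeling, maps, decoded field, field-sign map)."""
    maps = {}
    for coord in ("eccentricity", "polar"):
        mf = phase.dft_phase_snr(runs[(coord, "forward")])
        mb = phase.dft_phase_snr(runs[(coord, "backward")])
        combined, _ = phase.combine_opposite_directions(mf, mb, stim.period_s)
        maps[coord] = smoother.smooth_map(combined)
    decoded = surface.decode_visual_coordinates(
        maps["eccentricity"], maps["polar"], stim
    )
    fsm = fieldsign.compute_vfr(mesh, decoded)
    labeling = fieldsign.label_areas(
        mesh, fsm, maps["eccentricity"], maps["polar"], decoded
    )
    return labeling, maps, decoded, fsm


@pytest.fixture(scope="session")
def noiseless_runs(ground_truth, stim):
    vf, _ = ground_truth
    return synth.simulate_runs(vf, stim, seed=1)


@pytest.fixture(scope="session")
def noiseless_delineation(default_mesh, noiseless_runs, stim, smoother):
    return delineate_from_runs(default_mesh, noiseless_runs, stim, smoother)


def route_phases(runs, coord, stim):
    """Stimulus-phase maps from both delay-cancellation routes.

    Returns (phase-combination map, reverse-average map) as PhaseSNRMaps
    with the documented time-reversal offset already removed from the
    reverse-average route.
    """
    fwd, bwd = runs[(coord, "forward")], runs[(coord, "backward")]
    mf = phase.dft_phase_snr(fwd)
    mb = phase.dft_phase_snr(bwd)
    m1, _ = phase.combine_opposite_directions(mf, mb, stim.period_s)
    combined, offset = phase.reverse_average_combine(fwd, bwd)
    mc = phase.dft_phase_snr(combined)
    p2 = phase.stimulus_phase_from_reverse_average(mc, offset)
    m2 = dataclasses.replace(mc, phase=np.where(mc.defined, p2, np.nan))
    return m1, m2
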