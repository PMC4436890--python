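"""Stimulus phase coding: visual-field coordinates <-> response phase.

The periodic stimuli convert position in the visual field into the
temporal phase of the BOLD response.  The expanding/contracting ring
moves so that the cortical activation wave travels at constant speed
under an exponential magnification factor, i.e. the ring's eccentricity
grows exponentially in time; response phase is therefore proportional
to log-eccentricity.  Polar angle is encoded by two wedges 180 deg
apart, so within one hemisphere (one contralateral hemifield) a single
response cycle corresponds to a 180 deg wedge sweep and phase maps
linearly onto the hemifield [-pi/2, +pi/2].

Both encodings sweep their coordinate exactly once per cycle, so phases
map injectively onto [0, 2*pi) and the coding is exactly invertible.
"""

from __future__ import annotations

import numpy as np

from .types import StimulusParams

__all__ = [
    "eccentricity_to_phase",
    "phase_to_eccentricity",
    "polar_to_phase",
    "phase_to_polar",
]


def eccentricity_to_phase(ecc_deg: np.ndarray | float, stim: StimulusParams) -> np.ndarray:
    """Stimulus phase in [0, 2*pi] for an eccentricity in degrees.

    phi = 2*pi * ln(ecc / ecc_min) / ln(ecc_max / ecc_min)
    """
    ecc = np.asarray(ecc_deg, dtype=float)
    span = np.log(stim.ecc_max_deg / stim.ecc_min_deg)
    return 2.0 * np.pi * np.log(ecc / stim.ecc_min_deg) / span


def phase_to_eccentricity(phi: np.ndarray | float, stim: StimulusParams) -> np.ndarray:
    """Inverse of :func:`eccentricity_to_phase`; phi taken modulo 2*pi."""
    phi = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
    span = np.log(stim.ecc_max_deg / stim.ecc_min_deg)
    return stim.ecc_min_deg * np.exp(phi / (2.0 * np.pi) * span)


def polar_to_phase(theta_rad: np.ndarray | float, stim: StimulusParams) -> np.ndarray:
    """Stimulus phase in [0, 2*pi] for a hemifield polar angle.

    phi = 2*pi * (theta + pi/2) / pi  — one response cycle per 180 deg
    wedge sweep (two wedges with a 180 deg lag).
    """
    theta = np.asarray(theta_rad, dtype=float)
    hemifield_span = np.pi * 2.0 / stim.n_wedges
    return 2.0 * np.pi * (theta + np.pi / 2.0) / hemifield_span


def phase_to_polar(phi: np.ndarray | float, stim: StimulusParams) -> np.ndarray:
    """Inverse of :func:`polar_to_phase`; phi taken modulo 2*pi."""
    phi = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
    hemifield_span = np.pi * 2.0 / stim.n_wedges
    return -np.pi / 2.0 + phi / (2.0 * np.pi) * hemifield_span
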