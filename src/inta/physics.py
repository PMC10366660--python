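"""Stokes-Einstein relation, shared by the simulator and the estimator.

Keeping the diffusion<->diameter mapping in one place guarantees that the
synthetic-data generator and the analysis pipeline agree exactly on
D = k_B T / (3 pi eta d).
"""

from __future__ import annotations

import numpy as np

from .config import OpticalConfig

BOLTZMANN_J_PER_K = 1.380649e-23

__all__ = ["diffusion_from_diameter", "diameter_from_diffusion", "BOLTZMANN_J_PER_K"]


def diffusion_from_diameter(diameter_nm, optics: OpticalConfig):
    """Stokes-Einstein diffusion constant in um^2/s for a diameter in nm."""
    d = np.asarray(diameter_nm, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("diameter must be finite and positive")
    d_m = d * 1e-9
    D_m2s = BOLTZMANN_J_PER_K * optics.temperature_K / (
        3.0 * np.pi * optics.viscosity_Pa_s * d_m
    )
    return D_m2s * 1e12  # m^2/s -> um^2/s


def diameter_from_diffusion(diffusion_um2_s, optics: OpticalConfig):
    """Hydrodynamic diameter in nm from a diffusion constant in um^2/s.

    The relation is self-inverse: ``d = k_B T / (3 pi eta D)``.
    """
    D = np.asarray(diffusion_um2_s, dtype=float)
    if np.any(~np.isfinite(D)) or np.any(D <= 0):
        raise ValueError("diffusion constant must be finite and positive")
    D_m2s = D * 1e-12
    d_m = BOLTZMANN_J_PER_K * optics.temperature_K / (
        3.0 * np.pi * optics.viscosity_Pa_s * D_m2s
    )
    return d_m * 1e9
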