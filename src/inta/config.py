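"""Configuration objects shared across the pipeline.

Every stage of the analysis (simulation, detection, estimation,
classification, quantification) reads its parameters from the dataclasses
defined here.  A :class:`PipelineConfig` can be loaded from a TOML file with
``[optics]``, ``[instrument]``, ``[calibration]``, ``[estimation]``,
``[detection]``, ``[classifier]`` and ``[quantification]`` blocks; missing
keys fall back to the documented defaults.  Output files embed
:func:`config_hash` so that results are traceable to the exact settings that
produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "OpticalConfig",
    "InstrumentSpec",
    "ContrastCalibration",
    "EstimationConfig",
    "DetectionConfig",
    "ClassifierConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented constraint."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and fluid context of a measurement.

    Parameters
    ----------
    wavelength_nm:
        Vacuum illumination wavelength. Default 525 nm, a standard green
        iSCAT line; it only shifts the contrast-to-cross-section calibration,
        which is itself configurable.
    medium_ri:
        Refractive index of the suspension medium (aqueous buffer, 1.33).
    temperature_K:
        Fluid temperature entering the Stokes-Einstein relation.
    viscosity_Pa_s:
        Dynamic viscosity of the medium (water at 25 C, 8.9e-4 Pa s).
    """

    wavelength_nm: float = 525.0
    medium_ri: float = 1.33
    temperature_K: float = 298.15
    viscosity_Pa_s: float = 8.9e-4

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ConfigError("wavelength_nm must be positive")
        if self.medium_ri < 1:
            raise ConfigError("medium_ri must be >= 1")
        if not self.temperature_K > 0:
            raise ConfigError("temperature_K must be positive")
        if not self.viscosity_Pa_s > 0:
            raise ConfigError("viscosity_Pa_s must be positive")

    @property
    def wavelength_medium_nm(self) -> float:
        """Wavelength inside the medium, lambda / n_m."""
        return self.wavelength_nm / self.medium_ri


@dataclass(frozen=True)
class InstrumentSpec:
    """Acquisition geometry and timing of the tracking instrument.

    ``fov_side_um`` matches the 7.1 um x 7.1 um field of view of the
    measurements the simulator emulates; ``frame_rate_hz`` the 5 kHz
    acquisition.  ``focal_depth_um`` is the axial slab (centred on focus)
    within which a particle is considered detectable; particles leaving it
    terminate their trajectory.  ``min_localizations`` is the
    keep-trajectories-longer-than filter (strictly greater than).
    ``contrast_noise_sd`` is the additive per-frame contrast noise of the
    simulator and the default noise used by the RI-precision simulation.
    """

    frame_rate_hz: float = 5000.0
    fov_side_um: float = 7.1
    focal_depth_um: float = 2.0
    min_localizations: int = 100
    contrast_noise_sd: float = 2.0e-3
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ConfigError("frame_rate_hz must be positive")
        if not self.fov_side_um > 0:
            raise ConfigError("fov_side_um must be positive")
        if not self.focal_depth_um > 0:
            raise ConfigError("focal_depth_um must be positive")
        if self.min_localizations < 1:
            raise ConfigError("min_localizations must be >= 1")
        if self.contrast_noise_sd < 0:
            raise ConfigError("contrast_noise_sd must be >= 0")
        if self.duration_s < 0:
            raise ConfigError("duration_s must be >= 0")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def detection_volume_ml(self) -> float:
        """Observation volume FOV^2 x focal depth, in mL (1 um^3 = 1e-12 uL)."""
        vol_um3 = self.fov_side_um**2 * self.focal_depth_um
        return vol_um3 * 1e-12 * 1e-3  # um^3 -> uL -> mL


@dataclass(frozen=True)
class ContrastCalibration:
    """Instrument calibration linking iSCAT contrast to scattering.

    The measured contrast of a particle is modelled as ``C = A * sqrt(sigma)``
    with ``sigma`` the scattering cross-section in nm^2; ``amplitude`` is A in
    contrast per sqrt(nm^2).  The default gives ~1e-2 contrast for a 100 nm
    vesicle, typical of iSCAT recordings.
    """

    amplitude: float = 5.0e-3

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ConfigError("calibration amplitude must be positive")

    def contrast_from_sigma(self, sigma_nm2):
        import numpy as np

        return self.amplitude * np.sqrt(sigma_nm2)

    def sigma_from_contrast(self, contrast):
        """Invert C = A sqrt(sigma); negative contrast maps to sigma = 0."""
        import numpy as np

        c = np.clip(np.asarray(contrast, dtype=float), 0.0, None)
        return (c / self.amplitude) ** 2


@dataclass(frozen=True)
class EstimationConfig:
    """Per-particle estimation settings.

    ``iqr_s_cutoff`` is the RI precision gate: particles whose simulated RI
    interquartile range exceeds it are excluded from population RI medians.
    ``noise_from_trajectory`` switches the precision simulation between the
    configured contrast noise and the per-trajectory empirical contrast sd.
    """

    iqr_s_cutoff: float = 0.05
    n_precision_sims: int = 200
    ri_bracket_max: float = 2.5
    noise_from_trajectory: bool = False

    def __post_init__(self) -> None:
        if self.n_precision_sims < 100:
            raise ConfigError("n_precision_sims must be >= 100")
        if not self.iqr_s_cutoff > 0:
            raise ConfigError("iqr_s_cutoff must be positive")


@dataclass(frozen=True)
class DetectionConfig:
    """Frame-level detection and linking settings."""

    pixel_size_um: float = 0.055
    median_window: int = 11
    median_guard: int = 0
    background_mode: str = "subtract"
    rvt_rmin_px: int = 1
    rvt_rmax_px: int = 6
    detect_snr: float = 8.0
    max_disp_px: float | None = None
    link_memory: int = 3
    min_localizations: int = 100

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ConfigError("median_window must be odd and >= 3")
        if self.background_mode not in ("subtract", "divide"):
            raise ConfigError("background_mode must be 'subtract' or 'divide'")
        if not 0 <= self.rvt_rmin_px < self.rvt_rmax_px:
            raise ConfigError("require 0 <= rvt_rmin_px < rvt_rmax_px")


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest hyperparameters and the confidence threshold."""

    n_trees: int = 200
    max_depth: int | None = None
    confidence_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.5 < self.confidence_threshold < 1:
            raise ConfigError("confidence_threshold must lie in (0.5, 1)")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of all configuration blocks plus the global seed."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    instrument: InstrumentSpec = field(default_factory=InstrumentSpec)
    calibration: ContrastCalibration = field(default_factory=ContrastCalibration)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCKS = {
    "optics": OpticalConfig,
    "instrument": InstrumentSpec,
    "calibration": ContrastCalibration,
    "estimation": EstimationConfig,
    "detection": DetectionConfig,
    "classifier": ClassifierConfig,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a TOML file.

    Unknown keys raise :class:`ConfigError` so typos do not silently fall
    back to defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs: dict = {}
    for block, cls in _BLOCKS.items():
        values = raw.pop(block, {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - names
        if unknown:
            raise ConfigError(f"unknown keys in [{block}]: {sorted(unknown)}")
        kwargs[block] = cls(**values)
    seed = raw.pop("seed", 0)
    if raw:
        raise ConfigError(f"unknown top-level config blocks: {sorted(raw)}")
    return PipelineConfig(seed=int(seed), **kwargs)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of a configuration, embedded in every output."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
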