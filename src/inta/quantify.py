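"""Concentration quantification and plasma back-calculation.

Trajectory counts are converted to particles/mL through a calibration
factor fitted on a dilution series of beads of known concentration (a
through-origin least-squares line of concentration against trajectories per
10 minutes).  Measured EV concentrations in enriched samples are mapped
back to the original plasma concentration by undoing the enrichment:

    original = measured / (recovery_rate * V_plasma / V_final)

Recovery presets ship for the three enrichment protocols used with plasma
EV samples: size-exclusion chromatography (SEC, 80% recovery, 0.5 mL plasma
concentrated to 0.1 mL), dual-mode chromatography (DMC, 33%, 0.5 -> 0.1 mL)
and density-gradient separation (DG, 25%, 6 -> 0.1 mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConcentrationCalibration",
    "RecoverySpec",
    "SampleQuantification",
    "RECOVERY_PRESETS",
    "fit_concentration_calibration",
    "trajectories_to_concentration",
    "back_calculate_plasma_concentration",
    "round_sig",
]

REFERENCE_DURATION_S = 600.0  # counts are normalized to a 10-minute recording


@dataclass(frozen=True)
class ConcentrationCalibration:
    """Calibration factor: particles/mL per (trajectories / 10 min)."""

    factor: float
    reference: str = ""
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("calibration factor must be positive")


@dataclass(frozen=True)
class RecoverySpec:
    """EV-enrichment protocol metadata for back-calculation."""

    method: str
    recovery_rate: float
    plasma_volume_ml: float
    final_volume_ml: float

    def __post_init__(self) -> None:
        if not 0 < self.recovery_rate <= 1:
            raise ValueError("recovery_rate must lie in (0, 1]")
        if self.plasma_volume_ml <= 0 or self.final_volume_ml <= 0:
            raise ValueError("volumes must be positive")

    @property
    def enrichment_factor(self) -> float:
        """Concentration gain of the protocol at 100% recovery."""
        return self.plasma_volume_ml / self.final_volume_ml


RECOVERY_PRESETS: dict[str, RecoverySpec] = {
    "SEC": RecoverySpec("SEC", 0.80, 0.5, 0.1),
    "DMC": RecoverySpec("DMC", 0.33, 0.5, 0.1),
    "DG": RecoverySpec("DG", 0.25, 6.0, 0.1),
}


@dataclass
class SampleQuantification:
    """Absolute and relative concentrations for one measured sample."""

    total_conc_per_ml: float
    ev_conc_per_ml: float
    lp_conc_per_ml: float
    relative_ev: float
    dilution_factor: float = 1.0
    back_calculated_plasma_conc_per_ml: float | None = None
    recovery_method: str | None = None

    def __post_init__(self) -> None:
        if self.ev_conc_per_ml + self.lp_conc_per_ml > self.total_conc_per_ml * (1 + 1e-9):
            raise ValueError("classified concentrations exceed the total")
        if not 0 <= self.relative_ev <= 1:
            raise ValueError("relative_ev must lie in [0, 1]")


def fit_concentration_calibration(
    series: list[tuple[float, float, float]],
    reference: str = "bead dilution series",
) -> ConcentrationCalibration:
    """Fit the counts-to-concentration factor on a dilution series.

    ``series`` holds (known_conc per mL, trajectory_count, duration_s)
    triples; at least 3 points spanning a tenfold concentration range are
    required.  The factor is the slope of the through-origin least-squares
    line of concentration versus counts per 10 minutes.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 calibration points")
    conc = np.array([p[0] for p in series], dtype=float)
    counts = np.array([p[1] for p in series], dtype=float)
    durations = np.array([p[2] for p in series], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("calibration concentrations must be positive")
    if conc.max() / conc.min() < 10:
        raise ValueError("calibration series must span at least 10x in concentration")
    x = counts * REFERENCE_DURATION_S / durations
    slope = float(np.sum(conc * x) / np.sum(x * x))
    residuals = conc - slope * x
    ss_tot = float(np.sum((conc - conc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else float("nan")
    return ConcentrationCalibration(slope, reference, r2, len(series))


def trajectories_to_concentration(
    count: float,
    duration_s: float,
    calib: ConcentrationCalibration,
    dilution_factor: float = 1.0,
) -> float:
    """particles/mL = count * (600 s / duration) * factor * dilution."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return count * (REFERENCE_DURATION_S / duration_s) * calib.factor * dilution_factor


def back_calculate_plasma_concentration(
    measured_ev_conc_per_ml: float, spec: RecoverySpec
) -> float:
    """Undo enrichment: original = measured / (recovery * V_plasma / V_final)."""
    return measured_ev_conc_per_ml / (spec.recovery_rate * spec.enrichment_factor)


def round_sig(value: float, digits: int = 2) -> float:
    """Round to significant figures for reporting (full precision kept internally)."""
    if value == 0 or not np.isfinite(value):
        return value
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + digits - 1)
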