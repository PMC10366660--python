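"""Per-particle estimation: trajectory -> size, cross-section, effective RI.

Each trajectory longer than the localization filter becomes one record:

* Diffusion constant via the covariance-based estimator (CVE)
  ``D = (<dx^2>/2 + <dx_t dx_{t+1}>) / dt`` averaged over x and y.  The
  lag-1 covariance term cancels static localization noise, so the estimator
  is unbiased without any fit parameters.
* Hydrodynamic diameter from Stokes-Einstein.
* Per-trajectory contrast summary = median of per-frame contrasts (robust
  to tails); scattering cross-section sigma = (contrast / A)^2; effective
  RI by Mie inversion at the estimated diameter.
* IQR_S, the interquartile range of RI that contrast noise alone would
  produce for this particle, by Monte Carlo: redraw the per-frame contrasts
  about the particle's contrast, re-estimate the median, re-invert at fixed
  diameter.  Particles with IQR_S below the cutoff (default 0.05) pass the
  precision gate; population RI medians use passing records only.

Population summaries (:func:`population_summary`) correct two acquisition
biases that the per-record estimates inherit from finite trajectories:

* survival selection -- slow (large) particles stay in the observation
  volume longer and are over-represented among trajectories passing the
  localization filter; records are reweighted by the inverse of the
  Monte-Carlo survival probability of their diameter (inverse-probability
  weighting for length-biased sampling);
* log-scale convexity -- d is proportional to 1/D, so multiplicative noise
  in the diffusion estimate shifts log d up by ~Var(D)/2D^2; each record's
  diameter is shrunk by exp(-Var/2D^2) using the CVE's own variance formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mie
from .config import (
    ContrastCalibration,
    EstimationConfig,
    InstrumentSpec,
    OpticalConfig,
)
from .physics import diameter_from_diffusion, diffusion_from_diameter  # noqa: F401
from .simulate import Trajectory, TrajectorySet

__all__ = [
    "EstimationError",
    "estimate_diffusion",
    "diameter_from_diffusion",
    "cross_section_from_contrast",
    "simulated_iqr",
    "apply_precision_gate",
    "build_records",
    "survival_probability",
    "weighted_median",
    "population_summary",
]

RECORD_COLUMNS = [
    "particle_id",
    "n_loc",
    "D_um2_s",
    "se_D_um2_s",
    "diameter_nm",
    "contrast",
    "sigma_nm2",
    "ri",
    "iqr_s",
    "gate",
]


class EstimationError(ValueError):
    """Raised when a trajectory cannot support the requested estimate."""


def estimate_diffusion(traj: Trajectory, frame_rate_hz: float) -> tuple[float, float]:
    """Covariance-based diffusion estimate (um^2/s) and its standard error.

    Uses consecutive-frame displacements only.  The standard error follows
    the known variance of the CVE,
    ``var(D) = D^2 [(6 + 4 eps + 2 eps^2)/N + 4 (1 + eps)^2 / N^2]``
    with eps the localization-noise-to-motion ratio estimated from the
    lag-1 covariance (halved here because x and y are averaged).
    """
    dt = 1.0 / frame_rate_hz
    frames = traj.frame_indices
    pos = traj.positions_um
    consecutive = np.flatnonzero(np.diff(frames) == 1)
    if consecutive.size < 1:
        raise EstimationError("trajectory has no consecutive-frame displacement pairs")
    disp = pos[consecutive + 1] - pos[consecutive]  # (N, 2)

    msq = np.mean(disp**2, axis=0)
    if disp.shape[0] >= 2:
        # lag-1 covariance among displacement pairs that are themselves adjacent
        adj = np.flatnonzero(np.diff(consecutive) == 1)
        if adj.size:
            cov = np.mean(disp[adj] * disp[adj + 1], axis=0)
        else:
            cov = np.zeros(2)
    else:
        cov = np.zeros(2)

    D_axes = msq / (2.0 * dt) + cov / dt
    D = float(np.mean(D_axes))

    # noise-to-signal ratio from sigma_loc^2 ~ -cov (clipped at 0)
    sigma2_loc = float(np.mean(np.clip(-cov, 0.0, None)))
    N = disp.shape[0]
    if D > 0:
        eps = sigma2_loc / (D * dt)
        var = D**2 * ((6 + 4 * eps + 2 * eps**2) / N + 4 * (1 + eps) ** 2 / N**2)
        se = float(np.sqrt(var / 2.0))  # two independent axes averaged
    else:
        se = float("nan")
    return D, se


def cross_section_from_contrast(
    contrasts: np.ndarray | float, calib: ContrastCalibration
) -> tuple[float, float, bool]:
    """(median contrast, sigma in nm^2, negative-contrast flag).

    Accepts the per-frame contrast array or an already-summarized scalar.
    A negative median contrast (pure noise) maps to sigma = 0 and is
    flagged.
    """
    c = float(np.median(np.asarray(contrasts, dtype=float)))
    negative = c < 0
    sigma = 0.0 if negative else (c / calib.amplitude) ** 2
    return c, sigma, negative


def simulated_iqr(
    diameter_nm: float,
    contrast: float,
    n_localizations: int,
    contrast_noise_sd: float,
    optics: OpticalConfig,
    calib: ContrastCalibration,
    n_sims: int = 200,
    rng: np.random.Generator | int = 0,
    ri_bracket_max: float = 2.5,
    inversion_grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """IQR_S: RI interquartile range attributable to contrast noise alone.

    Monte Carlo at fixed diameter: draw ``n_localizations`` per-frame
    contrasts about ``contrast`` with sd ``contrast_noise_sd``, summarize by
    the median, convert to sigma and invert to RI; IQR_S is the
    interquartile range of the resulting RI sample.  Out-of-bracket
    inversions clamp to the bracket edges.  Inversion uses a cached
    monotone sigma(n) grid for speed.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if contrast_noise_sd < 0:
        raise ValueError("contrast_noise_sd must be >= 0")
    if contrast_noise_sd == 0:
        return 0.0
    rng = np.random.default_rng(rng)
    draws = contrast + contrast_noise_sd * rng.standard_normal(
        (n_sims, int(n_localizations))
    )
    medians = np.median(draws, axis=1)
    sigmas = calib.sigma_from_contrast(medians)
    if inversion_grid is None:
        inversion_grid = mie.ri_inversion_grid(diameter_nm, optics, n_max=ri_bracket_max)
    n_grid, sigma_grid = inversion_grid
    ris = np.interp(sigmas, sigma_grid, n_grid)  # clamps at bracket edges
    q25, q75 = np.percentile(ris, [25, 75])
    return float(q75 - q25)


def apply_precision_gate(records: pd.DataFrame, cutoff: float = 0.05) -> pd.DataFrame:
    """Set the precision gate flag: pass iff IQR_S < cutoff."""
    out = records.copy()
    out["gate"] = out["iqr_s"] < cutoff
    return out


def build_records(
    trajset: TrajectorySet,
    estimation: EstimationConfig | None = None,
    n_sims: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full per-particle estimation over a trajectory set.

    Keeps trajectories with strictly more than ``min_localizations``
    localizations, drops records with non-positive diffusion estimates
    (reported in the ``n_dropped`` DataFrame attr), and returns the record
    table with the precision gate applied.
    """
    est = estimation or EstimationConfig()
    instr = trajset.instrument
    optics = trajset.optics
    calib = trajset.calibration
    n_sims = n_sims or est.n_precision_sims
    rng = np.random.default_rng(seed)

    rows = []
    dropped = 0
    for traj in trajset.trajectories:
        if len(traj) <= instr.min_localizations:
            continue
        if traj.contrasts is None:
            raise EstimationError(
                f"trajectory {traj.particle_id} carries no contrast data"
            )
        D, _se = estimate_diffusion(traj, instr.frame_rate_hz)
        if not np.isfinite(D) or D <= 0:
            dropped += 1
            continue
        diameter = float(diameter_from_diffusion(D, optics))
        contrast, sigma, _neg = cross_section_from_contrast(traj.contrasts, calib)

        grid = mie.ri_inversion_grid(diameter, optics, n_max=est.ri_bracket_max)
        n_grid, sigma_grid = grid
        ri = float(np.interp(sigma, sigma_grid, n_grid))

        if est.noise_from_trajectory:
            noise_sd = float(np.std(traj.contrasts, ddof=1))
        else:
            noise_sd = instr.contrast_noise_sd
        iqr_s = simulated_iqr(
            diameter,
            contrast,
            len(traj),
            noise_sd,
            optics,
            calib,
            n_sims=n_sims,
            rng=rng,
            ri_bracket_max=est.ri_bracket_max,
            inversion_grid=grid,
        )
        rows.append(
            {
                "particle_id": traj.particle_id,
                "n_loc": len(traj),
                "D_um2_s": D,
                "se_D_um2_s": _se,
                "diameter_nm": diameter,
                "contrast": contrast,
                "sigma_nm2": sigma,
                "ri": ri,
                "iqr_s": iqr_s,
                "gate": False,
                "true_diameter_nm": (traj.truth or {}).get("diameter_nm", np.nan),
                "true_ri": (traj.truth or {}).get("ri", np.nan),
                "true_label": (traj.truth or {}).get("label"),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=RECORD_COLUMNS + ["true_diameter_nm", "true_ri", "true_label"],
    )
    records = apply_precision_gate(records, est.iqr_s_cutoff)
    records.attrs["n_dropped_nonpositive_D"] = dropped
    return records


def survival_probability(
    diameters_nm: np.ndarray,
    optics: OpticalConfig,
    instr: InstrumentSpec,
    n_mc: int = 4000,
    seed: int = 123,
) -> np.ndarray:
    """P(trajectory survives the localization filter | diameter), by Monte Carlo.

    For each diameter, simulates ``n_mc`` Brownian entries uniform in the
    observation volume and returns the fraction still inside after
    ``min_localizations`` steps -- the probability that a particle of that
    size yields a kept trajectory.  Used as the inverse-probability weight
    of population summaries.
    """
    rng = np.random.default_rng(seed)
    from .physics import diffusion_from_diameter as _D

    nf = instr.min_localizations
    L = instr.fov_side_um
    hd = instr.focal_depth_um / 2.0
    out = []
    for d in np.atleast_1d(np.asarray(diameters_nm, dtype=float)):
        D = float(_D(d, optics))
        sd = np.sqrt(2.0 * D * instr.dt_s)
        start = np.stack(
            [
                rng.uniform(0, L, n_mc),
                rng.uniform(0, L, n_mc),
                rng.uniform(-hd, hd, n_mc),
            ],
            axis=1,
        )
        pos = start[:, None, :] + np.cumsum(
            sd * rng.standard_normal((n_mc, nf, 3)), axis=1
        )
        ok = (
            (pos[:, :, 0] >= 0)
            & (pos[:, :, 0] <= L)
            & (pos[:, :, 1] >= 0)
            & (pos[:, :, 1] <= L)
            & (np.abs(pos[:, :, 2]) <= hd)
        )
        out.append(float(np.mean(ok.all(axis=1))))
    return np.array(out)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of a weighted sample (linear interpolation of the weighted CDF)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5 * w.sum(), cw, v))


def population_summary(
    records: pd.DataFrame,
    optics: OpticalConfig,
    instr: InstrumentSpec,
    selection_correction: bool = True,
    n_mc: int = 4000,
    seed: int = 123,
) -> dict:
    """Population median diameter and RI with acquisition-bias corrections.

    Diameters are first shrunk by the log-convexity factor
    ``exp(-Var(D)/2 D^2)`` (the CVE standard error the record already
    carries), then records are reweighted by the inverse survival
    probability of their diameter.  The RI median is taken over
    precision-gate-passing records only, with the same weights.  Set
    ``selection_correction=False`` for plain unweighted medians of the raw
    estimates.
    """
    if records.empty:
        raise EstimationError("no records to summarize")
    d = records["diameter_nm"].to_numpy(dtype=float)
    if selection_correction:
        rel_var = (records["se_D_um2_s"] / records["D_um2_s"]) ** 2
        d = d * np.exp(-0.5 * np.clip(rel_var.to_numpy(dtype=float), 0, 1))
        grid = np.linspace(max(d.min() - 10, 10.0), d.max() + 10, 24)
        p_grid = survival_probability(grid, optics, instr, n_mc=n_mc, seed=seed)
        weights = 1.0 / np.clip(np.interp(d, grid, p_grid), 0.02, None)
    else:
        weights = np.ones_like(d)
    gate = records["gate"].to_numpy(dtype=bool)
    ri = records["ri"].to_numpy(dtype=float)
    summary = {
        "n_records": int(len(records)),
        "median_diameter_nm": weighted_median(d, weights),
        "n_gate": int(gate.sum()),
        "median_ri": weighted_median(ri[gate], weights[gate]) if gate.any() else float("nan"),
        "gate_fraction": float(gate.mean()),
    }
    return summary
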