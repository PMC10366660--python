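"""Synthetic iNTA measurement generator.

Produces ground-truth-labelled datasets that emulate an interferometric
tracking recording: particle populations (size and effective-RI
distributions plus a concentration), 3D Brownian trajectories sampled at the
instrument frame rate inside a bounded observation volume, and noisy
per-frame iSCAT contrasts C = A sqrt(sigma) + N(0, noise_sd).

Population presets carry the median (IQR) sizes and refractive indices
measured for SKMEL37 extracellular vesicles, chylomicrons (ULDL) and VLDL:
EV 97 (79-120) nm / 1.37 (1.36-1.38); ULDL 57 (48-71) nm / 1.52 (1.48-1.57);
VLDL 46 (41-52) nm / 1.49 (1.45-1.52), with the corresponding iNTA mean
concentrations.  Diameters are lognormal (size distributions of biological
nanoparticles are right-skewed) and RIs truncated-normal, both matched to
the quoted median and IQR.

Simplifications relative to a real recording (documented in the methods
note): per-particle contrast is constant up to additive Gaussian noise (no
axial contrast modulation); particles enter the observation volume only at
t = 0; no wall effects, interactions or flow.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import mie
from .config import ContrastCalibration, InstrumentSpec, OpticalConfig
from .physics import diffusion_from_diameter

__all__ = [
    "PopulationSpec",
    "Trajectory",
    "TrajectorySet",
    "POPULATION_PRESETS",
    "sample_population",
    "simulate_trajectory",
    "simulate_contrasts",
    "simulate_sample",
]

# quartile z-score: Phi^-1(0.75)
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class PopulationSpec:
    """One particle class: size/RI distributions and a concentration.

    ``size_iqr`` and ``ri_iqr`` are (25th, 75th) percentile pairs; the
    degenerate case q25 == q75 == median yields zero-spread draws.
    """

    name: str
    size_median_nm: float
    size_iqr_nm: tuple[float, float]
    ri_median: float
    ri_iqr: tuple[float, float]
    concentration_per_ml: float = 0.0

    def __post_init__(self) -> None:
        q25, q75 = self.size_iqr_nm
        if q25 > q75 or not (q25 <= self.size_median_nm <= q75):
            raise ValueError(f"{self.name}: size median must lie within its IQR")
        r25, r75 = self.ri_iqr
        if r25 > r75 or not (r25 <= self.ri_median <= r75):
            raise ValueError(f"{self.name}: RI median must lie within its IQR")
        if self.size_median_nm <= 0:
            raise ValueError("size_median_nm must be positive")
        if self.concentration_per_ml < 0:
            raise ValueError("concentration must be >= 0")


POPULATION_PRESETS: dict[str, PopulationSpec] = {
    "EV": PopulationSpec("EV", 97.0, (79.0, 120.0), 1.37, (1.36, 1.38), 1.58e12),
    "ULDL": PopulationSpec("ULDL", 57.0, (48.0, 71.0), 1.52, (1.48, 1.57), 8.56e13),
    "VLDL": PopulationSpec("VLDL", 46.0, (41.0, 52.0), 1.49, (1.45, 1.52), 2.80e13),
}


@dataclass
class Trajectory:
    """One particle's time-ordered localizations and per-frame contrasts."""

    particle_id: int
    frame_indices: np.ndarray
    positions_um: np.ndarray  # shape (L, 2): x, y
    contrasts: np.ndarray | None = None
    truth: dict | None = None  # diameter_nm, ri, label when synthetic

    def __len__(self) -> int:
        return len(self.frame_indices)

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.frame_indices) != len(self.positions_um):
            raise ValueError("frame_indices and positions must align")
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame_indices must be strictly increasing")
        if self.contrasts is not None:
            self.contrasts = np.asarray(self.contrasts, dtype=float)
            if len(self.contrasts) != len(self.frame_indices):
                raise ValueError("contrasts must align with frames")


@dataclass
class TrajectorySet:
    """A collection of trajectories with the config that generated them."""

    trajectories: list[Trajectory]
    optics: OpticalConfig
    instrument: InstrumentSpec
    calibration: ContrastCalibration
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trajectories)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for traj in self.trajectories:
            c = traj.contrasts if traj.contrasts is not None else np.full(len(traj), np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "particle_id": traj.particle_id,
                        "frame": traj.frame_indices,
                        "x_um": traj.positions_um[:, 0],
                        "y_um": traj.positions_um[:, 1],
                        "contrast": c,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["particle_id", "frame", "x_um", "y_um", "contrast"]
            )
        return pd.concat(rows, ignore_index=True)

    def _meta(self) -> dict:
        truth = {
            str(t.particle_id): t.truth for t in self.trajectories if t.truth is not None
        }
        meta = {
            "seed": self.seed,
            "optics": dataclasses.asdict(self.optics),
            "instrument": dataclasses.asdict(self.instrument),
            "calibration": dataclasses.asdict(self.calibration),
            "truth": truth,
        }
        payload = json.dumps(meta, sort_keys=True)
        meta["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:12]
        return meta

    def to_csv(self, path: str | Path) -> None:
        """Write the localization table plus a ground-truth/config sidecar JSON."""
        path = Path(path)
        df = self.to_dataframe()
        df.to_csv(path, index=False, float_format="%.9g")
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(self._meta(), fh, sort_keys=True, indent=1)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrajectorySet":
        path = Path(path)
        df = pd.read_csv(path)
        required = {"particle_id", "frame", "x_um", "y_um", "contrast"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
        sidecar = path.with_suffix(path.suffix + ".json")
        optics, instr, calib, seed, truth = (
            OpticalConfig(),
            InstrumentSpec(),
            ContrastCalibration(),
            None,
            {},
        )
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            optics = OpticalConfig(**meta["optics"])
            instr_kwargs = meta["instrument"]
            instr = InstrumentSpec(**instr_kwargs)
            calib = ContrastCalibration(**meta["calibration"])
            seed = meta.get("seed")
            truth = meta.get("truth", {})
        trajectories = []
        for pid, group in df.groupby("particle_id", sort=True):
            group = group.sort_values("frame")
            trajectories.append(
                Trajectory(
                    particle_id=int(pid),
                    frame_indices=group["frame"].to_numpy(),
                    positions_um=group[["x_um", "y_um"]].to_numpy(),
                    contrasts=group["contrast"].to_numpy(),
                    truth=truth.get(str(int(pid))),
                )
            )
        return cls(trajectories, optics, instr, calib, seed=seed)


def sample_population(
    spec: PopulationSpec,
    n: int,
    rng: np.random.Generator | int,
    medium_ri: float = 1.33,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (diameter, RI) pairs matching the population's median and IQR.

    Diameters: lognormal with log-median ln(median) and
    log-sd ln(q75/q25) / (2 * 0.67449).  RIs: normal matched the same way
    on the natural scale, truncated below at the medium index by resampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)

    q25, q75 = spec.size_iqr_nm
    log_sd = np.log(q75 / q25) / (2 * _Z75) if q75 > q25 else 0.0
    diameters = spec.size_median_nm * np.exp(log_sd * rng.standard_normal(n))

    r25, r75 = spec.ri_iqr
    ri_sd = (r75 - r25) / (2 * _Z75) if r75 > r25 else 0.0
    ris = spec.ri_median + ri_sd * rng.standard_normal(n)
    # truncate at the medium index: an effective RI below n_m is unphysical
    while np.any(ris < medium_ri):
        bad = ris < medium_ri
        ris[bad] = spec.ri_median + ri_sd * rng.standard_normal(bad.sum())
        if ri_sd == 0.0:
            ris[bad] = max(spec.ri_median, medium_ri)
            break
    return diameters, ris


def simulate_trajectory(
    diameter_nm: float,
    optics: OpticalConfig,
    instr: InstrumentSpec,
    rng: np.random.Generator | int,
    particle_id: int = 0,
    start_frame: int = 0,
) -> Trajectory:
    """3D Brownian trajectory truncated at the observation-volume boundary.

    Per-axis steps are N(0, 2 D dt) with D from Stokes-Einstein.  The
    particle enters at a uniform random position in the volume (FOV x FOV in
    x,y; +-focal_depth/2 in z about focus) and the trajectory ends at the
    first frame outside it; only x,y are reported, as in a real recording.
    """
    rng = np.random.default_rng(rng)
    D = float(diffusion_from_diameter(diameter_nm, optics))
    dt = instr.dt_s
    max_frames = int(round(instr.duration_s * instr.frame_rate_hz))
    L = instr.fov_side_um
    half_depth = instr.focal_depth_um / 2.0

    if max_frames == 0:
        return Trajectory(particle_id, np.empty(0, int), np.empty((0, 2)))

    start = np.array(
        [rng.uniform(0, L), rng.uniform(0, L), rng.uniform(-half_depth, half_depth)]
    )
    step_sd = np.sqrt(2.0 * D * dt)
    steps = step_sd * rng.standard_normal((max_frames - 1, 3))
    pos = np.vstack([start, start + np.cumsum(steps, axis=0)])

    inside = (
        (pos[:, 0] >= 0)
        & (pos[:, 0] <= L)
        & (pos[:, 1] >= 0)
        & (pos[:, 1] <= L)
        & (np.abs(pos[:, 2]) <= half_depth)
    )
    exits = np.flatnonzero(~inside)
    end = exits[0] if exits.size else max_frames
    frames = np.arange(start_frame, start_frame + end)
    return Trajectory(particle_id, frames, pos[:end, :2])


def simulate_contrasts(
    diameter_nm: float,
    ri: float,
    calib: ContrastCalibration,
    optics: OpticalConfig,
    n_frames: int,
    noise_sd: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Per-frame iSCAT contrasts A sqrt(sigma(d, n)) + N(0, noise_sd)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng)
    sigma = mie.scattering_cross_section(diameter_nm, ri, optics)
    c0 = calib.contrast_from_sigma(sigma)
    return c0 + noise_sd * rng.standard_normal(n_frames)


def simulate_sample(
    populations: Sequence[PopulationSpec],
    instr: InstrumentSpec,
    optics: OpticalConfig,
    calib: ContrastCalibration,
    seed: int | np.random.Generator,
    n_expected: int | None = None,
) -> TrajectorySet:
    """Simulate a full recording of a (possibly mixed) particle sample.

    The total trajectory count is Poisson with mean
    ``sum(concentration) * detection_volume`` (or ``n_expected`` when given)
    and is split across populations in proportion to their concentrations.
    Trajectories shorter than the localization filter are still emitted --
    filtering is the analysis pipeline's job.
    """
    populations = list(populations)
    conc = np.array([p.concentration_per_ml for p in populations], dtype=float)
    if len(populations) == 0 or np.all(conc == 0):
        raise ValueError("need at least one population with concentration > 0")
    rng = np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    if n_expected is None:
        n_expected = conc.sum() * instr.detection_volume_ml
    n_total = rng.poisson(n_expected)
    weights = conc / conc.sum()
    counts = rng.multinomial(n_total, weights)

    trajectories: list[Trajectory] = []
    pid = 0
    for pop, n_pop in zip(populations, counts):
        if n_pop == 0:
            continue
        diameters, ris = sample_population(pop, n_pop, rng, medium_ri=optics.medium_ri)
        for d, ri in zip(diameters, ris):
            traj = simulate_trajectory(d, optics, instr, rng, particle_id=pid)
            if len(traj) > 0:
                traj.contrasts = simulate_contrasts(
                    d, ri, calib, optics, len(traj), instr.contrast_noise_sd, rng
                )
            else:
                traj.contrasts = np.empty(0)
            traj.truth = {"diameter_nm": float(d), "ri": float(ri), "label": pop.name}
            trajectories.append(traj)
            pid += 1
    return TrajectorySet(trajectories, optics, instr, calib, seed=seed_val)
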