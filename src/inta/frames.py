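"""Optional image-level stage: render interferometric movies and recover
localizations from them.

The forward path (`render_frames`) paints each localization as a radially
symmetric interferometric spot -- a central lobe plus one ring of opposite
sign, peak amplitude equal to the particle's contrast -- on a unit
background with additive Gaussian pixel noise, and the reverse path
recovers trajectories:

1. `median_background_correct`: pixel-wise rolling temporal median removes
   the static background (subtractive mode leaves the spot signal on a
   zero baseline).
2. `radial_variance_transform`: per pixel, the variance of mean intensities
   on integer-radius rings centred there; large at centres of radially
   symmetric patterns and insensitive to constant offsets.
3. `detect_and_link`: thresholded local maxima of the RVT map,
   centroid-refined to subpixel, greedily linked frame-to-frame by nearest
   neighbour within a displacement cap; per-frame contrast read from the
   corrected frame; short trajectories discarded.

The whole module is bypassable: the analysis accepts trajectory CSVs
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from scipy.signal import fftconvolve

from .config import DetectionConfig, InstrumentSpec
from .simulate import Trajectory, TrajectorySet

__all__ = [
    "FrameStack",
    "PSFModel",
    "render_frames",
    "median_background_correct",
    "radial_variance_transform",
    "detect_and_link",
    "link_localizations",
]


@dataclass
class FrameStack:
    """A movie: (T, H, W) pixel array plus geometry and timing."""

    frames: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def save_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.frames.astype(np.float32),
            photometric="minisblack",
            metadata={
                "pixel_size_um": self.pixel_size_um,
                "frame_rate_hz": self.frame_rate_hz,
            },
        )

    @classmethod
    def load_tiff(cls, path, pixel_size_um: float, frame_rate_hz: float) -> "FrameStack":
        return cls(tifffile.imread(path), pixel_size_um, frame_rate_hz)


@dataclass(frozen=True)
class PSFModel:
    """Radially symmetric interferometric spot: core lobe plus one ring."""

    core_sd_px: float = 1.6
    ring_radius_px: float = 4.0
    ring_sd_px: float = 1.0
    ring_amplitude: float = -0.4  # relative to the core peak

    def profile(self, r: np.ndarray) -> np.ndarray:
        core = np.exp(-(r**2) / (2 * self.core_sd_px**2))
        ring = self.ring_amplitude * np.exp(
            -((r - self.ring_radius_px) ** 2) / (2 * self.ring_sd_px**2)
        )
        return core + ring


def _um_to_px(x_um: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Pixel-centred convention: the centre of pixel i sits at (i + 0.5) px."""
    return np.asarray(x_um) / pixel_size_um - 0.5


def render_frames(
    trajset: TrajectorySet,
    detection: DetectionConfig | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int = 0,
    psf: PSFModel | None = None,
    n_frames: int | None = None,
) -> FrameStack:
    """Render a trajectory set into an interferometric movie.

    Each localization is stamped at its subpixel position with peak
    amplitude equal to its per-frame contrast, on a unit background.
    """
    det = detection or DetectionConfig()
    psf = psf or PSFModel()
    rng = np.random.default_rng(rng)
    instr = trajset.instrument
    n_px = int(round(instr.fov_side_um / det.pixel_size_um))
    if n_px < 2 * det.rvt_rmax_px + 1:
        raise ValueError("pixel size incompatible with FOV: frame too small")

    if n_frames is None:
        last = 0
        for t in trajset.trajectories:
            if len(t):
                last = max(last, int(t.frame_indices[-1]))
        n_frames = last + 1
    stack = np.ones((n_frames, n_px, n_px), dtype=float)

    half = int(np.ceil(psf.ring_radius_px + 4 * psf.ring_sd_px))
    for traj in trajset.trajectories:
        if traj.contrasts is None:
            raise ValueError(f"trajectory {traj.particle_id} has no contrasts to render")
        for f, (x_um, y_um), c in zip(
            traj.frame_indices, traj.positions_um, traj.contrasts
        ):
            if f >= n_frames:
                break
            cx = _um_to_px(x_um, det.pixel_size_um)
            cy = _um_to_px(y_um, det.pixel_size_um)
            ix, iy = int(round(cx)), int(round(cy))
            x0, x1 = max(ix - half, 0), min(ix + half + 1, n_px)
            y0, y1 = max(iy - half, 0), min(iy + half + 1, n_px)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            r = np.hypot(xx - cx, yy - cy)
            stack[f, y0:y1, x0:x1] += c * psf.profile(r)
    if noise_sd > 0:
        stack += noise_sd * rng.standard_normal(stack.shape)
    return FrameStack(stack, det.pixel_size_um, instr.frame_rate_hz)


def median_background_correct(
    stack: FrameStack, window: int, mode: str = "subtract", guard: int = 0
) -> FrameStack:
    """Remove the static background with a pixel-wise rolling temporal median.

    ``subtract`` returns frame - median (signal on a zero baseline);
    ``divide`` returns frame / median - 1.

    ``guard`` excludes the central ``+-guard`` frames from the median
    window.  A slowly diffusing particle lingers near its own past
    positions, so a plain centred median partially contains it and its
    subtraction leaves a motion-correlated residue that biases downstream
    diffusion estimates; a guard of a few tens of frames (enough for the
    particle to diffuse past its own spot) removes that self-subtraction.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > stack.frames.shape[0]:
        raise ValueError("window exceeds stack length")
    if guard < 0 or window - (2 * guard + 1) < 3:
        raise ValueError("guard must leave at least 3 frames in the window")
    if guard == 0:
        med = ndimage.median_filter(stack.frames, size=(window, 1, 1), mode="nearest")
    else:
        footprint = np.ones((window, 1, 1), dtype=bool)
        centre = window // 2
        footprint[centre - guard : centre + guard + 1] = False
        med = ndimage.median_filter(stack.frames, footprint=footprint, mode="nearest")
    if mode == "subtract":
        corrected = stack.frames - med
    elif mode == "divide":
        corrected = stack.frames / med - 1.0
    else:
        raise ValueError("mode must be 'subtract' or 'divide'")
    return FrameStack(corrected, stack.pixel_size_um, stack.frame_rate_hz)


def _ring_kernels(rmin: int, rmax: int) -> list[np.ndarray]:
    size = 2 * rmax + 1
    yy, xx = np.mgrid[-rmax : rmax + 1, -rmax : rmax + 1]
    rr = np.rint(np.hypot(xx, yy)).astype(int)
    kernels = []
    for r in range(rmin, rmax + 1):
        k = (rr == r).astype(float)
        kernels.append(k / k.sum())
    return kernels


def radial_variance_transform(frame: np.ndarray, rmin: int = 1, rmax: int = 6) -> np.ndarray:
    """Variance of ring-mean intensities around each pixel.

    For each pixel, the mean intensity on every integer-radius ring
    r in [rmin, rmax] centred there is computed by convolution; the
    response is the variance of those ring means.  It peaks at the centres
    of radially symmetric patterns and vanishes on constant frames.
    """
    frame = np.asarray(frame, dtype=float)
    if not 0 <= rmin < rmax:
        raise ValueError("require 0 <= rmin < rmax")
    if 2 * rmax + 1 > min(frame.shape):
        raise ValueError("rmax exceeds frame half-size")
    kernels = _ring_kernels(rmin, rmax)
    # near the frame edge only part of each ring is inside; normalizing by
    # the in-frame ring fraction keeps constant frames at exactly zero
    # response and makes the transform offset-invariant everywhere
    norms = _ring_norms(frame.shape, rmin, rmax)
    ring_means = np.stack(
        [
            fftconvolve(frame, k, mode="same") / norm
            for k, norm in zip(kernels, norms)
        ]
    )
    return np.var(ring_means, axis=0)


_NORM_CACHE: dict = {}


def _ring_norms(shape: tuple, rmin: int, rmax: int) -> list[np.ndarray]:
    """In-frame ring fractions, cached per (shape, rmin, rmax)."""
    key = (shape, rmin, rmax)
    if key not in _NORM_CACHE:
        ones = np.ones(shape)
        _NORM_CACHE[key] = [
            fftconvolve(ones, k, mode="same") for k in _ring_kernels(rmin, rmax)
        ]
        if len(_NORM_CACHE) > 8:
            _NORM_CACHE.pop(next(iter(_NORM_CACHE)))
    return _NORM_CACHE[key]


def _detect_frame(
    corrected: np.ndarray, det: DetectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Localizations in one corrected frame -> (positions px (N,2), contrasts)."""
    response = radial_variance_transform(corrected, det.rvt_rmin_px, det.rvt_rmax_px)
    # robust noise floor of the response map
    med = np.median(response)
    mad = np.median(np.abs(response - med)) + 1e-30
    threshold = med + det.detect_snr * 1.4826 * mad
    # suppress secondary maxima on the interferometric ring itself
    sep = 2 * det.rvt_rmax_px + 1
    footprint = np.ones((sep, sep), dtype=bool)
    is_max = (response == ndimage.maximum_filter(response, footprint=footprint)) & (
        response > threshold
    )
    peaks = np.argwhere(is_max)  # (row, col) = (y, x)
    positions = []
    contrasts = []
    h, w = corrected.shape

    def _parabolic(vm, v0, vp):
        denom = vm - 2 * v0 + vp
        if denom >= 0:  # not a local max in this axis
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    for y, x in peaks:
        dy = dx = 0.0
        if 0 < y < h - 1:
            dy = _parabolic(response[y - 1, x], response[y, x], response[y + 1, x])
        if 0 < x < w - 1:
            dx = _parabolic(response[y, x - 1], response[y, x], response[y, x + 1])
        positions.append((x + dx, y + dy))
        contrasts.append(float(corrected[y, x]))
    if not positions:
        return np.empty((0, 2)), np.empty(0)
    return np.array(positions), np.array(contrasts)


def link_localizations(
    detections: list[tuple[np.ndarray, np.ndarray]],
    max_disp_px: float,
    min_localizations: int,
    pixel_size_um: float,
    memory: int = 0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    ``detections[f]`` is the (positions_px, contrasts) pair for frame f.
    A track missing a detection stays eligible for up to ``memory``
    further frames (with the distance cap growing diffusively, by
    sqrt(gap + 1)) before it is closed; skipped frames are simply absent
    from the trajectory.  Trajectories with <= ``min_localizations``
    localizations are discarded.
    """
    active: list[dict] = []
    finished: list[dict] = []
    for f, (pos, con) in enumerate(detections):
        n_det = len(pos)
        assigned_det = np.zeros(n_det, dtype=bool)
        extended = np.zeros(len(active), dtype=bool)
        if active and n_det:
            last = np.array([trk["pos"][-1] for trk in active])
            gaps = np.array([f - trk["frames"][-1] for trk in active], dtype=float)
            dists = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            caps = max_disp_px * np.sqrt(gaps)  # gap = 1 for an unbroken link
            order = np.argsort(dists, axis=None)
            for flat in order:
                i, j = np.unravel_index(flat, dists.shape)
                if extended[i] or assigned_det[j] or dists[i, j] > caps[i]:
                    continue
                trk = active[i]
                trk["frames"].append(f)
                trk["pos"].append(pos[j])
                trk["con"].append(con[j])
                extended[i] = True
                assigned_det[j] = True
        still_active = []
        for trk, ext in zip(active, extended):
            if ext or f - trk["frames"][-1] <= memory:
                still_active.append(trk)
            else:
                finished.append(trk)
        active = still_active
        for j in range(n_det):
            if not assigned_det[j]:
                active.append({"frames": [f], "pos": [pos[j]], "con": [con[j]]})
    finished.extend(active)

    trajectories = []
    pid = 0
    for trk in finished:
        if len(trk["frames"]) <= min_localizations:
            continue
        pos_px = np.array(trk["pos"])
        pos_um = (pos_px + 0.5) * pixel_size_um
        trajectories.append(
            Trajectory(
                particle_id=pid,
                frame_indices=np.array(trk["frames"]),
                positions_um=pos_um,
                contrasts=np.array(trk["con"]),
            )
        )
        pid += 1
    return trajectories


def detect_and_link(
    stack: FrameStack,
    instr: InstrumentSpec,
    det: DetectionConfig | None = None,
    background_corrected: bool = False,
) -> TrajectorySet:
    """Full detection chain: background correction, RVT peaks, linking.

    ``max_disp_px`` defaults to 4 sqrt(2 D_max dt) / pixel_size with D_max
    the diffusion constant of a 40 nm particle -- four step standard
    deviations of the fastest particle of interest.
    """
    from .config import ContrastCalibration, OpticalConfig
    from .physics import diffusion_from_diameter

    det = det or DetectionConfig()
    if background_corrected:
        corrected = stack
    else:
        corrected = median_background_correct(
            stack, det.median_window, det.background_mode, det.median_guard
        )
    max_disp = det.max_disp_px
    if max_disp is None:
        optics = OpticalConfig()
        D_max = float(diffusion_from_diameter(40.0, optics))
        max_disp = 4.0 * np.sqrt(2.0 * D_max / stack.frame_rate_hz) / stack.pixel_size_um
    detections = [_detect_frame(frame, det) for frame in corrected.frames]
    trajectories = link_localizations(
        detections,
        max_disp,
        det.min_localizations,
        stack.pixel_size_um,
        memory=det.link_memory,
    )
    return TrajectorySet(
        trajectories,
        OpticalConfig(),
        instr,
        ContrastCalibration(),
        seed=None,
    )
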