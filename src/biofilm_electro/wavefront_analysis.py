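"""Anomalous-transport analysis of biofilm wavefronts.

The radial position R(t) of the bright wavefront is extracted from
simulation frames (or rendered image stacks), split into the outward
(centrifugal, core -> periphery) and inward (centripetal, periphery ->
core) phases, and each phase is fitted with the anomalous power law

    R(t)^2 = Rc^2 + b t^gamma

whose exponent classifies the transport: subdiffusive (gamma < 1),
diffusive (gamma = 1), superdiffusive subballistic (1 < gamma < 2),
ballistic (gamma = 2), or super-ballistic (gamma > 2). The intercept Rc is
the critical radius for wave initiation. Velocity-curvature relations
(v = dR/dt against kappa = 2/R for a spherical front) probe the Eikonal
prediction that propagation slows as the front flattens... or rather, as
curvature falls while the wave spreads, speed decays for these potassium
waves.

Centripetal convention: the phase split is at the global maximum of R(t);
the inward phase keeps the absolute front radius (decreasing toward the
core) with t measured from collapse onset, defined as the first frame at
which the front has receded a resolvable distance (one shell width) from
its peak. The power law is fitted with a negative prefactor b, so gamma
describes how the collapse accelerates. This choice affects gamma and is
therefore part of the module contract (see the methods note for the
rationale against the distance-travelled alternative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .fdf_biofilm import SimFrame

__all__ = [
    "WavefrontTrack",
    "PowerLawFit",
    "VelocityProfile",
    "track_wavefront_radius",
    "fit_power_law",
    "classify_transport",
    "velocity_curvature",
    "radial_profile",
]


@dataclass(frozen=True)
class WavefrontTrack:
    """R(t) samples for one wave phase.

    ``phase`` is "centrifugal" (outward; R non-decreasing up to noise) or
    "centripetal" (inward collapse; R is the absolute front radius,
    non-increasing up to noise, with the time origin at collapse onset).
    """

    times: np.ndarray  # min, increasing, phase origin at 0
    R: np.ndarray  # um, >= 0
    phase: str
    source: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "R", R)
        if times.size != R.size:
            raise ValueError("times and R must have the same length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(R < 0):
            raise ValueError("R must be non-negative")
        if self.phase not in ("centrifugal", "centripetal"):
            raise ValueError("phase must be 'centrifugal' or 'centripetal'")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting R(t)^2 = Rc^2 + b t^gamma."""

    Rc: float  # um
    b: float  # um^2 / min^gamma
    gamma: float
    Rc_sd: float
    b_sd: float
    gamma_sd: float
    residual_norm: float
    n_points: int
    phase: str = ""

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.Rc < 0:
            raise ValueError("Rc must be non-negative")
        if self.n_points < 4:
            raise ValueError("fit requires at least 4 points")


@dataclass(frozen=True)
class VelocityProfile:
    """Front velocity and curvature along a track."""

    times: np.ndarray  # min
    v: np.ndarray  # um/min
    kappa: np.ndarray  # 1/um
    R: np.ndarray  # um
    phase: str

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.v) == len(self.kappa) == len(self.R) == n):
            raise ValueError("velocity profile arrays must have equal length")


def radial_profile(
    values: np.ndarray,
    radii: np.ndarray,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` in concentric shells of width ``bin_width``.

    Returns (shell center radii, shell means); empty shells are NaN.
    """
    r_max = float(radii.max())
    n_bins = max(1, int(math.ceil((r_max + 1e-9) / bin_width)))
    idx = np.minimum((radii / bin_width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return centers, means


def _frame_radius(
    centers: np.ndarray,
    means: np.ndarray,
    threshold: float,
    reference_max: float | None = None,
) -> float:
    """Outermost shell center whose mean intensity reaches the threshold.

    The threshold is ``threshold * reference_max`` (the movie maximum, so a
    uniformly decaying profile is seen to collapse) or, if no reference is
    given, ``threshold * frame max`` (per-frame normalization).
    """
    valid = ~np.isnan(means)
    if not np.any(valid):
        return np.nan
    ref = np.nanmax(means) if reference_max is None else reference_max
    if ref <= 0:
        return np.nan
    level = threshold * ref
    bright = valid & (means >= level)
    if not np.any(bright):
        return np.nan
    i_last = int(np.where(bright)[0][-1])
    # sub-bin resolution: linearly interpolate the crossing between the
    # outermost bright shell and the next (dimmer) valid shell
    r_bright = float(centers[i_last])
    for j in range(i_last + 1, means.size):
        if valid[j]:
            lo, hi = float(means[j]), float(means[i_last])
            if hi > lo:
                frac = (hi - level) / (hi - lo)
                frac = min(max(frac, 0.0), 1.0)
                return r_bright + frac * (float(centers[j]) - r_bright)
            break
    return r_bright


def track_wavefront_radius(
    frames: Sequence[SimFrame] | np.ndarray,
    threshold: float = 0.5,
    positions: np.ndarray | None = None,
    times: np.ndarray | None = None,
    bin_width: float | None = None,
    voxel_size: float = 1.0,
    temporal_smooth: int = 3,
    min_radius: float | None = None,
    max_mode: str = "movie",
) -> list[WavefrontTrack]:
    """Extract centrifugal and centripetal wavefront tracks.

    Two input forms are supported:

    * a list of :class:`SimFrame` together with the agent ``positions``
      (um): per frame, cells are binned into radial shells (default width:
      inferred from nearest-neighbour spacing) and the front radius is the
      outermost shell whose mean tht is at least ``threshold`` times the
      frame maximum;
    * a 4-D image stack (t, z, y, x) with isotropic ``voxel_size`` (um):
      voxel intensities are radially averaged about the stack center after
      a ``temporal_smooth``-frame moving average.

    The track is split at the global maximum of R(t): frames up to the
    maximum form the centrifugal phase (time origin at the first bright
    frame); later frames form the centripetal phase, reported as inward
    distance travelled from the peak radius with time measured from
    collapse onset. Frames whose front radius falls below one bin width
    are dropped (discretization artifacts).

    Raises
    ------
    ValueError
        If no frame exceeds the threshold ("no wavefront detected").
    """
    if isinstance(frames, np.ndarray):
        stack = np.asarray(frames, dtype=float)
        if stack.ndim != 4:
            raise ValueError("image stack must be 4-D (t, z, y, x)")
        if times is None:
            times_arr = np.arange(stack.shape[0], dtype=float)
        else:
            times_arr = np.asarray(times, dtype=float)
        if temporal_smooth > 1:
            kernel = np.ones(temporal_smooth) / temporal_smooth
            flat = stack.reshape(stack.shape[0], -1)
            sm = np.apply_along_axis(
                lambda m: np.convolve(m, kernel, mode="same"), 0, flat
            )
            stack = sm.reshape(stack.shape)
        # subtract the background floor so the far field does not count as bright
        stack = np.clip(stack - np.median(stack[0]), 0.0, None)
        zc, yc, xc = [(s - 1) / 2.0 for s in stack.shape[1:]]
        zz, yy, xx = np.meshgrid(
            np.arange(stack.shape[1]), np.arange(stack.shape[2]),
            np.arange(stack.shape[3]), indexing="ij",
        )
        radii = np.sqrt((zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2).ravel()
        radii = radii * voxel_size
        bw = bin_width if bin_width is not None else voxel_size
        profiles = [
            radial_profile(stack[i].ravel(), radii, bw)
            for i in range(stack.shape[0])
        ]
        mean_intensity = stack.reshape(stack.shape[0], -1).mean(axis=1)
        source = "image-stack"
    else:
        if positions is None:
            raise ValueError("agent positions are required for SimFrame input")
        radii = np.linalg.norm(np.atleast_2d(positions), axis=1)
        times_arr = np.array([f.t for f in frames])
        bw = bin_width if bin_width is not None else 1.5
        profiles = [radial_profile(f.tht, radii, bw) for f in frames]
        mean_intensity = np.array([f.global_tht for f in frames])
        source = "sim-frames"

    if max_mode not in ("movie", "frame"):
        raise ValueError("max_mode must be 'movie' or 'frame'")
    min_r = bw if min_radius is None else min_radius
    # Restrict to the first-peak event: the habituated plateau re-brightens
    # the whole biofilm and is not part of the travelling wave. The event
    # window runs to the quiescent trough of the mean intensity that
    # follows its global maximum.
    if mean_intensity.size >= 3:
        i_peak = int(np.argmax(mean_intensity))
        i_trough = i_peak + int(np.argmin(mean_intensity[i_peak:]))
        if i_trough > i_peak:
            profiles = profiles[: i_trough + 1]
            times_arr = times_arr[: i_trough + 1]
    reference = None
    if max_mode == "movie":
        frame_maxes = [
            np.nanmax(m) if np.any(~np.isnan(m)) else -np.inf
            for _, m in profiles
        ]
        reference = float(max(frame_maxes))
        if not np.isfinite(reference) or reference <= 0:
            raise ValueError(
                "no wavefront detected: no frame exceeds the threshold"
            )
    R_t = np.array([
        _frame_radius(c, m, threshold, reference_max=reference)
        for c, m in profiles
    ])

    valid = ~np.isnan(R_t)
    if not np.any(valid):
        raise ValueError("no wavefront detected: no frame exceeds the threshold")

    first = int(np.argmax(valid))
    # the front exists from the first bright frame until detection is lost
    lost = np.where(~valid[first:])[0]
    last = first + (int(lost[0]) if lost.size else valid.size - first)
    t_seg = times_arr[first:last]
    R_seg = R_t[first:last]

    i_max = int(np.argmax(R_seg))
    tracks: list[WavefrontTrack] = []
    out_keep = R_seg[: i_max + 1] >= min_r
    if np.any(out_keep):
        tracks.append(
            WavefrontTrack(
                times=t_seg[: i_max + 1][out_keep] - t_seg[0],
                R=R_seg[: i_max + 1][out_keep],
                phase="centrifugal",
                source=source,
            )
        )
    # The collapse ends at the post-maximum minimum of R; later frames
    # belong to the habituated re-brightening and are not part of the wave.
    # Collapse onset is when the front has receded a resolvable distance
    # (one bin width) from the peak radius: the slow turn-around at the
    # maximum is below the spatial resolution of the shell binning, the
    # same discretization-artifact exclusion applied near R = 0.
    R_in = R_seg[i_max:]
    t_in = t_seg[i_max:]
    if R_in.size >= 2:
        i_min = int(np.argmin(R_in))
        if i_min >= 1:
            R_in = R_in[: i_min + 1]
            t_in = t_in[: i_min + 1]
            travelled = R_seg[i_max] - R_in
            in_keep = (travelled >= min_r) & (R_in >= min_r)
            if int(np.sum(in_keep)) >= 2:
                t_kept = t_in[in_keep]
                tracks.append(
                    WavefrontTrack(
                        times=t_kept - t_kept[0],
                        R=R_in[in_keep],
                        phase="centripetal",
                        source=source,
                    )
                )
    return tracks


def _power_law_residuals(theta: np.ndarray, t: np.ndarray, R2: np.ndarray):
    rc2, b, gamma = theta
    tg = np.power(np.maximum(t, 0.0), gamma)
    return rc2 + b * tg - R2


def _power_law_jac(theta: np.ndarray, t: np.ndarray, R2: np.ndarray):
    _, b, gamma = theta
    tpos = np.maximum(t, 1e-300)
    tg = np.power(tpos, gamma)
    J = np.empty((t.size, 3))
    J[:, 0] = 1.0
    J[:, 1] = tg
    J[:, 2] = np.where(t > 0, b * tg * np.log(tpos), 0.0)
    return J


def fit_power_law(track: WavefrontTrack, gamma_starts: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5)) -> PowerLawFit:
    """Nonlinear least squares of R^2 against Rc^2 + b t^gamma.

    Levenberg-Marquardt-style trust-region fit on the squared radius with
    an analytic Jacobian, multi-started over ``gamma_starts`` to avoid
    local minima (lowest residual wins, ties broken toward smaller gamma).
    Rc^2 is constrained non-negative. An overall decreasing track (the
    centripetal collapse) is fitted with a negative prefactor b, so the
    intercept is the radius at collapse onset. Parameter SDs come from the
    residual covariance; times are shifted so the phase starts at t = 0.

    Raises
    ------
    ValueError
        For fewer than 4 points.
    RuntimeError
        On non-convergence of every start (reports the final residual).
    """
    if len(track) < 4:
        raise ValueError(f"power-law fit needs >= 4 points, got {len(track)}")
    t = track.times - track.times[0]
    R2 = track.R**2

    scale = max(R2.max(), 1.0)
    t_span = max(t.max(), 1e-9)
    # a collapsing (centripetal) track has decreasing R^2: fit with b < 0
    decreasing = R2[-1] < R2[0]
    b_sign = -1.0 if decreasing else 1.0
    b_bounds = (-np.inf, 0.0) if decreasing else (0.0, np.inf)
    best = None
    last_residual = math.inf
    for g0 in sorted(gamma_starts):
        b0 = abs(R2.max() - R2.min()) / t_span**g0 if t_span > 0 else 1.0
        x0 = np.array([max(R2[0 if decreasing else np.argmin(R2)], 0.0),
                       b_sign * max(b0, 1e-9), g0])
        try:
            res = least_squares(
                _power_law_residuals,
                x0,
                jac=_power_law_jac,
                args=(t, R2),
                bounds=([0.0, b_bounds[0], 1e-6],
                        [np.inf, b_bounds[1], 10.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        last_residual = float(np.linalg.norm(res.fun))
        if not res.success:
            continue
        cost = float(res.cost)
        if best is None or cost < best[0] - 1e-12 * scale**2 or (
            abs(cost - best[0]) <= 1e-12 * scale**2 and res.x[2] < best[1].x[2]
        ):
            best = (cost, res)
    if best is None:
        raise RuntimeError(
            f"power-law fit failed to converge; final residual {last_residual:.4g}"
        )
    res = best[1]
    rc2, b, gamma = res.x
    n, k = len(t), 3
    dof = max(n - k, 1)
    s2 = 2.0 * res.cost / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sds = np.full(3, np.nan)
    rc = math.sqrt(max(rc2, 0.0))
    # SD of Rc from SD of Rc^2 by the delta method (undefined at Rc = 0)
    rc_sd = sds[0] / (2.0 * rc) if rc > 1e-12 else float(np.sqrt(sds[0])) if np.isfinite(sds[0]) else np.nan
    return PowerLawFit(
        Rc=rc, b=float(b), gamma=float(gamma),
        Rc_sd=float(rc_sd), b_sd=float(sds[1]), gamma_sd=float(sds[2]),
        residual_norm=float(np.linalg.norm(res.fun)),
        n_points=n, phase=track.phase,
    )


TRANSPORT_CLASSES = (
    "subdiffusive",
    "diffusive",
    "superdiffusive subballistic",
    "ballistic",
    "super-ballistic",
)


def classify_transport(gamma: float) -> str:
    """Transport class of an anomalous exponent.

    Exhaustive, disjoint partition of (0, inf): gamma < 1 subdiffusive,
    gamma = 1 diffusive, 1 < gamma < 2 superdiffusive subballistic,
    gamma = 2 ballistic, gamma > 2 super-ballistic.
    """
    if not math.isfinite(gamma) or gamma <= 0:
        raise ValueError("gamma must be a positive finite number")
    if gamma < 1.0:
        return "subdiffusive"
    if gamma == 1.0:
        return "diffusive"
    if gamma < 2.0:
        return "superdiffusive subballistic"
    if gamma == 2.0:
        return "ballistic"
    return "super-ballistic"


def velocity_curvature(
    track: WavefrontTrack,
    smoothing_window: int = 5,
    curvature_convention: str = "2/R",
) -> VelocityProfile:
    """Front velocity v = dR/dt and curvature kappa along a track.

    R(t) is smoothed with a ``smoothing_window``-point moving average, the
    velocity computed by central differences, and the curvature taken as
    2/R (mean curvature of a sphere; pass "1/R" for the 2D-literature
    convention). Frames with R = 0 are excluded with a warning (curvature
    diverges there).
    """
    if curvature_convention not in ("1/R", "2/R"):
        raise ValueError("curvature_convention must be '1/R' or '2/R'")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    if len(track) < smoothing_window + 2:
        raise ValueError(
            f"track has {len(track)} points; need >= smoothing_window + 2 "
            f"= {smoothing_window + 2}"
        )
    R = track.R.astype(float)
    t = track.times.astype(float)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        padded = np.pad(R, pad, mode="edge")
        R_s = np.convolve(padded, kernel, mode="valid")[: R.size]
    else:
        R_s = R
    v = np.gradient(R_s, t)
    nonzero = R_s > 0
    if not np.all(nonzero):
        warnings.warn(
            f"excluding {int(np.sum(~nonzero))} frame(s) with R = 0 from the "
            "velocity profile",
            stacklevel=2,
        )
    factor = 2.0 if curvature_convention == "2/R" else 1.0
    kappa = factor / R_s[nonzero]
    return VelocityProfile(
        times=t[nonzero], v=v[nonzero], kappa=kappa, R=R_s[nonzero],
        phase=track.phase,
    )
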