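"""Golden-angle uniform-density spiral trajectories and frame binning.

k-space coordinates are expressed in cycles/mm throughout; angles are degrees
at the interface and radians internally.  Only sample locations are modelled:
gradient waveform design, slew limits and moment nulling do not enter the
reconstruction and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

GOLDEN_ANGLE_DEG = 360.0 * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # 137.50776405...

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "SpiralTrajectory",
    "FrameBinning",
    "design_spiral",
    "golden_angle_sequence",
    "bin_arms_to_frames",
    "density_compensation",
]


class InfeasibleDesignError(ValueError):
    """The requested spiral cannot reach kmax within the readout duration."""


@dataclass
class SpiralTrajectory:
    """A set of rotated copies of one uniform-density spiral arm.

    Attributes
    ----------
    kx, ky : (n_arms, n_samples) float arrays, cycles/mm.
    arm_angles : rotation of each arm in degrees, reduced modulo 360.
    dwell_time : seconds per sample.
    kmax : cycles/mm, the outermost sample radius.
    fov : field of view in mm used for the Nyquist turn spacing.
    n_arms_full : number of arms that together satisfy Nyquist.
    dcf : (n_arms, n_samples) non-negative density-compensation weights in
        (cycles/mm)^2, or None until :func:`density_compensation` is called.
    """

    kx: np.ndarray
    ky: np.ndarray
    arm_angles: np.ndarray
    dwell_time: float
    kmax: float
    fov: float
    n_arms_full: int
    dcf: np.ndarray | None = field(default=None)

    @property
    def n_arms(self) -> int:
        return self.kx.shape[0]

    @property
    def n_samples_per_arm(self) -> int:
        return self.kx.shape[1]

    def subset(self, arm_indices) -> "SpiralTrajectory":
        """View of a subset of arms (e.g. the arms of one frame)."""
        idx = np.asarray(arm_indices)
        return SpiralTrajectory(
            kx=self.kx[idx],
            ky=self.ky[idx],
            arm_angles=self.arm_angles[idx],
            dwell_time=self.dwell_time,
            kmax=self.kmax,
            fov=self.fov,
            n_arms_full=self.n_arms_full,
            dcf=None if self.dcf is None else self.dcf[idx],
        )

    def coords(self) -> np.ndarray:
        """All sample coordinates flattened to (n, 2), cycles/mm."""
        return np.stack([self.kx.ravel(), self.ky.ravel()], axis=-1)


@dataclass
class FrameBinning:
    """Assignment of acquisition arms to fixed-duration real-time frames."""

    frame_duration: float  # ms
    tr: float  # ms
    arms_per_frame: int
    frame_index: np.ndarray  # per arm; -1 for dropped trailing arms

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.max()) + 1 if self.frame_index.size else 0

    def arms_of_frame(self, f: int) -> np.ndarray:
        return np.nonzero(self.frame_index == f)[0]


def golden_angle_sequence(n_arms: int, increment: float = GOLDEN_ANGLE_DEG) -> np.ndarray:
    """Rotation angle of each arm: ``angles[k] = (k * increment) mod 360``.

    The default increment is the 2D golden angle 360*(1 - 1/phi), the standard
    choice for golden-angle spiral/radial dynamic MRI: any contiguous window
    of arms covers angles near-uniformly.
    """
    if n_arms < 1:
        raise ValueError(f"n_arms must be >= 1, got {n_arms}")
    return (np.arange(n_arms) * increment) % 360.0


def design_spiral(
    fov: float,
    resolution: float,
    readout_duration: float,
    dwell_time: float,
    n_arms_full: int,
    n_arms: int | None = None,
    angle_increment: float = GOLDEN_ANGLE_DEG,
    max_kspace_speed: float | None = None,
) -> SpiralTrajectory:
    """Design a golden-angle uniform-density (Archimedean) spiral.

    Parameters
    ----------
    fov : field of view in mm.
    resolution : nominal pixel size in mm; sets ``kmax = 1/(2*resolution)``.
    readout_duration : arm duration in ms.
    dwell_time : seconds per sample.
    n_arms_full : number of arms that together satisfy Nyquist; sets the
        radial spacing between turns of a single arm to ``n_arms_full / fov``
        per full revolution.
    n_arms : number of arms actually generated (defaults to ``n_arms_full``).
    max_kspace_speed : optional limit in cycles/mm/ms; if the design requires
        traversing k-space faster than this, an infeasible-design error is
        raised (a stand-in for gradient amplitude limits).

    Notes
    -----
    The arm is the Archimedean spiral r(theta) = kmax * theta/theta_max with
    constant angular sample density, so the radial spacing between successive
    turns is ``n_arms_full/fov`` and ``n_arms_full`` uniformly rotated arms
    meet the 1/fov Nyquist spacing.
    """
    if fov <= 0 or resolution <= 0 or readout_duration <= 0 or dwell_time <= 0:
        raise ValueError("fov, resolution, readout_duration and dwell_time must be > 0")
    if n_arms_full < 1:
        raise ValueError("n_arms_full must be >= 1")

    kmax = 1.0 / (2.0 * resolution)
    n_samples = int(round(readout_duration * 1e-3 / dwell_time))
    if n_samples < 2:
        raise ValueError("readout too short for the given dwell time")
    # Turn spacing Nyquist condition: n_arms_full interleaved turns spaced 1/fov.
    delta_r = n_arms_full / fov  # radial advance per 2*pi of one arm
    theta_max = 2.0 * np.pi * kmax / delta_r
    if max_kspace_speed is not None:
        # crude speed estimate at the outer edge, cycles/mm per ms
        arc = kmax * theta_max  # total path length scale
        speed = arc / readout_duration
        if speed > max_kspace_speed:
            raise InfeasibleDesignError(
                f"spiral needs ~{speed:.3g} cycles/mm/ms > limit {max_kspace_speed:.3g}"
            )

    theta = np.linspace(0.0, theta_max, n_samples)
    r = kmax * theta / theta_max
    base = r * np.exp(1j * theta)

    if n_arms is None:
        n_arms = n_arms_full
    angles = golden_angle_sequence(n_arms, angle_increment)
    rot = np.exp(1j * np.deg2rad(angles))[:, None]
    arms = base[None, :] * rot
    return SpiralTrajectory(
        kx=np.ascontiguousarray(arms.real),
        ky=np.ascontiguousarray(arms.imag),
        arm_angles=angles,
        dwell_time=dwell_time,
        kmax=kmax,
        fov=fov,
        n_arms_full=n_arms_full,
    )


def bin_arms_to_frames(tr: float, frame_duration: float, n_arms_total: int) -> FrameBinning:
    """Group consecutively acquired arms into fixed-duration frames.

    ``arms_per_frame = floor(frame_duration / tr)``; a trailing group that
    does not fill a frame is dropped (frame_index -1), keeping the temporal
    resolution of every frame identical.
    """
    if tr <= 0 or frame_duration <= 0:
        raise ValueError("tr and frame_duration must be > 0")
    if frame_duration < tr:
        raise ValueError(f"frame_duration {frame_duration} ms < tr {tr} ms")
    apf = int(np.floor(frame_duration / tr))
    n_frames = n_arms_total // apf
    frame_index = np.full(n_arms_total, -1, dtype=np.int64)
    frame_index[: n_frames * apf] = np.repeat(np.arange(n_frames), apf)
    return FrameBinning(
        frame_duration=frame_duration, tr=tr, arms_per_frame=apf, frame_index=frame_index
    )


def _radial_dcf(traj: SpiralTrajectory) -> np.ndarray:
    """|k|-proportional weights with an interior floor, scaled to tile the
    kmax disc: sum of weights = pi * kmax**2 (so that density-compensated
    adjoint reconstruction lands on the image's own intensity scale)."""
    r = np.hypot(traj.kx, traj.ky)
    # floor: half the first-sample radial step, so the DC sample gets the
    # area of a small central disc instead of zero
    nonzero = r[r > 0]
    floor = 0.5 * nonzero.min() if nonzero.size else 1.0
    w = np.maximum(r, floor)
    w *= np.pi * traj.kmax**2 / w.sum()
    return w


def _voronoi_dcf(traj: SpiralTrajectory) -> np.ndarray:
    """Voronoi cell areas of the sample locations, clipped at the kmax disc.

    Unbounded outer cells are clipped by intersecting with a dense polygon of
    the kmax circle via area integration on a bounded Voronoi of the points
    augmented with a ring slightly outside kmax.
    """
    pts = traj.coords()
    shape = traj.kx.shape
    uniq, inverse, counts = np.unique(
        np.round(pts / (1e-9 * max(traj.kmax, 1.0))), axis=0, return_inverse=True, return_counts=True
    )
    if uniq.shape[0] < 2:
        raise ValueError("degenerate trajectory: fewer than 2 distinct sample locations")
    # Bound outer cells with dense guard rings just outside the kmax circle
    # (ring spacing well below 1/fov so no interior cell is left unbounded).
    n_ring = max(360, int(np.ceil(4 * np.pi * traj.kmax * traj.fov)))
    ring_t = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    rings = [np.stack([r * np.cos(ring_t + off), r * np.sin(ring_t + off)], axis=-1)
             for r, off in ((traj.kmax * 1.005, 0.0),
                            (traj.kmax * 1.02, np.pi / n_ring))]
    vor = Voronoi(np.vstack([pts] + rings))
    areas = np.zeros(pts.shape[0])
    for i in range(pts.shape[0]):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            areas[i] = 0.0
            continue
        poly = vor.vertices[region]
        x, y = poly[:, 0], poly[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    # duplicate sample locations share one cell
    dup = counts[inverse] > 1
    if dup.any():
        areas[dup] /= counts[inverse][dup]
    return areas.reshape(shape)


def _pipe_dcf(traj: SpiralTrajectory, n_iter: int = 20) -> np.ndarray:
    """Pipe-Menon iterative weights: w <- w / (P P^T w) until the gridding-
    kernel-convolved sampling density is flat, normalized to the disc area.
    Makes the density-compensated normal operator close to the identity even
    for heavily undersampled arm subsets."""
    from .encoding import NufftPlan  # deferred: encoding imports this module

    grid = max(int(round(2.0 * traj.kmax * traj.fov)), 8)
    plan = NufftPlan(traj.coords(), grid, traj.fov / grid)
    w = np.ones(plan.n)
    for _ in range(n_iter):
        dens = plan._P.dot(plan._PT.dot(w))
        w /= np.maximum(dens, 1e-12 * dens.max())
    w *= np.pi * traj.kmax**2 / w.sum()
    return w.reshape(traj.kx.shape)


def density_compensation(traj: SpiralTrajectory, method: str = "pipe") -> np.ndarray:
    """Per-sample density-compensation weights in (cycles/mm)^2.

    method='pipe' (default): Pipe-Menon iterative equalization of the
    kernel-convolved sampling density (robust for undersampled frame
    subsets).  method='radial': analytic |k|-proportional weights
    (uniform-density spiral geometry).  method='voronoi': Voronoi cell areas
    clipped at the kmax disc (slower, geometry-exact).  All are normalized so
    the weights tile the kmax disc.  The result is also stored on
    ``traj.dcf``.
    """
    pts = traj.coords()
    if np.unique(np.round(pts, 12), axis=0).shape[0] < 2:
        raise ValueError("degenerate trajectory: fewer than 2 distinct sample locations")
    if method == "radial":
        w = _radial_dcf(traj)
    elif method == "voronoi":
        w = _voronoi_dcf(traj)
    elif method == "pipe":
        w = _pipe_dcf(traj)
    else:
        raise ValueError(f"unknown density-compensation method {method!r}")
    if not np.all(np.isfinite(w)) or (w < 0).any():
        raise ValueError("density compensation produced invalid weights")
    traj.dcf = w
    return w
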