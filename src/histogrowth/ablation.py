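"""Laser-ablation analytics: ellipse fitting of excised discs, Hencky
(true) strain along the AP/DV axes, recoil velocity and relaxation time,
and single-junction recoil.

Conventions: x is the anterior-posterior (AP) axis, y dorsal-ventral
(DV); axis "lengths" are full lengths (diameters), matching the annulus
diameters used to cut; times in seconds, lengths in microns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from skimage.measure import EllipseModel

__all__ = ["EllipseFit", "RecoilSeries", "fit_ellipse",
           "lab_frame_deformation", "hencky_strain", "recoil_series",
           "relaxation_time", "junction_recoil"]


@dataclass
class EllipseFit:
    """A fitted ellipse: center, shape tensor and principal axes.

    The shape tensor is ``M = R diag(a^2, b^2) R^T`` (a >= b the
    semi-axes, R the rotation by the orientation angle); its eigenpairs
    are exactly the squared semi-axes and principal directions.
    """

    center: tuple[float, float]
    shape_tensor: np.ndarray
    semi_axes: tuple[float, float]
    orientation_deg: float


@dataclass
class RecoilSeries:
    """Axis-length time course of a relaxing excised disc."""

    times: np.ndarray            # s, one per frame
    axis_length: np.ndarray      # um, one per frame
    recoil_velocity: np.ndarray  # um/s, one per frame interval (n-1)
    relaxation_time: Optional[float] = None  # s; None if undefined


def fit_ellipse(points) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    ``points`` is an (n, 2) array of boundary coordinates, n >= 5 and
    not collinear.  Axes and orientation come from the fitted conic; the
    orientation is the angle of the long axis from the x (AP) axis,
    folded into (-90, 90] degrees.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need >= 5 (x, y) boundary points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) boundary points")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed on the supplied outline")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not all(map(math.isfinite, (xc, yc, a, b, theta))):
        raise ValueError("ellipse fit returned non-finite parameters")
    if b > a:  # normalize so a is the long semi-axis
        a, b = b, a
        theta += math.pi / 2.0
    theta = math.atan2(math.sin(theta), math.cos(theta))
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    m = rot @ np.diag([a * a, b * b]) @ rot.T
    return EllipseFit(center=(float(xc), float(yc)), shape_tensor=m,
                      semi_axes=(float(a), float(b)),
                      orientation_deg=math.degrees(theta))


def lab_frame_deformation(ellipse: EllipseFit) -> tuple[float, float, float]:
    """Axis lengths of the ellipse along the lab AP (x) and DV (y) axes.

    The shape tensor is already expressed in the lab frame (it was built
    as R diag(a^2, b^2) R^T); its diagonal entries give the squared
    semi-axis extents along x and y, the normalized off-diagonal entry
    is reported as the shear component.  Returns ``(L_ap, L_dv, shear)``
    with L full lengths (diameters).
    """
    m = ellipse.shape_tensor
    l_ap = 2.0 * math.sqrt(m[0, 0])
    l_dv = 2.0 * math.sqrt(m[1, 1])
    shear = float(m[0, 1] / math.sqrt(m[0, 0] * m[1, 1]))
    return l_ap, l_dv, shear


def hencky_strain(length_nonablated: float, length_relaxed: float) -> float:
    """Hencky (true) strain ``eps = ln(L / Lr)``.

    Positive when the tissue was stretched (it relaxes inward after the
    cut, Lr < L).  Antisymmetric under exchange of the two lengths and
    additive along a deformation path.
    """
    if length_nonablated <= 0 or length_relaxed <= 0:
        raise ValueError("lengths must be > 0")
    return math.log(length_nonablated / length_relaxed)


def recoil_series(lengths, dt: float, times=None,
                  signed: bool = True) -> RecoilSeries:
    """Frame-to-frame recoil velocity of an axis-length time course.

    ``velocity_i = (L_{i+1} - L_i) / dt``; a relaxing (previously
    stretched) disc shrinks, so signed velocities are negative.  With
    ``signed=False`` magnitudes are reported.  The relaxation time is
    fitted lazily by :func:`relaxation_time` and attached when at least
    three intervals are available.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 2:
        raise ValueError("need >= 2 frames")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if times is None:
        times = np.arange(lengths.size) * dt
    vel = np.diff(lengths) / dt
    if not signed:
        vel = np.abs(vel)
    series = RecoilSeries(times=np.asarray(times, float),
                          axis_length=lengths, recoil_velocity=vel)
    if lengths.size >= 4:
        series.relaxation_time = relaxation_time(series)
    return series


def relaxation_time(series: RecoilSeries,
                    slope_tol: float = 1e-12) -> Optional[float]:
    """Relaxation time from the velocity-versus-length line.

    Fits an ordinary least-squares straight line to the signed recoil
    velocity against the mid-interval axis length (velocity is an
    interval quantity); for Kelvin-Voigt relaxation
    ``L(t) = Linf + (L0 - Linf) exp(-t/tau)`` the slope is -1/tau, so
    tau = 1/|slope|.  Returns None when the slope magnitude is below
    ``slope_tol`` (constant-velocity series: tau undefined).
    """
    lengths = series.axis_length
    vel = np.diff(lengths) / np.diff(series.times)
    mid = 0.5 * (lengths[:-1] + lengths[1:])
    if mid.size < 3 or np.ptp(mid) == 0:
        return None
    slope, _intercept = np.polyfit(mid, vel, 1)
    if abs(slope) < slope_tol:
        return None
    return float(1.0 / abs(slope))


def junction_recoil(vertex_a, vertex_b, dt: float,
                    mode: str = "first_interval") -> float:
    """Initial recoil speed of a cut junction from its two vertices.

    The vertex separation ``d(t) = |a - b|`` grows after the cut.
    ``mode="first_interval"`` returns the finite difference over the
    first frame interval; ``mode="exponential_fit"`` fits
    ``d(t) = dinf - (dinf - d0) exp(-t/tau)`` and returns the analytic
    initial slope ``(dinf - d0)/tau``, falling back to the first
    interval (with a warning) when the fit does not converge.
    """
    a = np.asarray(vertex_a, float)
    b = np.asarray(vertex_b, float)
    d = np.linalg.norm(a - b, axis=1)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if mode == "first_interval":
        if d.size < 2:
            raise ValueError("need >= 2 frames")
        return float((d[1] - d[0]) / dt)
    if mode != "exponential_fit":
        raise ValueError(f"unknown mode {mode!r}")
    if d.size < 5:
        raise ValueError("need >= 5 frames for exponential_fit")
    t = np.arange(d.size) * dt

    def model(t, dinf, amp, tau):
        return dinf - amp * np.exp(-t / tau)

    try:
        p0 = (float(d[-1]), float(d[-1] - d[0]), float(t[-1] / 3.0))
        popt, _ = optimize.curve_fit(model, t, d, p0=p0, maxfev=5000)
        dinf, amp, tau = popt
        if tau <= 0:
            raise RuntimeError("non-physical tau")
        return float(amp / tau)
    except (RuntimeError, optimize.OptimizeWarning):
        import warnings
        warnings.warn("exponential fit diverged; falling back to "
                      "first_interval estimate")
        return float((d[1] - d[0]) / dt)
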