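"""Physiological post-processing of predicted profiles and fields.

Wall shear stress (WSS) is the product of plasma viscosity and the radial
velocity gradient at the wall, evaluated with a one-sided near-wall finite
difference whose stencil lies inside the cell-free layer (CFL). The CFL is
delineated by the hematocrit threshold H ~= 0.085 separating the cell-rich
core from the plasma layer. Predictions are first passed through a
moving-average filter to remove small-amplitude noise. Profile means and
skewness quantify the cross-sectional bias of u and H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateProfileError
from .prep import Field2D, Profile1D

__all__ = ["WssResult", "CflResult", "ProfileMoments", "filter_prediction",
           "compute_wss_1d", "compute_wss_field", "extract_cfl_1d",
           "extract_cfl_field", "profile_moments", "PLASMA_VISCOSITY",
           "CFL_THRESHOLD"]

#: plasma viscosity (Pa s); a configurable free parameter of the WSS step
PLASMA_VISCOSITY = 1.2e-3
#: hematocrit threshold delineating the CFL/core interface
CFL_THRESHOLD = 0.085


@dataclass
class WssResult:
    """Wall shear stress in Pa: per diameter end (1D) or per circumference
    angle (2D fields)."""

    wall_0: float | None = None       # at xi = 0
    wall_1: float | None = None       # at xi = 1
    angles_deg: np.ndarray | None = None
    wss_theta: np.ndarray | None = None
    mu: float = PLASMA_VISCOSITY


@dataclass
class CflResult:
    """Cell-free-layer geometry in micrometers."""

    width_0: float | None = None
    width_1: float | None = None
    angles_deg: np.ndarray | None = None
    r_cfl: np.ndarray | None = None   # interface radius per angle
    threshold: float = CFL_THRESHOLD
    degenerate: bool = False


@dataclass
class ProfileMoments:
    mean: float
    skewness: float


# ---------------------------------------------------------------------------

def filter_prediction(p: Profile1D | Field2D, window: int = 5):
    """Moving-average filter (window must be odd; 1 = identity).

    1D: along xi with truncated, renormalized windows at the ends.
    2D: separable within the mask, renormalized at mask edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return p
    kernel = np.ones(window)
    if isinstance(p, Profile1D):
        num = np.convolve(p.values, kernel, mode="same")
        den = np.convolve(np.ones_like(p.values), kernel, mode="same")
        return Profile1D(p.xi.copy(), num / den, p.kind, p.orientation)
    m = p.mask.astype(float)
    num = p.grid * m
    for axis in (0, 1):
        num = ndimage.convolve1d(num, kernel, axis=axis, mode="constant")
    den = m.copy()
    for axis in (0, 1):
        den = ndimage.convolve1d(den, kernel, axis=axis, mode="constant")
    out = np.where(p.mask, num / np.maximum(den, 1e-12), 0.0)
    return Field2D(out, p.mask.copy(), p.delta_beta, p.kind)


def _one_sided_gradient(values: np.ndarray, h: float,
                        stencil_points: int) -> float:
    """One-sided first-derivative estimate at index 0 with uniform spacing h
    (2 points: first order; 3 points: second order)."""
    if stencil_points == 2:
        return (values[1] - values[0]) / h
    if stencil_points == 3:
        return (-3.0 * values[0] + 4.0 * values[1] - values[2]) / (2.0 * h)
    # general: fit a degree-(m-1) polynomial through the m nearest points
    x = np.arange(stencil_points) * h
    coeffs = np.polynomial.polynomial.polyfit(x, values[:stencil_points],
                                              stencil_points - 1)
    return float(coeffs[1])


def compute_wss_1d(u: Profile1D, r_um: float, mu: float = PLASMA_VISCOSITY,
                   stencil_points: int = 3) -> WssResult:
    """WSS at both diameter ends of a velocity profile.

    The radial gradient is a one-sided finite difference over the
    ``stencil_points`` collocation points nearest each wall (default 3,
    second order), converted from xi-units via dr = 2 R dxi.
    """
    if stencil_points < 2:
        raise ValueError("stencil_points must be >= 2")
    n = u.n
    if stencil_points > n // 2:
        raise ValueError("stencil extends past the mid-profile")
    h_xi = float(u.xi[1] - u.xi[0])
    h_r = 2.0 * r_um * h_xi * 1e-6                 # m
    vals = u.values * 1e-3                          # m/s
    g0 = _one_sided_gradient(vals, h_r, stencil_points)
    g1 = _one_sided_gradient(vals[::-1], h_r, stencil_points)
    return WssResult(wall_0=mu * abs(g0), wall_1=mu * abs(g1), mu=mu)


def compute_wss_field(u: Field2D, r_um: float, mu: float = PLASMA_VISCOSITY,
                      n_angles: int = 64, stencil_points: int = 3
                      ) -> WssResult:
    """WSS along the vessel circumference from a velocity field.

    For each ray from the center, u is interpolated (bilinear) onto radial
    sample points spaced by one grid cell starting at the wall (where u = 0
    by no-slip), and the near-wall one-sided gradient is taken as in
    :func:`compute_wss_1d`.
    """
    ng = u.ng
    c = (ng - 1) / 2.0
    cell = 2.0 / ng                     # grid cell in lumen-radius units
    angles = np.arange(n_angles) / n_angles * 360.0
    th = np.deg2rad(angles)
    radii = 1.0 - cell * np.arange(stencil_points)   # r/R from the wall in
    if radii[-1] <= 0:
        raise ValueError("stencil reaches past the vessel center")
    # sample points in grid-index coordinates
    xs = np.outer(np.cos(th), radii)
    ys = np.outer(np.sin(th), radii)
    jj = c + xs * (ng / 2.0)
    ii = c + ys * (ng / 2.0)
    vals = ndimage.map_coordinates(u.grid, [ii, jj], order=1, mode="nearest")
    vals[:, 0] = 0.0                    # exact no-slip at the wall
    h_r = cell * r_um * 1e-6            # m
    wss = np.empty(n_angles)
    for a in range(n_angles):
        g = _one_sided_gradient(vals[a] * 1e-3, h_r, stencil_points)
        wss[a] = mu * abs(g)
    return WssResult(angles_deg=angles, wss_theta=wss, mu=mu)


def _crossing_from_wall(values: np.ndarray, xi: np.ndarray,
                        threshold: float) -> float | None:
    """First linear-interpolated crossing of ``threshold`` moving inward
    from index 0; returns xi of the crossing or None."""
    for i in range(len(values) - 1):
        v0, v1 = values[i], values[i + 1]
        if v0 < threshold <= v1:
            f = (threshold - v0) / (v1 - v0)
            return float(xi[i] + f * (xi[i + 1] - xi[i]))
        if v0 >= threshold:
            return float(xi[i])
    return None


def extract_cfl_1d(h: Profile1D, threshold: float = CFL_THRESHOLD,
                   r_um: float | None = None) -> CflResult:
    """CFL width at each diameter end: the distance from the wall to the
    first threshold crossing (linear interpolation between collocation
    points). Widths are in xi-units times the diameter when ``r_um`` is
    given, else in xi units of [0, 1]."""
    scale = 2.0 * r_um if r_um is not None else 1.0
    x0 = _crossing_from_wall(h.values, h.xi, threshold)
    x1 = _crossing_from_wall(h.values[::-1], h.xi, threshold)
    if x0 is None or x1 is None:
        half = 0.5 * scale
        return CflResult(width_0=half, width_1=half, threshold=threshold,
                         degenerate=True)
    return CflResult(width_0=x0 * scale, width_1=x1 * scale,
                     threshold=threshold)


def extract_cfl_field(h: Field2D, threshold: float = CFL_THRESHOLD,
                      n_angles: int = 64, r_um: float | None = None
                      ) -> CflResult:
    """CFL/core interface radius r_cfl(theta): per ray, the outermost inward
    crossing of the threshold. Radii are in units of the lumen radius, or in
    micrometers when ``r_um`` is given."""
    ng = h.ng
    c = (ng - 1) / 2.0
    step = 1.0 / ng
    angles = np.arange(n_angles) / n_angles * 360.0
    th = np.deg2rad(angles)
    radii = np.arange(1.0, 0.0, -step)            # wall -> center, r/R
    xs = np.outer(np.cos(th), radii)
    ys = np.outer(np.sin(th), radii)
    jj = c + xs * (ng / 2.0)
    ii = c + ys * (ng / 2.0)
    vals = ndimage.map_coordinates(h.grid, [ii, jj], order=1, mode="nearest")
    scale = r_um if r_um is not None else 1.0
    r_cfl = np.empty(n_angles)
    degenerate = False
    for a in range(n_angles):
        depth = _crossing_from_wall(vals[a], 1.0 - radii, threshold)
        if depth is None:
            r_cfl[a] = 0.0
            degenerate = True
        else:
            r_cfl[a] = (1.0 - depth) * scale
    return CflResult(angles_deg=angles, r_cfl=r_cfl, threshold=threshold,
                     degenerate=degenerate)


def profile_moments(p: Profile1D) -> ProfileMoments:
    """Mean and skewness of xi with the profile values as an unnormalized
    density: mean = sum(xi w)/sum(w); skewness = standardized third central
    moment. A symmetric profile has skewness 0; the sign follows the tail
    convention: mass concentrated near xi = 0 (tail toward xi = 1) gives
    positive skewness."""
    w = np.asarray(p.values, dtype=float)
    if np.any(w < 0):
        raise ValueError("profile values must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DegenerateProfileError("all-zero profile has no moments")
    xi = p.xi
    mean = float((xi * w).sum() / total)
    m2 = float((((xi - mean) ** 2) * w).sum() / total)
    m3 = float((((xi - mean) ** 3) * w).sum() / total)
    skew = 0.0 if m2 <= 0 else m3 / m2 ** 1.5
    return ProfileMoments(mean=mean, skewness=skew)
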