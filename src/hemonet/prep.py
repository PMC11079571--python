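"""Profile and field preparation for the component models.

The ML models consume fixed-size, consistently oriented data: length-N
(default 56) diameter profiles for the 2D models and Ng x Ng (default 32)
cross-sectional rasters for the 3D models. This module provides

* cubic-spline resampling of raw profiles onto N collocation points,
* penalized spline smoothing (GCV-selected weight by default),
* the apex-first orientation convention for bifurcation daughters,
* rasterization onto the masked lumen grid and rotation augmentation with a
  recorded conditioning angle delta_beta,
* assembly of per-component training samples from rendered ground truth.

Orientation convention: a "global" profile runs from the left wall to the
right wall of the vessel (left/right as seen looking along the flow in the
network plane). A daughter profile in "apex_first" orientation always has
xi = 0 on the apex (flow-divider) side, so the two daughters of one
bifurcation are globally opposite but locally aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import IncompleteComponentError, OrientationError

KIND_VELOCITY = "velocity"
KIND_HEMATOCRIT = "hematocrit"
ORIENT_GLOBAL = "global"
ORIENT_APEX = "apex_first"

DEFAULT_N = 56
DEFAULT_NG = 32


@dataclass
class Profile1D:
    """A length-N sample of u (mm/s) or H (-) along a vessel diameter.

    ``xi`` is the local diameter coordinate on [0, 1].
    """

    xi: np.ndarray
    values: np.ndarray
    kind: str = KIND_VELOCITY
    orientation: str = ORIENT_GLOBAL

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.xi.ndim != 1 or self.xi.shape != self.values.shape:
            raise ValueError("xi and values must be 1D arrays of equal length")
        if not np.all(np.diff(self.xi) > 0):
            raise ValueError("xi must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if self.kind == KIND_HEMATOCRIT and (
                self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12):
            raise ValueError("hematocrit values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class Field2D:
    """An Ng x Ng cross-sectional raster with a circular lumen mask.

    ``delta_beta`` records the cumulative rotation (degrees) applied to the
    field relative to its native orientation; it is fed to the 3D models as a
    conditioning scalar.
    """

    grid: np.ndarray
    mask: np.ndarray
    delta_beta: float = 0.0
    kind: str = KIND_VELOCITY

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match grid")
        if np.any(self.grid[~self.mask] != 0.0):
            raise ValueError("values outside the lumen mask must be 0")

    @property
    def ng(self) -> int:
        return self.grid.shape[0]


def lumen_mask(ng: int) -> np.ndarray:
    """Boolean disc of radius ng/2 centered on the grid center (cell-center
    convention)."""
    c = (np.arange(ng) + 0.5) / ng * 2.0 - 1.0
    xx, yy = np.meshgrid(c, c, indexing="xy")
    return xx * xx + yy * yy <= 1.0


@dataclass
class ComponentSample:
    """One training/evaluation sample for a component model.

    ``scalars`` hold the geometric conditioning inputs: ``a1``/``a2`` =
    (d1/dm)^2, (d2/dm)^2 for 2D junction models, ``r1``/``r2`` = d1/dm, d2/dm
    for 3D junction models, ``d``/``l`` for vessels and ``delta_beta`` for all
    3D samples.
    """

    component_kind: str
    component_id: str
    scalars: dict[str, float]
    inputs: dict[str, Profile1D | Field2D]
    outputs: dict[str, Profile1D | Field2D]

    def __post_init__(self):
        if self.component_kind not in ("vessel", "bifurcation", "merger"):
            raise ValueError(f"unknown component kind {self.component_kind!r}")
        for key in ("a1", "a2", "r1", "r2"):
            v = self.scalars.get(key)
            if v is not None and not 0.0 < v < 4.0:
                raise ValueError(f"scalar ratio {key}={v} outside (0, 4)")


# ---------------------------------------------------------------------------
# 1D operations
# ---------------------------------------------------------------------------

def resample_profile(raw_xi: np.ndarray, raw_values: np.ndarray,
                     n: int = DEFAULT_N, kind: str = KIND_VELOCITY,
                     orientation: str = ORIENT_GLOBAL) -> Profile1D:
    """Resample a raw profile onto ``n`` uniform collocation points on [0, 1]
    with a not-a-knot cubic spline. Endpoints are preserved exactly."""
    raw_xi = np.asarray(raw_xi, dtype=float)
    raw_values = np.asarray(raw_values, dtype=float)
    if raw_xi.size < 4:
        raise ValueError("at least 4 points are required for cubic resampling")
    if not np.all(np.diff(raw_xi) > 0):
        raise ValueError("raw_xi must be strictly increasing")
    spl = CubicSpline(raw_xi, raw_values, bc_type="not-a-knot")
    xi = np.linspace(0.0, 1.0, n)
    values = spl(xi)
    # endpoints exact if the raw grid spans [0, 1]
    if raw_xi[0] == 0.0:
        values[0] = raw_values[0]
    if raw_xi[-1] == 1.0:
        values[-1] = raw_values[-1]
    if kind == KIND_HEMATOCRIT:
        values = np.clip(values, 0.0, 1.0)
    return Profile1D(xi=xi, values=values, kind=kind, orientation=orientation)


def smooth_profile(p: Profile1D, lambda_s: float | None = None) -> Profile1D:
    """Penalized smoothing-spline fit evaluated at the profile's own
    collocation points.

    ``lambda_s`` is the roughness-penalty weight; ``None`` selects it by
    generalized cross-validation, ``0`` returns the input unchanged.
    """
    if lambda_s is not None and lambda_s < 0:
        raise ValueError("lambda_s must be >= 0")
    if lambda_s == 0:
        return replace(p)
    # center for conditioning: a constant profile is reproduced exactly
    mean = float(p.values.mean())
    spl = make_smoothing_spline(p.xi, p.values - mean, lam=lambda_s)
    values = spl(p.xi) + mean
    if p.kind == KIND_HEMATOCRIT:
        values = np.clip(values, 0.0, 1.0)
    return Profile1D(xi=p.xi.copy(), values=values, kind=p.kind,
                     orientation=p.orientation)


def orient_daughter(p: Profile1D, apex_side: str) -> Profile1D:
    """Map a globally oriented daughter profile to the apex-first convention
    (xi = 0 on the apex side)."""
    if p.orientation == ORIENT_APEX:
        raise OrientationError("profile is already apex-first")
    if apex_side not in ("left", "right"):
        raise ValueError("apex_side must be 'left' or 'right'")
    if apex_side == "left":
        return Profile1D(p.xi.copy(), p.values.copy(), p.kind, ORIENT_APEX)
    return Profile1D(1.0 - p.xi[::-1], p.values[::-1].copy(), p.kind,
                     ORIENT_APEX)


def orient_to_global(p: Profile1D, apex_side: str) -> Profile1D:
    """Inverse of :func:`orient_daughter`."""
    if p.orientation == ORIENT_GLOBAL:
        raise OrientationError("profile is already global")
    if apex_side == "left":
        return Profile1D(p.xi.copy(), p.values.copy(), p.kind, ORIENT_GLOBAL)
    return Profile1D(1.0 - p.xi[::-1], p.values[::-1].copy(), p.kind,
                     ORIENT_GLOBAL)


# ---------------------------------------------------------------------------
# 2D operations
# ---------------------------------------------------------------------------

def rasterize_cross_section(f: Callable[[np.ndarray, np.ndarray], np.ndarray],
                            ng: int = DEFAULT_NG,
                            kind: str = KIND_VELOCITY) -> Field2D:
    """Sample ``f(x, y)`` at cell centers of an ng x ng grid covering the
    lumen ([-1, 1]^2 in normalized coordinates, lumen radius 1) and mask to
    the disc."""
    if ng < 8:
        raise ValueError("ng must be >= 8")
    c = (np.arange(ng) + 0.5) / ng * 2.0 - 1.0
    xx, yy = np.meshgrid(c, c, indexing="xy")
    mask = lumen_mask(ng)
    grid = np.where(mask, f(xx, yy), 0.0)
    return Field2D(grid=grid, mask=mask, delta_beta=0.0, kind=kind)


def rotate_augment(f: Field2D, delta_beta: float) -> Field2D:
    """Rotate the field about the grid center by ``delta_beta`` degrees
    (counter-clockwise, bilinear interpolation), re-mask to the lumen, and
    record the cumulative rotation angle."""
    if delta_beta == 0.0:
        return Field2D(f.grid.copy(), f.mask.copy(), f.delta_beta, f.kind)
    ng = f.ng
    c = (ng - 1) / 2.0
    th = np.deg2rad(delta_beta)
    ii, jj = np.meshgrid(np.arange(ng), np.arange(ng), indexing="ij")
    # inverse rotation of target coordinates (rows = y image axis)
    x = jj - c
    y = ii - c
    src_j = c + np.cos(th) * x + np.sin(th) * y
    src_i = c - np.sin(th) * x + np.cos(th) * y
    grid = ndimage.map_coordinates(f.grid, [src_i, src_j], order=1,
                                   mode="nearest")
    grid[~f.mask] = 0.0
    if f.kind == KIND_HEMATOCRIT:
        grid = np.clip(grid, 0.0, 1.0)
    return Field2D(grid=grid, mask=f.mask.copy(),
                   delta_beta=f.delta_beta + delta_beta, kind=f.kind)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _gt(fields: Mapping, vessel_id: str, end: str):
    try:
        return fields[(vessel_id, end)]
    except KeyError:
        raise IncompleteComponentError(
            f"no ground truth for vessel {vessel_id!r} at {end!r}") from None


def _profile_pair(gt) -> tuple[Profile1D, Profile1D]:
    return gt.profile_u, gt.profile_h


def _field_pair(gt) -> tuple[Field2D, Field2D]:
    return gt.u, gt.h


def build_dataset(net, flow, fields: Mapping, mode: str = "2d",
                  augment_count: int = 0, seed: int = 0,
                  delta_beta_range: tuple[float, float] = (-45.0, 45.0),
                  component_kinds: Sequence[str] = ("vessel", "bifurcation",
                                                    "merger"),
                  max_per_kind: int | None = None,
                  extra_samples: Sequence[ComponentSample] = ()):
    """Assemble :class:`ComponentSample` lists from rendered ground truth.

    ``fields`` maps ``(vessel_id, "start"|"end")`` to rendered ground-truth
    objects (see ``synthetic.render_network``). For ``mode="3d"`` each base
    sample is accompanied by ``augment_count`` rotated copies with the
    rotation angle recorded in the ``delta_beta`` scalar; 2D samples carry
    the mid-plane diameter profiles and are not augmented.

    Returns a dict ``{"vessel": [...], "bifurcation": [...], "merger": [...]}``.
    """
    from . import synthetic as sv  # local import to avoid a cycle

    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    rng = np.random.default_rng(seed)
    out: dict[str, list[ComponentSample]] = {k: [] for k in component_kinds}

    vessels = {v.id: v for v in net.vessels}

    def add(kind, cid, scalars, inputs, outputs):
        if mode == "2d":
            out[kind].append(ComponentSample(kind, cid, scalars, inputs,
                                             outputs))
            return
        base = ComponentSample(kind, cid, dict(scalars, delta_beta=0.0),
                               inputs, outputs)
        out[kind].append(base)
        for _ in range(augment_count):
            db = float(rng.uniform(*delta_beta_range))
            rin = {k: rotate_augment(v, db) for k, v in inputs.items()}
            rout = {k: rotate_augment(v, db) for k, v in outputs.items()}
            out[kind].append(ComponentSample(
                kind, cid, dict(scalars, delta_beta=db), rin, rout))

    pair = _profile_pair if mode == "2d" else _field_pair

    if "vessel" in component_kinds:
        vlist = [v for v in net.vessels]
        if max_per_kind is not None and len(vlist) > max_per_kind:
            idx = rng.choice(len(vlist), size=max_per_kind, replace=False)
            vlist = [vlist[i] for i in sorted(idx)]
        for v in vlist:
            u0, h0 = pair(_gt(fields, v.id, "start"))
            u1, h1 = pair(_gt(fields, v.id, "end"))
            add("vessel", v.id, {"d": v.d_um, "l": v.l_um},
                {"u_in": u0, "H_in": h0}, {"u_out": u1, "H_out": h1})

    if "bifurcation" in component_kinds:
        for node in net.nodes:
            if node.kind != "bifurcation":
                continue
            mother = net.in_vessels(node.id)[0]
            (left, right), apex = sv.bifurcation_daughters(net, node.id)
            um, hm = pair(_gt(fields, mother.id, "end"))
            outs = {}
            for tag, dv in (("1", left), ("2", right)):
                uu, hh = pair(_gt(fields, dv.id, "start"))
                if mode == "2d":
                    uu = orient_daughter(uu, apex[dv.id])
                    hh = orient_daughter(hh, apex[dv.id])
                outs[f"u_{tag}"] = uu
                outs[f"H_{tag}"] = hh
            if mode == "2d":
                scalars = {"a1": (left.d_um / mother.d_um) ** 2,
                           "a2": (right.d_um / mother.d_um) ** 2}
            else:
                scalars = {"r1": left.d_um / mother.d_um,
                           "r2": right.d_um / mother.d_um}
            add("bifurcation", node.id, scalars, {"u_m": um, "H_m": hm}, outs)

    if "merger" in component_kinds:
        for node in net.nodes:
            if node.kind != "merger":
                continue
            (left, right) = sv.merger_parents(net, node.id)
            child = net.out_vessels(node.id)[0]
            u1, h1 = pair(_gt(fields, left.id, "end"))
            u2, h2 = pair(_gt(fields, right.id, "end"))
            uc, hc = pair(_gt(fields, child.id, "start"))
            if mode == "2d":
                scalars = {"a1": (left.d_um / child.d_um) ** 2,
                           "a2": (right.d_um / child.d_um) ** 2}
            else:
                scalars = {"r1": left.d_um / child.d_um,
                           "r2": right.d_um / child.d_um}
            add("merger", node.id, scalars,
                {"u_1": u1, "H_1": h1, "u_2": u2, "H_2": h2},
                {"u_out": uc, "H_out": hc})

    for s in extra_samples:
        if s.component_kind in out:
            out[s.component_kind].append(s)
    return out
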