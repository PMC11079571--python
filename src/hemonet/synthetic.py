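"""Synthetic microvascular networks with RBC-suspension-like ground truth.

High-fidelity, RBC-resolved simulations of network blood flow are far too
expensive to regenerate, so this module emulates the *statistical structure*
of their time-averaged output with a parametric generator:

* binary-cascade networks of vessels, bifurcations and mergers whose
  diameters taper by a per-generation ratio (Horton-like);
* a linear (Poiseuille-resistance) flow solve with exact flow conservation;
* plasma-skimming phase separation at bifurcations (S-shaped RBC-flux split)
  with exact RBC-flux conservation;
* blunted, skewed velocity profiles u = U_max (1-(r/R)^k)(1 + lam_u (r/R)
  cos(theta)) and core-concentrated hematocrit with a sigmoidal cell-free
  layer whose interface radius r_c(theta) = R - delta (1 - lam_H cos(theta))
  is biased toward the bifurcation apex;
* exponential relaxation of the skew amplitudes along each vessel,
  lam(s) = lam(0) exp(-s / (10 d)).

Randomness enters through the geometry draws and the shape parameters of
*inlet* vessels; transfer across junctions is deterministic and smooth so
that every component's input -> output map is learnable. All operations are
reproducible for a fixed seed.

Conventions: the cross-sectional frame is viewed looking along the flow;
"left" is the left-hand wall in the network plane. Skew amplitudes are
signed with positive = toward the left wall. theta = 0 points to the left
wall. Velocities are in mm/s, lengths in micrometers, flows in um^3/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import TopologyError
from .prep import (Field2D, KIND_HEMATOCRIT, KIND_VELOCITY, Profile1D,
                   lumen_mask)

__all__ = [
    "SyntheticConfig", "Node", "Vessel", "NetworkSpec", "VesselShape",
    "FlowState", "GroundTruthField", "generate_network", "solve_flow",
    "phase_separation_split", "render_fields", "render_network",
    "bifurcation_daughters", "merger_parents", "default_inlet_flow",
]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults are the study conditions."""

    d_inlet_um: float = 24.0
    daughter_ratio: tuple[float, float] = (0.7, 0.9)
    length_over_d: tuple[float, float] = (7.0, 10.0)
    branch_angle_deg: tuple[float, float] = (20.0, 40.0)
    # profile-shape draws at inlet vessels
    k_range: tuple[float, float] = (1.8, 3.2)
    delta_over_r: tuple[float, float] = (0.1, 0.3)
    # junction transfer of shape parameters (deterministic)
    lam_bif: float = 0.8          # daughter lam_H(0) = lam_bif * (1 - a_hat)
    lam_u_ratio: float = 0.6      # |lam_u| / |lam_H|
    lam_merge: float = 0.4        # child lam_H(0) = lam_merge * (q1 - q2)
    relax_length_factor: float = 10.0   # L_relax = factor * d
    # phase separation
    q_low: float = 0.05
    steepness: float = 1.5
    diam_coef: float = 0.5
    h_max: float = 0.95
    # field rendering
    cfl_sharpness: float = 0.05   # interface width w / R
    hem_skew_gain: float = 0.5    # in-core hematocrit skew factor
    noise_frac: float = 0.02      # noise sd as a fraction of the field max
    # inflow
    inlet_velocity_mm_s: float = 2.0
    inlet_hematocrit: float = 0.30


@dataclass
class Node:
    id: str
    kind: str       # inlet | outlet | bifurcation | merger
    x: float
    y: float


@dataclass
class Vessel:
    id: str
    from_node: str
    to_node: str
    d_um: float
    l_um: float
    angle_deg: float   # flow-direction axis angle in the network plane


_DEGREES = {"inlet": (0, 1), "outlet": (1, 0),
            "bifurcation": (1, 2), "merger": (2, 1)}


@dataclass
class NetworkSpec:
    """Directed vascular graph with geometry."""

    nodes: list[Node]
    vessels: list[Vessel]

    def __post_init__(self):
        self._nodes = {n.id: n for n in self.nodes}
        self._in = {n.id: [] for n in self.nodes}
        self._out = {n.id: [] for n in self.nodes}
        for v in self.vessels:
            self._out[v.from_node].append(v)
            self._in[v.to_node].append(v)

    def node(self, node_id: str) -> Node:
        return self._nodes[node_id]

    def in_vessels(self, node_id: str) -> list[Vessel]:
        return self._in[node_id]

    def out_vessels(self, node_id: str) -> list[Vessel]:
        return self._out[node_id]

    def vessel(self, vessel_id: str) -> Vessel:
        for v in self.vessels:
            if v.id == vessel_id:
                return v
        raise KeyError(vessel_id)

    @property
    def inlets(self) -> list[Node]:
        return [n for n in self.nodes if n.kind == "inlet"]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for v in self.vessels:
            g.add_edge(v.from_node, v.to_node, vessel=v.id)
        return g

    def validate(self) -> None:
        for n in self.nodes:
            want = _DEGREES.get(n.kind)
            if want is None:
                raise TopologyError(f"unknown node kind {n.kind!r}")
            got = (len(self._in[n.id]), len(self._out[n.id]))
            if got != want:
                raise TopologyError(
                    f"node {n.id} ({n.kind}) has in/out degree {got}, "
                    f"expected {want}")
        for v in self.vessels:
            if v.d_um <= 0 or v.l_um <= 0:
                raise TopologyError(f"vessel {v.id} has non-positive geometry")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise TopologyError("vascular graph contains a cycle")

    # --- JSON schema: nodes [{id,kind,x,y}], vessels [{id,from,to,...}] ---
    def to_dict(self) -> dict:
        return {
            "nodes": [{"id": n.id, "kind": n.kind, "x": n.x, "y": n.y}
                      for n in self.nodes],
            "vessels": [{"id": v.id, "from": v.from_node, "to": v.to_node,
                         "d_um": v.d_um, "l_um": v.l_um,
                         "angle_deg": v.angle_deg} for v in self.vessels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        nodes = [Node(n["id"], n["kind"], n["x"], n["y"]) for n in d["nodes"]]
        vessels = [Vessel(v["id"], v["from"], v["to"], v["d_um"], v["l_um"],
                          v["angle_deg"]) for v in d["vessels"]]
        return cls(nodes, vessels)


def _wrap(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def bifurcation_daughters(net: NetworkSpec, node_id: str):
    """Order the two daughters of a bifurcation as (left, right) relative to
    the mother's flow direction, and give each daughter's apex side.

    The left daughter sees the flow-dividing apex on its right wall and vice
    versa.
    """
    node = net.node(node_id)
    if node.kind != "bifurcation":
        raise TopologyError(f"{node_id} is not a bifurcation")
    mother = net.in_vessels(node_id)[0]
    d1, d2 = net.out_vessels(node_id)
    r1 = _wrap(d1.angle_deg - mother.angle_deg)
    r2 = _wrap(d2.angle_deg - mother.angle_deg)
    left, right = (d1, d2) if r1 >= r2 else (d2, d1)
    return (left, right), {left.id: "right", right.id: "left"}


def merger_parents(net: NetworkSpec, node_id: str):
    """Order the two parents of a merger as (left, right) relative to the
    child's flow direction."""
    node = net.node(node_id)
    if node.kind != "merger":
        raise TopologyError(f"{node_id} is not a merger")
    child = net.out_vessels(node_id)[0]
    p1, p2 = net.in_vessels(node_id)
    r1 = _wrap(p1.angle_deg - child.angle_deg)
    r2 = _wrap(p2.angle_deg - child.angle_deg)
    left, right = (p1, p2) if r1 <= r2 else (p2, p1)
    return left, right


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def generate_network(n_generations: int, seed: int,
                     config: SyntheticConfig | None = None) -> NetworkSpec:
    """Generate a binary bifurcation cascade of ``n_generations`` mirrored by
    a merger cascade. Daughter diameters taper by a ratio drawn from the
    configured range; merged diameters follow Murray's law."""
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)

    nodes: list[Node] = []
    vessels: list[Vessel] = []
    counter = {"n": 0, "v": 0}

    def add_node(kind, x, y):
        nid = f"n{counter['n']}"
        counter["n"] += 1
        nodes.append(Node(nid, kind, float(x), float(y)))
        return nodes[-1]

    def add_vessel(frm: Node, kind_to: str, d: float, angle: float):
        l = d * rng.uniform(*cfg.length_over_d)
        th = math.radians(angle)
        to = add_node(kind_to, frm.x + l * math.cos(th),
                      frm.y + l * math.sin(th))
        vid = f"v{counter['v']}"
        counter["v"] += 1
        vessels.append(Vessel(vid, frm.id, to.id, float(d), float(l),
                              float(angle)))
        return vessels[-1], to

    inlet = add_node("inlet", 0.0, 0.0)
    root_vessel, root = add_vessel(inlet, "bifurcation", cfg.d_inlet_um, 0.0)

    # bifurcation cascade; leaves in left-to-right order
    frontier = [(root, cfg.d_inlet_um, 0.0)]
    leaves: list[Vessel] = []
    for depth in range(n_generations):
        last = depth == n_generations - 1
        nxt = []
        for node, d, angle in frontier:
            spread = rng.uniform(*cfg.branch_angle_deg)
            for sign in (+1, -1):
                dd = d * rng.uniform(*cfg.daughter_ratio)
                kind_to = "merger" if last else "bifurcation"
                v, child = add_vessel(node, kind_to, dd,
                                      angle + sign * spread)
                if last:
                    leaves.append(v)
                else:
                    nxt.append((child, dd, angle + sign * spread))
        frontier = nxt

    # merger cascade mirroring the bifurcation tree: pair adjacent branches
    branches = leaves
    while len(branches) > 1:
        merged = []
        for a, b in zip(branches[0::2], branches[1::2]):
            # both parents end at one merger node
            m = nodes[[n.id for n in nodes].index(a.to_node)]
            m.kind = "merger"
            end_b = b.to_node
            b.to_node = m.id
            nodes[:] = [n for n in nodes if n.id != end_b]
            d = (a.d_um ** 3 + b.d_um ** 3) ** (1.0 / 3.0)
            angle = _wrap((a.angle_deg + b.angle_deg) / 2.0)
            kind_to = "outlet" if len(branches) == 2 else "merger"
            v, _ = add_vessel(m, kind_to, d, angle)
            merged.append(v)
        branches = merged

    net = NetworkSpec(nodes, vessels)
    net.validate()
    return net


def default_inlet_flow(config: SyntheticConfig | None = None,
                       d_um: float | None = None) -> float:
    """Inlet volumetric flow (um^3/s) giving the configured mean inlet
    velocity."""
    cfg = config or SyntheticConfig()
    d = cfg.d_inlet_um if d_um is None else d_um
    return cfg.inlet_velocity_mm_s * 1e3 * math.pi * (d / 2.0) ** 2


# ---------------------------------------------------------------------------
# Flow solve and hematocrit propagation
# ---------------------------------------------------------------------------

@dataclass
class VesselShape:
    """Per-vessel profile shape parameters at the vessel entrance."""

    k: float            # bluntness exponent
    delta_um: float     # cell-free-layer width
    lam_u0: float       # velocity skew at s=0 (+ = toward left wall)
    lam_h0: float       # hematocrit skew at s=0

    def lam_at(self, s: float, d_um: float, relax_factor: float):
        f = math.exp(-s / (relax_factor * d_um))
        return self.lam_u0 * f, self.lam_h0 * f


@dataclass
class FlowState:
    net: NetworkSpec
    q: dict[str, float]             # um^3/s per vessel
    h: dict[str, float]             # discharge hematocrit per vessel
    shapes: dict[str, VesselShape]
    inlet_hematocrit: float
    config: SyntheticConfig


def phase_separation_split(h_m: float, q1: float, d1: float, d2: float,
                           dm: float, *, q_low: float = 0.05,
                           steepness: float = 1.5, diam_coef: float = 0.5,
                           h_max: float = 0.95) -> tuple[float, float]:
    """Split the mother RBC flux between two daughters (plasma skimming).

    The daughter-1 RBC-flux fraction F1 is an S-shaped (logit-linear)
    function of the fractional flow q1, zero below ``q_low`` and one above
    ``1 - q_low``, with a diameter-asymmetry offset. Exact flux conservation
    holds: h_m = q1*h1 + (1-q1)*h2.
    """
    if not 0.0 <= q1 <= 1.0:
        raise ValueError("q1 must lie in [0, 1]")
    if not 0.0 <= h_m < 1.0:
        raise ValueError("h_m must lie in [0, 1)")
    if h_m > h_max:
        raise ValueError("h_m exceeds the configured hematocrit cap")
    if h_m == 0.0:
        return 0.0, 0.0

    if q1 <= q_low:
        f1 = 0.0
    elif q1 >= 1.0 - q_low:
        f1 = 1.0
    else:
        x = (q1 - q_low) / (1.0 - 2.0 * q_low)
        z = steepness * math.log(x / (1.0 - x)) + diam_coef * math.log(d1 / d2)
        f1 = 1.0 / (1.0 + math.exp(-z))

    h1 = f1 * h_m / q1 if q1 > 0 else 0.0
    h2 = (1.0 - f1) * h_m / (1.0 - q1) if q1 < 1 else 0.0
    # cap with overflow rerouted to the other daughter (conservation exact)
    if h1 > h_max:
        h1 = h_max
        h2 = (h_m - q1 * h1) / (1.0 - q1)
    elif h2 > h_max:
        h2 = h_max
        h1 = (h_m - (1.0 - q1) * h2) / q1
    return h1, h2


def solve_flow(net: NetworkSpec, inlet_flows: float | dict[str, float] | None
               = None, inlet_hematocrit: float | None = None,
               config: SyntheticConfig | None = None, seed: int = 0
               ) -> FlowState:
    """Solve the linear network flow (hydraulic resistance ~ l/d^4) and
    propagate hematocrit and profile-shape parameters downstream."""
    cfg = config or SyntheticConfig()
    if inlet_hematocrit is None:
        inlet_hematocrit = cfg.inlet_hematocrit
    if not 0.0 < inlet_hematocrit < 1.0:
        raise ValueError("inlet_hematocrit must lie in (0, 1)")
    net.validate()

    inlets = net.inlets
    if inlet_flows is None:
        qin = {n.id: default_inlet_flow(cfg, net.out_vessels(n.id)[0].d_um)
               for n in inlets}
    elif isinstance(inlet_flows, dict):
        qin = dict(inlet_flows)
        unknown = set(qin) - {n.id for n in inlets}
        if unknown:
            raise ValueError(f"flows given for non-inlet nodes: {unknown}")
    else:
        qin = {n.id: float(inlet_flows) for n in inlets}
    if any(q <= 0 for q in qin.values()):
        raise ValueError("inlet flows must be positive")

    g = net.graph()
    reachable = set()
    for n in inlets:
        if n.id in qin:
            reachable |= {n.id} | nx.descendants(g, n.id)
    missing = {n.id for n in net.nodes} - reachable
    if missing:
        raise TopologyError(f"nodes unreachable from any inlet: {sorted(missing)}")

    # nodal pressure solve: conductance ~ d^4 / l
    ids = [n.id for n in net.nodes]
    idx = {nid: i for i, nid in enumerate(ids)}
    n_nodes = len(ids)
    a = np.zeros((n_nodes, n_nodes))
    b = np.zeros(n_nodes)
    cond = {v.id: v.d_um ** 4 / v.l_um for v in net.vessels}
    for v in net.vessels:
        i, j = idx[v.from_node], idx[v.to_node]
        c = cond[v.id]
        a[i, i] += c
        a[j, j] += c
        a[i, j] -= c
        a[j, i] -= c
    for n in net.nodes:
        if n.kind == "inlet":
            b[idx[n.id]] += qin[n.id]
        elif n.kind == "outlet":
            i = idx[n.id]
            a[i, :] = 0.0
            a[i, i] = 1.0
            b[i] = 0.0
    p = np.linalg.solve(a, b)
    q = {v.id: cond[v.id] * (p[idx[v.from_node]] - p[idx[v.to_node]])
         for v in net.vessels}
    if min(q.values()) <= 0:
        raise TopologyError("flow reversal in a vessel; unsupported topology")

    # hematocrit + shape propagation in topological node order
    rng = np.random.default_rng(seed)
    h: dict[str, float] = {}
    shapes: dict[str, VesselShape] = {}

    def inlet_shape(v: Vessel) -> VesselShape:
        k = float(rng.uniform(*cfg.k_range))
        delta = (v.d_um / 2.0) * float(rng.uniform(*cfg.delta_over_r))
        return VesselShape(k=k, delta_um=delta, lam_u0=0.0, lam_h0=0.0)

    for nid in nx.topological_sort(g):
        node = net.node(nid)
        if node.kind == "inlet":
            v = net.out_vessels(nid)[0]
            h[v.id] = inlet_hematocrit
            shapes[v.id] = inlet_shape(v)
        elif node.kind == "bifurcation":
            mother = net.in_vessels(nid)[0]
            (left, right), apex = bifurcation_daughters(net, nid)
            qm = q[mother.id]
            q_left = q[left.id] / qm
            h_left, h_right = phase_separation_split(
                h[mother.id], q_left, left.d_um, right.d_um, mother.d_um,
                q_low=cfg.q_low, steepness=cfg.steepness,
                diam_coef=cfg.diam_coef, h_max=cfg.h_max)
            h[left.id], h[right.id] = h_left, h_right
            ms = shapes[mother.id]
            a1 = (left.d_um / mother.d_um) ** 2
            a2 = (right.d_um / mother.d_um) ** 2
            for dv, a_hat, hd in ((left, a1 / (a1 + a2), h_left),
                                  (right, a2 / (a1 + a2), h_right)):
                s_apex = +1.0 if apex[dv.id] == "left" else -1.0
                lam_h0 = s_apex * cfg.lam_bif * (1.0 - a_hat)
                lam_u0 = -cfg.lam_u_ratio * lam_h0
                k = float(np.clip(ms.k * (0.85 + 0.3 * a_hat), 1.5, 3.5))
                dor = (ms.delta_um / (mother.d_um / 2.0)) * \
                    (h[mother.id] / max(hd, 0.02)) ** 0.7
                delta = float(np.clip(dor, 0.03, 0.45)) * dv.d_um / 2.0
                shapes[dv.id] = VesselShape(k, delta, lam_u0, lam_h0)
        elif node.kind == "merger":
            left, right = merger_parents(net, nid)
            child = net.out_vessels(nid)[0]
            qc = q[child.id]
            q1, q2 = q[left.id] / qc, q[right.id] / qc
            h[child.id] = (h[left.id] * q[left.id] +
                           h[right.id] * q[right.id]) / qc
            s1, s2 = shapes[left.id], shapes[right.id]
            k = q1 * s1.k + q2 * s2.k
            dor = q1 * s1.delta_um / (left.d_um / 2.0) + \
                q2 * s2.delta_um / (right.d_um / 2.0)
            lam_h0 = cfg.lam_merge * (q1 - q2)
            shapes[child.id] = VesselShape(
                float(k), float(dor) * child.d_um / 2.0,
                -cfg.lam_u_ratio * lam_h0, lam_h0)

    return FlowState(net=net, q=q, h=h, shapes=shapes,
                     inlet_hematocrit=inlet_hematocrit, config=cfg)


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthField:
    """Rendered cross-sectional ground truth at one station of one vessel."""

    vessel_id: str
    s: float
    u: Field2D
    h: Field2D
    profile_u: Profile1D
    profile_h: Profile1D
    d_um: float
    l_um: float
    q: float
    h_d: float
    u_max: float


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _shape_functions(cfg: SyntheticConfig, r_over, cos_left, k, delta_r,
                     lam_u, lam_h):
    """Normalized velocity and hematocrit shape factors on (r/R, cos_left)."""
    u_shape = (1.0 - r_over ** k) * (1.0 + lam_u * r_over * cos_left)
    w = cfg.cfl_sharpness
    r_c = 1.0 - delta_r * (1.0 - lam_h * cos_left)
    h_shape = _sigmoid((r_c - r_over) / w) * \
        (1.0 + cfg.hem_skew_gain * lam_h * r_over * cos_left)
    return u_shape, h_shape


def render_fields(flow: FlowState, vessel_id: str, s: float, ng: int = 32,
                  noise_sd: float | None = None, seed: int = 0,
                  n_profile: int = 56) -> GroundTruthField:
    """Render the u (mm/s) and H fields plus matched mid-plane profiles at
    streamwise station ``s`` of one vessel.

    U_max is scaled so the velocity field integrates to the vessel flow rate
    Q; H_core is scaled so the discharge (flux-weighted) hematocrit matches
    the flow solution. Additive Gaussian noise (sd = ``noise_sd``, default
    2% of the field max) is applied inside the lumen only and clipped to the
    physical ranges.
    """
    cfg = flow.config
    v = flow.net.vessel(vessel_id)
    if not 0.0 <= s <= v.l_um:
        raise ValueError(f"station s={s} outside [0, {v.l_um}]")
    if ng < 8:
        raise ValueError("ng must be >= 8")
    shape = flow.shapes[vessel_id]
    r_vessel = v.d_um / 2.0
    if shape.delta_um >= r_vessel:
        raise ValueError("CFL width delta must be smaller than the radius")
    lam_u, lam_h = shape.lam_at(s, v.d_um, cfg.relax_length_factor)
    k = shape.k
    delta_r = shape.delta_um / r_vessel
    q = flow.q[vessel_id]
    h_d = flow.h[vessel_id]

    # analytic flow-rate coefficient: the skew term integrates to zero
    mean_u_shape = k / (k + 2.0)               # lumen average of 1-(r/R)^k
    u_max_um = q / (math.pi * r_vessel ** 2) / mean_u_shape   # um/s
    u_max = u_max_um * 1e-3                                   # mm/s

    # H_core from discharge-hematocrit (flux) consistency, by quadrature
    nr, nt = 128, 96
    rq = (np.arange(nr) + 0.5) / nr                       # r/R midpoints
    tq = (np.arange(nt) + 0.5) / nt * 2.0 * math.pi
    rr, tt = np.meshgrid(rq, tq, indexing="ij")
    cl = np.cos(tt)                                       # theta=0 -> left
    u_s, h_s = _shape_functions(cfg, rr, cl, k, delta_r, lam_u, lam_h)
    da = rr / (nr * nt) * 2.0 * math.pi                   # dA / R^2
    flux_coef = float(np.sum(u_s * h_s * da))             # per U_max*H_core*R^2
    u_coef = float(np.sum(u_s * da))
    h_core = h_d * u_coef / flux_coef
    if h_core >= 1.0:
        h_core = min(h_core, 0.98)

    # Cartesian rasters
    c = (np.arange(ng) + 0.5) / ng * 2.0 - 1.0
    xx, yy = np.meshgrid(c, c, indexing="xy")
    mask = lumen_mask(ng)
    r_over = np.sqrt(xx ** 2 + yy ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_left = np.where(r_over > 0, -xx / np.maximum(r_over, 1e-30), 0.0)
    u_s, h_s = _shape_functions(cfg, np.minimum(r_over, 1.0), cos_left, k,
                                delta_r, lam_u, lam_h)
    u_grid = np.where(mask, u_max * u_s, 0.0)
    u_grid[r_over >= 1.0] = 0.0
    h_grid = np.where(mask, h_core * h_s, 0.0)

    # matched mid-plane profiles (global orientation: left wall at xi=0)
    xi = np.linspace(0.0, 1.0, n_profile)
    x = 2.0 * xi - 1.0
    r_p = np.abs(x)
    cl_p = np.where(r_p > 0, -np.sign(x), 0.0)
    u_ps, h_ps = _shape_functions(cfg, r_p, cl_p, k, delta_r, lam_u, lam_h)
    u_prof = u_max * u_ps
    u_prof[0] = u_prof[-1] = 0.0
    h_prof = h_core * h_ps

    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_u = cfg.noise_frac * float(u_grid.max())
        noise_h = cfg.noise_frac * float(h_grid.max())
    else:
        noise_u = noise_h = float(noise_sd)
    if noise_u > 0:
        u_grid[mask] += rng.normal(0.0, noise_u, int(mask.sum()))
        u_grid = np.clip(u_grid, 0.0, None)
        interior = slice(1, -1)
        u_prof[interior] = np.clip(
            u_prof[interior] + rng.normal(0.0, noise_u, n_profile - 2), 0.0,
            None)
    if noise_h > 0:
        h_grid[mask] += rng.normal(0.0, noise_h, int(mask.sum()))
        h_grid = np.clip(h_grid, 0.0, 1.0)
        h_prof = np.clip(h_prof + rng.normal(0.0, noise_h, n_profile), 0.0,
                         1.0)
    h_grid = np.clip(h_grid, 0.0, 1.0)
    h_prof = np.clip(h_prof, 0.0, 1.0)

    return GroundTruthField(
        vessel_id=vessel_id, s=float(s),
        u=Field2D(u_grid, mask, 0.0, KIND_VELOCITY),
        h=Field2D(h_grid, mask, 0.0, KIND_HEMATOCRIT),
        profile_u=Profile1D(xi, u_prof, KIND_VELOCITY, "global"),
        profile_h=Profile1D(xi, h_prof, KIND_HEMATOCRIT, "global"),
        d_um=v.d_um, l_um=v.l_um, q=q, h_d=h_d, u_max=u_max)


def render_network(flow: FlowState, ng: int = 32, noise_sd: float | None =
                   None, seed: int = 0, n_profile: int = 56,
                   stations: tuple[str, ...] = ("start", "end")
                   ) -> dict[tuple[str, str], GroundTruthField]:
    """Render ground truth at the requested stations of every vessel.

    Returns ``{(vessel_id, "start"|"end"): GroundTruthField}`` with one
    deterministic noise seed per field derived from ``seed``.
    """
    out = {}
    for i, v in enumerate(sorted(flow.net.vessels, key=lambda v: v.id)):
        for j, st in enumerate(stations):
            s = 0.0 if st == "start" else v.l_um
            child_seed = np.random.SeedSequence([seed, i, j])
            fld = render_fields(flow, v.id, s, ng=ng, noise_sd=noise_sd,
                                seed=child_seed, n_profile=n_profile)
            out[(v.id, st)] = fld
    return out
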