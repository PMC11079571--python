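"""Vasculature-wide sequential prediction over the network graph.

Data are specified only at the network inlets; the trained component models
are then chained through the hierarchy of vessels, bifurcations and mergers,
each component's prediction feeding the next component downstream. Mergers
are deferred until both parents have been predicted, which also handles
multiple inlets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import synthetic as sv
from .errors import TopologyError
from .models2d import (loss_mse_hematocrit, loss_mse_velocity,
                       predict_component_2d)
from .models3d import mae, predict_component_3d
from .prep import orient_to_global

__all__ = ["Component", "TraceEntry", "PredictionTrace", "topological_order",
           "traverse_predict", "evaluate_trace"]


@dataclass(frozen=True)
class Component:
    kind: str      # vessel | bifurcation | merger
    id: str        # vessel id or junction node id


@dataclass
class TraceEntry:
    component: Component
    inputs: dict
    outputs: dict
    scalars: dict


@dataclass
class PredictionTrace:
    entries: list[TraceEntry] = field(default_factory=list)
    #: predicted state keyed by (vessel_id, "start"|"end") -> {"u":..,"H":..}
    state: dict = field(default_factory=dict)

    @property
    def components(self) -> list[Component]:
        return [e.component for e in self.entries]


def topological_order(net: sv.NetworkSpec) -> list[Component]:
    """Order all components so every component appears after the components
    supplying its inputs (mergers after both parents)."""
    g = nx.DiGraph()
    for v in net.vessels:
        g.add_node(("vessel", v.id))
        from_kind = net.node(v.from_node).kind
        if from_kind in ("bifurcation", "merger"):
            g.add_edge((from_kind, v.from_node), ("vessel", v.id))
        to_kind = net.node(v.to_node).kind
        if to_kind in ("bifurcation", "merger"):
            g.add_edge(("vessel", v.id), (to_kind, v.to_node))
    if not nx.is_directed_acyclic_graph(g):
        raise TopologyError("component graph contains a cycle")
    inlet_fed = {("vessel", v.id) for n in net.inlets
                 for v in net.out_vessels(n.id)}
    for node, deg in g.in_degree():
        if deg == 0 and node not in inlet_fed:
            raise TopologyError(
                f"component {node} has no supplied input")
    order = [Component(kind, cid) for kind, cid in nx.lexicographical_topological_sort(
        g, key=str)]
    return order


def _component_scalars(net: sv.NetworkSpec, comp: Component, mode: str):
    if comp.kind == "vessel":
        v = net.vessel(comp.id)
        return {"d": v.d_um, "l": v.l_um}
    if comp.kind == "bifurcation":
        mother = net.in_vessels(comp.id)[0]
        (left, right), _ = sv.bifurcation_daughters(net, comp.id)
        ref = mother.d_um
    else:
        left, right = sv.merger_parents(net, comp.id)
        ref = net.out_vessels(comp.id)[0].d_um
    if mode == "2d":
        return {"a1": (left.d_um / ref) ** 2, "a2": (right.d_um / ref) ** 2}
    return {"r1": left.d_um / ref, "r2": right.d_um / ref}


def traverse_predict(net: sv.NetworkSpec, models: dict, inlet_data: dict,
                     mode: str = "2d") -> PredictionTrace:
    """Propagate inlet profiles/fields through the whole vasculature.

    ``models`` maps component kind to a trained model of the requested mode;
    ``inlet_data`` maps each inlet node id to ``{"u": ..., "H": ...}`` at the
    start of its outgoing vessel.
    """
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    for kind in ("vessel", "bifurcation", "merger"):
        if any(c.kind == kind for c in topological_order(net)) and \
                kind not in models:
            raise TopologyError(f"missing model for component kind {kind!r}")
    predict = predict_component_2d if mode == "2d" else predict_component_3d

    trace = PredictionTrace()
    state = trace.state
    for n in net.inlets:
        if n.id not in inlet_data:
            raise ValueError(f"missing inlet data for inlet {n.id!r}")
        v = net.out_vessels(n.id)[0]
        state[(v.id, "start")] = dict(inlet_data[n.id])

    for comp in topological_order(net):
        scalars = _component_scalars(net, comp, mode)
        if mode == "3d":
            scalars = dict(scalars, delta_beta=0.0)
        if comp.kind == "vessel":
            upstream = state[(comp.id, "start")]
            inputs = {"u_in": upstream["u"], "H_in": upstream["H"]}
            out = predict(models["vessel"], inputs=inputs, scalars=scalars)
            state[(comp.id, "end")] = {"u": out["u_out"], "H": out["H_out"]}
        elif comp.kind == "bifurcation":
            mother = net.in_vessels(comp.id)[0]
            (left, right), apex = sv.bifurcation_daughters(net, comp.id)
            up = state[(mother.id, "end")]
            inputs = {"u_m": up["u"], "H_m": up["H"]}
            out = predict(models["bifurcation"], inputs=inputs,
                          scalars=scalars)
            for tag, dv in (("1", left), ("2", right)):
                u, h = out[f"u_{tag}"], out[f"H_{tag}"]
                if mode == "2d":  # back from apex-first to global orientation
                    u = orient_to_global(u, apex[dv.id])
                    h = orient_to_global(h, apex[dv.id])
                state[(dv.id, "start")] = {"u": u, "H": h}
        else:
            left, right = sv.merger_parents(net, comp.id)
            child = net.out_vessels(comp.id)[0]
            up1, up2 = state[(left.id, "end")], state[(right.id, "end")]
            inputs = {"u_1": up1["u"], "H_1": up1["H"],
                      "u_2": up2["u"], "H_2": up2["H"]}
            out = predict(models["merger"], inputs=inputs, scalars=scalars)
            state[(child.id, "start")] = {"u": out["u_out"],
                                          "H": out["H_out"]}
        trace.entries.append(TraceEntry(comp, inputs, out, scalars))
    return trace


def evaluate_trace(trace: PredictionTrace, truth: dict,
                   mode: str = "2d") -> dict:
    """Per-station and aggregate error metrics of a traversal.

    ``truth`` maps ``(vessel_id, "start"|"end")`` to ground-truth objects
    (``GroundTruthField`` or ``{"u":..., "H":...}``). Stations without truth
    are skipped with a warning.
    """
    per_station = {}
    for key, pred in trace.state.items():
        gt = truth.get(key)
        if gt is None:
            warnings.warn(f"no ground truth for station {key}; skipped")
            continue
        if hasattr(gt, "profile_u"):
            gt_u = gt.profile_u if mode == "2d" else gt.u
            gt_h = gt.profile_h if mode == "2d" else gt.h
        else:
            gt_u, gt_h = gt["u"], gt["H"]
        if mode == "2d":
            per_station[key] = {
                "mse_u": loss_mse_velocity(gt_u.values, pred["u"].values),
                "mse_H": loss_mse_hematocrit(gt_h.values, pred["H"].values),
            }
        else:
            per_station[key] = {
                "mae_u": mae(gt_u, pred["u"]),
                "mae_H": mae(gt_h, pred["H"]),
            }
    agg = {}
    if per_station:
        for metric in next(iter(per_station.values())):
            agg[metric] = float(np.mean([v[metric]
                                         for v in per_station.values()]))
    return {"per_station": per_station, "aggregate": agg}
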