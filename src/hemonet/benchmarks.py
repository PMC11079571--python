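"""End-to-end benchmark runs: train the component models on synthetic
networks from one seed family and evaluate them on an independently
generated held-out network.

These routines reproduce the package's headline error numbers from scratch
and are shared by the acceptance script and the acceptance test suite. The
default problem sizes are chosen to run on a single CPU core in minutes;
they are documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import prep, synthetic as sv
from .models2d import (Ann2DConfig, build_ann, loss_mse_hematocrit,
                       loss_mse_velocity, predict_component_2d, train_2d)
from .models3d import (MERGER_LR_SCHEDULE, UnetConfig, build_unet, mae,
                       predict_component_3d, train_3d)

KINDS = ("vessel", "bifurcation", "merger")


@dataclass
class Benchmark2DResult:
    models: dict
    metrics: dict            # per kind: {"mse_u": ..., "mse_H": ..., "n": ...}
    overall_mse: float       # mean of both metrics over all held-out samples
    n_heldout: int
    test_network: object
    test_flow: object
    test_fields: dict


@dataclass
class Benchmark3DResult:
    models: dict
    metrics: dict            # per kind: {"mae": ..., "n": ...}
    mean_mae: float          # average of the three per-model means
    n_heldout: int


def _datasets_2d(seed: int, n_generations: int, n_train_networks: int):
    def make(s):
        net = sv.generate_network(n_generations, seed=s)
        flow = sv.solve_flow(net, seed=s)
        fields = sv.render_network(flow, ng=32, seed=s + 1000)
        return net, flow, fields

    train_parts = []
    for i in range(n_train_networks):
        net, flow, fields = make(seed + 10 * i)
        train_parts.append(prep.build_dataset(net, flow, fields, mode="2d"))
    train = {k: sum((p[k] for p in train_parts), []) for k in KINDS}
    test_net, test_flow, test_fields = make(seed + 1)
    test = prep.build_dataset(test_net, test_flow, test_fields, mode="2d")
    return train, test, (test_net, test_flow, test_fields)


def run_2d_benchmark(seed: int = 1, n_generations: int = 4,
                     n_train_networks: int = 3, epochs: int = 2000,
                     max_vessel_samples: int = 60,
                     model_seed: int = 11) -> Benchmark2DResult:
    """Train the three profile ANNs on networks from seed family
    ``seed, seed+10, ...`` and evaluate the per-profile MSE metrics on all
    held-out components of an independent network (seed+1)."""
    train, test, test_objs = _datasets_2d(seed, n_generations,
                                          n_train_networks)
    rng = np.random.default_rng(model_seed)
    if len(train["vessel"]) > max_vessel_samples:
        idx = rng.choice(len(train["vessel"]), size=max_vessel_samples,
                         replace=False)
        train["vessel"] = [train["vessel"][i] for i in sorted(idx)]

    models, metrics = {}, {}
    all_metric_values = []
    for kind in KINDS:
        model = build_ann(Ann2DConfig(kind, epochs=epochs, seed=model_seed))
        train_2d(model, train[kind])
        models[kind] = model
        mu, mh = [], []
        for s in test[kind]:
            pred = predict_component_2d(model, s)
            for key in model.out_keys:
                t, p = s.outputs[key].values, pred[key].values
                if key.startswith("u"):
                    mu.append(loss_mse_velocity(t, p))
                else:
                    mh.append(loss_mse_hematocrit(t, p))
        metrics[kind] = {"mse_u": float(np.mean(mu)),
                         "mse_H": float(np.mean(mh)),
                         "n": len(test[kind])}
        all_metric_values += mu + mh
    n_heldout = sum(len(test[k]) for k in KINDS)
    return Benchmark2DResult(
        models=models, metrics=metrics,
        overall_mse=float(np.mean(all_metric_values)),
        n_heldout=n_heldout, test_network=test_objs[0],
        test_flow=test_objs[1], test_fields=test_objs[2])


def run_3d_benchmark(seed: int = 1, n_generations: int = 4,
                     base_per_kind: int = 15, augments: int = 20,
                     epochs: int = 50, batch_size: int = 16,
                     model_seed: int = 11) -> Benchmark3DResult:
    """Train the three U-nets with rotation augmentation and evaluate the
    masked, max-normalized MAE on held-out base components of an independent
    network. The merger learning-rate schedule is compressed proportionally
    to the reduced epoch budget."""
    def make(s, aug, cap):
        net = sv.generate_network(n_generations, seed=s)
        flow = sv.solve_flow(net, seed=s)
        fields = sv.render_network(flow, ng=32, seed=s + 1000)
        return prep.build_dataset(net, flow, fields, mode="3d",
                                  augment_count=aug, seed=s + 5,
                                  max_per_kind=cap)

    train = make(seed, augments, base_per_kind)
    test = make(seed + 1, 0, None)

    models, metrics = {}, {}
    per_model_means = []
    for kind in KINDS:
        if kind == "merger":
            cfg = UnetConfig(kind, lr_schedule=MERGER_LR_SCHEDULE,
                             batch_size=batch_size, seed=model_seed)
        else:
            cfg = UnetConfig(kind, lr_schedule=((60_000, 5e-4),),
                             batch_size=batch_size, seed=model_seed)
        model = build_unet(cfg)
        train_3d(model, train[kind], epochs=epochs)
        models[kind] = model
        maes = []
        for s in test[kind]:
            pred = predict_component_3d(model, s)
            for key in model.out_keys:
                maes.append(mae(s.outputs[key], pred[key]))
        metrics[kind] = {"mae": float(np.mean(maes)), "n": len(test[kind])}
        per_model_means.append(metrics[kind]["mae"])
    return Benchmark3DResult(
        models=models, metrics=metrics,
        mean_mae=float(np.mean(per_model_means)),
        n_heldout=sum(len(test[k]) for k in KINDS))


def deepest_path_errors(result: Benchmark2DResult) -> list[tuple[str, float]]:
    """Traverse the held-out network from its inlet and return the combined
    per-station error at successive stations along the deepest root-to-leaf
    flow path."""
    import networkx as nx

    from .traversal import evaluate_trace, traverse_predict

    net, fields = result.test_network, result.test_fields
    inlet = net.inlets[0]
    v0 = net.out_vessels(inlet.id)[0]
    gt = fields[(v0.id, "start")]
    inlet_data = {inlet.id: {"u": gt.profile_u, "H": gt.profile_h}}
    trace = traverse_predict(net, result.models, inlet_data, mode="2d")
    ev = evaluate_trace(trace, fields, mode="2d")

    g = net.graph()
    path = nx.dag_longest_path(g)
    errors = []
    for a, b in zip(path[:-1], path[1:]):
        vid = g.edges[a, b]["vessel"]
        m = ev["per_station"].get((vid, "end"))
        if m is not None:
            errors.append((vid, m["mse_u"] + m["mse_H"]))
    return errors
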