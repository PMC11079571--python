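# hemonet

Surrogate models for cross-sectional hemodynamics in microvascular
networks: given only the blood-velocity and red-blood-cell (RBC)
concentration data at a network's inlets, `hemonet` predicts the full
velocity profile u and hematocrit profile H in **every** vessel of the
network, and derives the wall shear stress (WSS) and cell-free layer (CFL)
from them.

In the microcirculation these profiles are far from Poiseuille flow: the
RBC core blunts the velocity profile, a cell-depleted plasma layer forms at
the wall, and downstream of each bifurcation the hematocrit skews toward
the flow-dividing apex while the velocity skews away from it. Resolving
this with RBC-resolved simulation costs tens of thousands of core-hours per
network. `hemonet` instead trains one small model per vascular component
kind and chains them over the network graph:

* **2D profile models** — dense ReLU networks over N = 56 diameter
  profiles: a bifurcation model (mother profiles + daughter/mother area
  ratios → both daughter profiles), a vessel model (entrance profiles +
  d, l → exit profiles) and a merger model (both parent profiles + area
  ratios → merged profiles). Seven hidden layers × 80 neurons (ten for the
  merger), Adam 1e-3, dropout, per-profile losses
  `MSE_u = Σ(u−û)²/N` and `MSE_H = Σ(H−Ĥ)²/(N·max H²)`.
* **3D field models** — U-nets over masked 32×32 cross-sectional rasters
  (5 levels, 16 base filters) with the geometric scalars (diameter ratios,
  rotation-augmentation angle Δβ) injected at the bottleneck.
* **Sequential traversal** — components are ordered topologically and each
  prediction feeds the next component downstream, so only inlet data is
  required; mergers wait for both parents, which also covers multi-inlet
  networks.
* **Post-processing** — WSS = plasma viscosity × one-sided near-wall
  velocity gradient (the stencil lies inside the CFL); the CFL edge is the
  H ≈ 0.085 crossing; predictions are moving-average filtered first.

Because RBC-resolved training data is not reproducible at desk scale, the
package ships a synthetic generator (`hemonet.synthetic`) that emulates its
statistical structure — tapered binary networks, conservative Poiseuille
flow splits, plasma-skimming phase separation, blunted/skewed profiles with
a sigmoidal CFL, 30% inflow hematocrit — with exact flow and RBC-flux
conservation and full seed determinism. All neural-network layers
(dense/conv/pool/transposed-conv, Adam, dropout) are implemented in NumPy;
see `docs/methods.md` for the model equations, parameter defaults, problem
sizes and limitations.

## Worked example

```python
from hemonet import (generate_network, solve_flow, render_network,
                     build_dataset, Ann2DConfig, build_ann, train_2d,
                     traverse_predict, evaluate_trace, compute_wss_1d,
                     extract_cfl_1d)

# synthetic training network (4 generations: 46 vessels, 15 bifurcations,
# 15 mergers) and an independent test network
net = generate_network(4, seed=1)
flow = solve_flow(net, seed=1)                  # 30% inflow hematocrit
fields = render_network(flow, ng=32, seed=1001)
data = build_dataset(net, flow, fields, mode="2d")

models = {}
for kind in ("vessel", "bifurcation", "merger"):
    m = build_ann(Ann2DConfig(kind, epochs=2000, seed=11))
    models[kind] = train_2d(m, data[kind])

# vasculature-wide prediction from inlet data only
inlet = net.inlets[0]
v0 = net.out_vessels(inlet.id)[0]
gt = fields[(v0.id, "start")]
trace = traverse_predict(net, models,
                         {inlet.id: {"u": gt.profile_u, "H": gt.profile_h}},
                         mode="2d")
print(evaluate_trace(trace, fields, mode="2d")["aggregate"])

# physiology from a predicted vessel-end profile
end = trace.state[(v0.id, "end")]
r = net.vessel(v0.id).d_um / 2
print(compute_wss_1d(end["u"], r_um=r).wall_0,
      extract_cfl_1d(end["H"], r_um=r).width_0)
```

On the training network itself this prints an aggregate
`{'mse_u': 0.0203, 'mse_H': 0.0087}` (u in mm/s, so MSE_u is in mm²/s²;
the H metric is dimensionless), a wall shear stress of `1.182` Pa and a
CFL width of `2.373` μm at the end of the 24 μm inlet vessel —
physiological values for an arteriole-scale vessel at a 2 mm/s mean
velocity.

The same pipeline is scriptable from the shell:

```bash
hemonet generate --seed 1 --out data/
hemonet train --data data/ --kind bifurcation --mode 2d --out ckpt/
hemonet traverse --data data/ --checkpoints ckpt/ --mode 2d --out out/
```

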