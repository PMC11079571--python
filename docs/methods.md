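# Methods

## Problem

In the microcirculation, blood is a suspension of deformable red blood
cells (RBCs) in plasma. The time-averaged velocity profile u over a vessel
cross-section is blunted (non-parabolic) by the RBC core, and the RBC
concentration (hematocrit) H is core-concentrated with a cell-free layer
(CFL) next to the wall. Downstream of a bifurcation both profiles are
skewed: H toward the flow-dividing apex side, u toward the opposite side,
and the skew relaxes along the vessel. Resolving these fields with
RBC-resolved simulation is accurate but prohibitively expensive for large
networks. `hemonet` replaces that step with trained surrogate models, one
per vascular component kind — vessel, bifurcation, merger — chained over
the network graph so that data only has to be supplied at the inlets.

Two model families are provided:

* **2D (profile) models**: dense ReLU networks over N = 56 diameter
  profiles. The bifurcation model maps (u_m, H_m, (d1/dm)², (d2/dm)²) to
  (u, H) in both daughters; the vessel model maps (u, H, d, l) across the
  vessel length; the merger model maps both parents' profiles plus area
  ratios to the merged profile. Scalars are broadcast to length-N vectors
  and concatenated with the velocity profile before the first hidden layer
  (the flow-rate-preserving combination of velocity and area); the
  hematocrit profile joins after the first hidden layer. Seven hidden
  layers of width 80 (ten for the merger), dropout after each hidden layer,
  linear output. Training uses per-sample Adam updates (learning rate
  1e-3) in a seed-determined random order per epoch with the loss
  MSE_u = Σ(u−û)²/N plus MSE_H = Σ(H−Ĥ)²/(N·max H²), summed over output
  profiles.
* **3D (field) models**: U-nets over 32×32 cross-sectional rasters masked
  to the circular lumen. Five encoder levels (two 3×3 convolutions + ReLU,
  then 2×2 max-pooling; 16 base filters doubling per level) down to a 1×1
  bottleneck, which is flattened and concatenated with the geometric
  conditioning scalars (d1/dm, d2/dm and the augmentation angle Δβ for
  junctions; d, l, Δβ for vessels) and mixed by a dense ReLU layer. The
  decoder mirrors the encoder with 2×2 transposed convolutions and skip
  concatenations. The loss is the same MSE pair evaluated cell-wise over
  in-mask cells. Bifurcations and vessels train at a constant learning rate
  of 5e-4; mergers use the piecewise schedule 5e-4 → 1e-4 → 5e-5 (segment
  lengths 5e4/3e4/3e4 epochs at full scale, compressed proportionally when
  a reduced epoch budget is set). Rotation augmentation creates extra
  samples by rotating input and output fields by a common random angle
  Δβ ~ U(−45°, 45°) (bilinear, re-masked) and passing Δβ as conditioning.

Both families are implemented directly in NumPy (`hemonet._nn`): dense,
3×3-convolution, max-pool and transposed-convolution layers with explicit
backward passes, inverted dropout and Adam. Every source of randomness
(initialization, shuffling, dropout, augmentation) flows through seeded
`numpy.random.Generator` instances, so training is bit-reproducible.

## Synthetic ground truth

Training data comes from a parametric emulator of RBC-suspension
hemodynamics (`hemonet.synthetic`), not from an RBC-resolved solver. It
generates:

* **Networks**: a binary cascade of bifurcations mirrored by a merger
  cascade (n generations; 3·2ⁿ−2 vessels). Daughter diameters taper by a
  ratio drawn from U(0.7, 0.9); merged diameters follow Murray's law;
  vessel lengths are d × U(7, 10); the inlet diameter defaults to 24 μm.
  With n = 4 a network has 46 vessels, 15 bifurcations and 15 mergers,
  comparable to a real capillary network patch.
* **Flow**: a linear nodal-pressure solve with Poiseuille conductance
  d⁴/l, inlet flow set by a 2 mm/s mean inlet velocity, outlet pressure 0.
  Flow conservation holds to the linear-solver residual (≪1e−10 relative).
* **Hematocrit**: inflow discharge hematocrit 0.30; at bifurcations a
  plasma-skimming split assigns the daughter RBC-flux fraction by a
  logit-linear S-curve of the fractional flow (steepness 1.5, cutoff
  q_low = 0.05, diameter-asymmetry offset 0.5·ln(d1/d2)), exactly
  conserving RBC flux; mergers mix flux-weighted.
* **Fields**: u(r,θ) = U_max(1−(r/R)^k)(1 + λ_u (r/R) cosθ) with U_max
  scaled analytically so the field integrates to the vessel flow rate, and
  H(r,θ) = H_core · sigmoid((r_c(θ)−r)/w) · (1 + 0.5 λ_H (r/R) cosθ) with
  interface radius r_c(θ) = R − δ(1 − λ_H cosθ) and w = 0.05 R. H_core is
  set by flux consistency (numerical quadrature) so the discharge
  hematocrit matches the flow solution — this reproduces the Fåhræus
  effect (tube hematocrit below discharge hematocrit). Gaussian noise
  (sd = 2% of the field max) is added inside the lumen and clipped to the
  physical ranges.

Shape parameters: bluntness k ~ U(1.8, 3.2) and CFL width δ/R ~ U(0.1, 0.3)
are drawn at inlet vessels; across junctions they propagate by smooth
deterministic maps (k scaled by the local area split, δ/R by the
hematocrit change, daughter skew λ_H(0) = ±0.8·(1−â) toward the apex with
λ_u = −0.6 λ_H, merger skew 0.4·(q1−q2) toward the dominant parent), and
skew relaxes as λ(s) = λ(0)·exp(−s/(10 d)). Randomness therefore enters at
the inlets and through geometry only: each component's input→output map is
a deterministic smooth function plus measurement noise, which is what makes
the surrogate problem well-posed. This is also the emulator's main
limitation: real RBC suspensions show history effects, tortuosity-induced
skew and cell-scale fluctuations that this parametric family cannot
represent, so passing error bounds here demonstrates that the models and
the chaining machinery are wired correctly, not that they generalize to
RBC-resolved data.

## Post-processing

* **WSS**: plasma viscosity μ (default 1.2e−3 Pa·s, a free parameter — the
  plasma value, since the near-wall stencil lies inside the CFL) times the
  one-sided near-wall radial gradient: a 3-point second-order stencil over
  the collocation points nearest the wall (exact for parabolic profiles;
  for fields, sampled along rays with u(R) = 0 imposed by no-slip).
* **CFL**: first inward crossing of H = 0.085 (linear interpolation
  between samples); per-ray for fields, giving the interface radius
  r_cfl(θ).
* **Filtering**: a moving-average filter (default window 5, renormalized
  at profile ends and mask edges) removes small-amplitude prediction noise
  before WSS/CFL extraction.
* **Moments**: profile mean and skewness treat the values as an
  unnormalized density over ξ; skewness is the standardized third central
  moment (tail convention: mass near ξ = 0 gives positive skew).

## Benchmark problem sizes

`scripts/acceptance.py` (and the scaled-down acceptance tests) train from
scratch at sizes chosen to complete on one CPU core in minutes:

* 2D: three training networks (seed family s, s+10, s+20; 45 bifurcations,
  45 mergers, 138 vessels capped at 60 samples), 2,000 epochs, evaluated
  on all 76 components of an independent network (seed s+1).
* 3D: one training network, up to 15 base components per kind × 20
  rotation augments (315 samples per kind), 50 epochs at batch size 16,
  merger schedule compressed proportionally; evaluated on the held-out
  network's base components with the masked MAE, each field normalized by
  the true field's in-mask maximum.

The full-scale settings (6×10⁴ epochs, constant 5e-4, full merger
schedule) remain available through the configuration.

## Numerical and design choices

* Not-a-knot cubic resampling (exact on cubics, which doubles as the test
  oracle); smoothing-spline weight chosen by generalized cross-validation
  when not given.
* Apex-first orientation: daughter profiles are stored with ξ = 0 on the
  apex side; the two daughters of a bifurcation are thus globally opposite
  but locally aligned. Traversal re-maps predictions back to the global
  frame using junction geometry.
* The hematocrit-loss normalization max H² is per-profile (per sample),
  not global.
* The bifurcation U-net predicts both daughters jointly (4 output
  channels); u and H travel as channels of one tensor because the two
  fields are physically coupled and are predicted simultaneously.
* Input standardization (z-score per collocation feature for the ANNs,
  max-scaling per channel for the U-nets) is stored in the checkpoint and
  re-applied at inference.
* Dropout rate 0.1 (regularization the profile models need at these small
  sample counts); linear output layers since targets are unbounded.
* Field rotation uses bilinear interpolation with re-masking; rotation of
  a masked disc cannot preserve non-zero boundary data, which is harmless
  here because physical fields vanish at the wall (no-slip, CFL).
* Degenerate cases: an all-zero hematocrit profile has no CFL crossing and
  reports width R with a `degenerate` flag; all-zero profiles are rejected
  by the moment and loss-normalization routines.

## Known limitations

* Cylindrical, constant-diameter, straight vessels only; no curvature or
  taper effects.
* Strictly feed-forward prediction: no iterative network coupling, no
  prediction at intermediate stations 0 < s < l, and no time-resolved
  quantities (e.g. WSS fluctuations).
* The emulator's functional forms (power-law bluntness, cosine skew,
  sigmoid CFL edge, logit phase separation, exponential skew relaxation)
  are package design choices made for smoothness and exact conservation;
  they are not fitted to measured RBC-suspension data.
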