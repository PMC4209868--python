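# shapecode

Models of the neural code for three-dimensional object shape in visually
guided grasping, for computational neuroscientists studying the parietal
grasp circuit (and roboticists curious about its shape representations).

The macaque anterior intraparietal area (AIP) encodes visual 3D shape for
hand pre-shaping, fed by depth-gradient and curvature signals from the
caudal intraparietal area (CIP). This package asks, in runnable form:
*which shape parameterizations are consistent with AIP tuning, and which
can a feedforward network actually compute from CIP-like input?* Two
candidates are compared:

- **superquadric parameters** — the implicit-surface family
  `F(x,y,z) = (|x|/A₁)^(2/ε₁) + (|y|/A₂)^(2/ε₂) + (|z|/A₃)^(2/ε₃) = 1`,
  nine parameters per shape (scales A, exponents ε, rotation angles θ),
  the robotics-style compact shape code;
- **Isomap coordinates** — a nonlinear dimension reduction of the depth
  map's spatial derivatives, in which geodesic distances along the shape
  manifold are preserved, so similar shapes always get similar
  parameters.

Neurons are modeled as cosine-tuned leaky integrate-and-fire (LIF) units:
driving current `I = φᵀx + b`, spike rate
`r = 1 / (τ_ref − τ_RC ln(1 − 1/I))` for `I > 1` (else 0), optionally with
Gaussian background noise simulated into a rate lookup table. Decoding
and synaptic-weight composition follow the Neural Engineering Framework:
decoders Φ give `p̂ = Φ r_pre`, and any cosine tuning over `p̂` is realized
exactly by weights `wᵀ = φᵀΦ`.

## What's in the package

| module | contents |
|---|---|
| `shapecode.shapes` | superquadric geometry, canonicalization, the 40k-style shape database sampler, the 36-stimulus augmented tuning design |
| `shapecode.render` | observer-centered depth maps by ray casting (16×16 warped grid, ±10°, object at 0.75 m) |
| `shapecode.features` | CIP-like 1280-value feature stacks (depth + 4 derivative channels), curvature/curvedness/shape-index formulas, V3A disparity channels |
| `shapecode.neurons` | cosine-LIF rates (closed-form and noisy-table), 50-branch dendritic model with truncated-SVD readout, NEF decoders |
| `shapecode.tuning` | augmented AIP tuning curves, multistart cosine-LIF fitting, error statistics, Levene's test |
| `shapecode.embedding` | Isomap (k-NN graph → Dijkstra geodesics → classical MDS), out-of-sample extension, distance histograms |
| `shapecode.mapping` | CIP→AIP multilayer perceptrons (1280→600→300→d, logistic/linear), NEF-population alternative, end-to-end pipeline |

## Worked example

`examples/06_cip_to_aip_network.py` renders 1,200 random superquadrics,
builds their feature stacks, fits an 8-D Isomap, and trains identical
networks against the two target spaces:

```
isomap        mean Euclidean error 0.930, normalized 0.133, median per-dim correlation 0.952
superquadric  mean Euclidean error 1.140, normalized 0.909, median per-dim correlation 0.535

median prediction error 0.759 vs median pairwise shape distance 8.893 (8.5%)
```

The normalized error (mean Euclidean error ÷ RMS norm of the centered
targets) is scale-free, so the two spaces are directly comparable: the
network approximates Isomap coordinates about seven times more accurately
than superquadric parameters. The reason is geometric — canonical
superquadric angles jump discontinuously at ±π/4 while the Isomap stays
continuous — and the last line shows that typical prediction errors are
far smaller than typical distances between shapes in the space. The other
examples (`examples/01` … `05`) walk through the database sampler, the
renderer, the feature channels, tuning-curve fitting, and the embedding's
treatment of the tall-box/wide-box discontinuity.

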