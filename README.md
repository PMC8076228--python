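# suturesim

A moving-interface model of cranial/palatal **suture pattern formation**,
with companion **morphometrics** for quantifying suture geometry in both
simulated fields and calibrated specimen images.

The model couples two lattice fields on a 2-D domain:

- `u` — bone differentiation degree (`u ≈ 1` bone, `u ≈ 0` the soft
  mesenchyme strip forming the suture);
- `v` — concentration of a diffusible osteogenesis-promoting factor,
  produced by mesenchyme, diffusing (coefficient `D_v`) and decaying.

The osteogenic front (the `u = 0.5` level set) moves in its normal
direction with speed

```
V = α (v − v_c) − σ κ
```

where `v_c` is the critical concentration at which osteogenesis and
resorption balance, `α` the efficacy of the factor, `σ` a surface tension
and `κ` the front curvature (positive where bone protrudes).  A bone tip
protruding into the factor-producing mesenchyme sees a higher `v` and
advances further; this amplifies small perturbations into interdigitated
(finger-like) sutures, while `σκ` suppresses them.  Passive soft-tissue
expansion at speed `c` is modelled by inserting lattice columns at the
minimum of `v` in a co-moving frame; at the steady balance each front
advances at `c/2`.

Numerically, the front law is realised as a forced Allen–Cahn phase field
(`du/dt = σ(∇²u − W′(u)/ε²) + α(v−v_c)·5u²(1−u)²/ε`) and the factor by a
backward-Euler screened-diffusion solve, both with cached sparse LU
factorisations (no-flux x boundaries, periodic along the suture axis).
The scheme is validated against closed-form oracles: planar front speed,
the shrinking-circle curvature-flow law `R²(t) = R₀² − 2σt`, and the
matched `cosh` steady profile of the factor across a source strip.

## Layout

| module | contents |
| --- | --- |
| `suturesim.model_core` | `SimulationParams`, `FieldState`, forcing `f(v)`, curvature operator, sub-pixel interface extraction, YAML/JSON config IO |
| `suturesim.simulator` | initial condition, `step_v`/`step_u`, column-insertion growth operator, full runs, steady-state detection, growth-balance measurement |
| `suturesim.morphometrics` | Otsu/manual binarisation, brightness profiles, per-transect width, centreline + maximum interdigitation amplitude, skeleton length, group statistics |
| `suturesim.screening` | two-parameter sweeps, phase diagrams with per-cell flags, monotonicity reports, heatmap/CSV rendering |
| `suturesim.fixtures` | synthetic sinusoidal suture images with closed-form ground truth; analytic step/disc phase fields for oracles |

## CLI

```sh
# one simulation: 16-bit TIFF snapshots of u and v + a JSON run manifest
suturesim run --config cfg.yaml --seed 0 --out runs/demo/

# morphometry of a calibrated image (or sidecar <img>.yaml calibration)
suturesim measure --image suture.tif --pixel-size 0.05 --axis y --out m.csv

# two-parameter screening sweep: tidy CSV + heatmap PNGs + manifest
suturesim sweep --config sweep.yaml --out sweeps/vc/

# synthetic ground-truth fixtures (TIFF + JSON truth + calibration sidecar)
suturesim fixtures --spec fx.yaml --out fixtures/
```

A simulation config is a flat YAML with `SimulationParams` field names
(unknown keys rejected); defaults are the calibrated baseline on the
128×128, Δx = 50, Δt = 2, length-6000 lattice.  A sweep config gives
`param1/values1`, `param2/values2`, `seeds` and a `base` params mapping.

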