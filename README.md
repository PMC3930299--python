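# aneuscale

Geometric morphometry and virtual growth for saccular aneurysm surface
models. Given a triangulated vascular surface (STL, units mm) and a neck
cutting plane, `aneuscale`:

- places the model in a **neck frame** (rigid transform taking the neck
  plane to `{z = d}` with the sac above),
- extracts the **neck curve** by mesh–plane intersection and measures the
  sac: height `h`, neck perimeter `P`, average neck diameter `D = P / π`,
  and the **size ratio** `ASR = h / D` (plus the classical aspect ratio
  `h / neck width` for comparison),
- applies a **height-graded anisotropic scaling** of the sac about the
  vertical axis through the neck centroid — each point at height `z` above
  the neck is scaled laterally by `1 + a (z − z_m)(k − 1)/h` (and in z with
  coefficient `c`), so displacement is zero at the neck and maximal at the
  apex, keeping the parent vessel and the neck invariant while the height
  scales by `k`,
- solves `k` in closed form for any target size ratio and generates a
  **longitudinal series** of scaled models (default schedule
  0.3, 0.5, 0.7, 1.0, 1.3, 1.5, 1.7, 2.0 with `a=2, b=2, c=1`),
- guards **feasibility**: deep shrinking can drive scale factors negative
  (with the defaults, any `k ≤ 0.5` collapses the apex laterally); strict
  mode refuses, stepwise mode splits `k` into equal geometric sub-steps,
- provides **measurement planes** P1/P2/P3 dividing the sac height into
  equal thirds, plane-averaging of external field samples (e.g. velocity
  or WSS from a flow solver), and Pearson correlation against the size
  ratio,
- ships a **phantom generator** (tube + half-ellipsoid sac) with analytic
  ground truth (`ASR = sac_height / (2 · sac_radius)`), used throughout
  the test suite.

No flow solving is performed; hemodynamic fields are external CSV inputs.

## CLI

All commands assume millimetres. A plane is a JSON file
`{"point": [x,y,z], "normal": [nx,ny,nz]}` or
`{"three_points": [[…],[…],[…]], "sac_side": [x,y,z]}`.

```sh
# synthetic model with analytic morphometry (also writes plane + apex seed)
aneuscale phantom --sac-radius 2 --sac-height 2 --tess 128 \
    --out phantom.stl --plane-out plane.json

# morphometry: {h_mm, perimeter_mm, D_mm, ASR, aspect_ratio}
aneuscale measure --mesh phantom.stl --plane plane.json --seed "0,0,3.839"

# scale the sac to a target size ratio (vessel + neck invariant)
aneuscale scale --mesh phantom.stl --plane plane.json --seed "0,0,3.839" \
    --target-asr 1.3 --out scaled.stl

# the full series + manifest.csv
aneuscale series --mesh phantom.stl --plane plane.json --seed "0,0,3.839" \
    --outdir series/

# measurement planes and their cross-section polylines
aneuscale planes --mesh phantom.stl --plane plane.json --seed "0,0,3.839" \
    --out sections.csv

# Pearson correlation on a per-model summary table
aneuscale correlate --table summary.csv --x ASR --y grand_mean
```

`--seed` is the apex seed point (on the sac, above the plane) used to pick
the sac connected component — a curved parent vessel may also rise above
the neck plane and must not be deformed. Exit codes: 2 I/O, 3 validation,
4 infeasible scaling.

## Library sketch

```python
from aneuscale import (PhantomSpec, make_phantom, build_neck_frame,
                       extract_neck_curve, split_sac, measure,
                       ScalingParams, scale_sac, generate_series)

ph = make_phantom(PhantomSpec(sac_radius=2, sac_height=2, tessellation=128))
model = build_neck_frame(ph.mesh, ph.plane)
model = extract_neck_curve(model)
model = split_sac(model, model.transform.apply(ph.apex_seed))
print(measure(model).asr)                     # ~0.5
series = generate_series(model)               # default eight-entry schedule
print(series.manifest())
```
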