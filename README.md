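# follikel

Speckle-reducing bilateral filtering and B-spline GVF snake segmentation
for ultrasound-like images.

Ultrasound images of ovarian follicles — the fluid-filled structures whose
diameters and areas are tracked when monitoring cattle reproduction — are
degraded by speckle: a granular, *multiplicative* interference pattern,
`J(X) = I(X) · (1 + η(X))` with zero-mean noise `η`. Because the
perturbation scales with brightness, the classic bilateral filter fails on
speckle: its range kernel

```
w_r(X, Y) = exp( −|J(Y) − J(X)|² / 2σ_r² )
```

uses an *absolute* intensity difference, so one σ_r cannot simultaneously
remove noise in bright regions and preserve edges in dark ones. This
package implements the speckle-reducing variant, whose range distance is
normalized by the center-pixel intensity,

```
D(X, Y) = |J(Y) − J(X)| / |J(X)|
```

which in a homogeneous region depends on the noise alone, making the range
kernel invariant to local brightness. Around that core the package
provides:

- **`follikel.phantom`** — piecewise-constant phantom generation (circles
  and rectangles on a darker background) and the multiplicative speckle
  model, with a reproducible seeded RNG.
- **`follikel.bilateral`** — conventional and normalized-range bilateral
  filters (exact windowed implementation, mirror padding), a Gaussian
  baseline, and the iterative scheme that re-applies the filter to its own
  output.
- **`follikel.metrics`** — despeckling quality measures: NMSE,
  noise-suppression α and edge-preservation β (mean-removed normalized
  cross-correlations of intensities and 4-neighbor Laplacians), local
  Laplacian contrast, and Pratt's figure of merit (FOM) for boundary
  accuracy.
- **`follikel.snake`** — a closed cubic B-spline active contour (48
  control points by default, circle initialization) driven by a
  generalized gradient vector flow (GGVF) field with edge gate
  `g = exp(−|∇f|/k)`.
- **`follikel.sweep`** / **`follikel.cli`** — the σ_r sweep experiment, the
  filter→segment→score pipeline, and a `follikel` command-line tool
  (`phantom`, `filter`, `metrics`, `contrast`, `fom`, `segment`, `sweep`,
  `pipeline`).

It is intended for researchers working on despeckling algorithms and
ultrasound image analysis who need a tested, reproducible reference
implementation rather than a clinical tool.

## Worked example

```python
import numpy as np
from follikel import (BilateralParams, SpeckleParams, apply_speckle,
                      compute_report, default_phantom_spec, filter_iterative,
                      generate_phantom)

clean = generate_phantom(default_phantom_spec())            # 256x256 phantom
noisy = apply_speckle(clean, SpeckleParams(variance=0.075, seed=42))

for mode, sigma_r in [("conventional", 0.3), ("normalized", 0.7)]:
    params = BilateralParams(sigma_d=3.0, sigma_r=sigma_r, mode=mode, iterations=5)
    report = compute_report(clean, filter_iterative(noisy, params))
    print(f"{mode:12s} sigma_r={sigma_r}: NMSE={report.nmse:.4f} "
          f"alpha={report.alpha:.4f} beta={report.beta:.4f}")
```

prints

```
conventional sigma_r=0.3: NMSE=0.0999 alpha=0.9623 beta=0.7747
normalized   sigma_r=0.7: NMSE=0.1974 alpha=0.9315 beta=0.8499
```

Each filter is evaluated at its characteristic operating point (σ_d = 3,
five iterations). NMSE measures the residual error against the clean
phantom (lower is better); α is the intensity correlation with the clean
image and β the correlation of Laplacians — β is the edge-preservation
score, and the normalized filter's higher β (0.85 vs 0.77) is the point of
the method: comparable smoothing with visibly better edge retention.

The same experiment from the shell:

```sh
follikel phantom --seed 42 --out clean.tif --out-noisy noisy.tif
follikel filter --in noisy.tif --out filtered.tif --mode normalized \
    --sigma-d 3 --sigma-r 0.7 --iterations 5
follikel metrics --clean clean.tif --test filtered.tif
```

Segmentation of a follicle-like dark disk, after filtering:

```sh
follikel segment --in filtered.tif --init-center 64,64 --init-radius 10 \
    --out boundary.csv --out-mask mask.png
```

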