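# Methods

## Noise model and phantom

Speckle is modelled multiplicatively: the observed image is
`J(X) = I(X) · (1 + η(X))` with `η` i.i.d., zero mean and variance 0.075
by default. The default distribution is uniform on `[−a, a]` with
`a = √(3·var)` — the classic `imnoise`-style speckle model — with Gaussian
`η` as an option; the uniform default was chosen because a bounded support
keeps post-clip censoring mild at the phantom's brightest level. Corrupted
images are clipped to [0, 1] *after* corruption; any statistical check on
the perturbation (e.g. its sample variance) is computed pre-clip to avoid
censoring bias.

The packaged phantom is a 256×256 piecewise-constant image: background
0.15, circles of radii {6, 12, 24} and squares of sides {5, 15, 31},
alternating between foreground levels 0.5 and 0.9. It is an *emulation*
of the classic despeckling test scene (several object sizes, high- and
low-intensity regions on a darker background), not a reconstruction of any
particular published figure; quantitative scores on it are therefore
comparable to published values only approximately. Rasterization is
0-based (row, col): a pixel belongs to a circle iff its integer center
lies within the radius; rectangles are half-open.

What the generator does **not** emulate: physically realistic ultrasound
speckle (Rayleigh statistics, spatial correlation at the PSF scale,
log-compression), attenuation, or textured tissue. Conclusions drawn on
the phantom about *relative* filter behavior transfer to real images only
where they depend on the multiplicative scaling of the noise, not on its
spatial structure.

## Bilateral filters

Both filters replace a pixel by the normalized weighted mean of its
`(2h+1)×(2h+1)` neighborhood, with spatial weight
`exp(−‖X−Y‖²/2σ_d²)` and range weight `exp(−D²/2σ_r²)`:

- conventional: `D = |J(Y) − J(X)|` (absolute intensity units);
- normalized:  `D = |J(Y) − J(X)| / max(|J(X)|, ε)` (relative units).

Numerical choices:

- `h = ⌈3σ_d⌉` (3-sigma truncation of the spatial Gaussian; 19×19 at
  σ_d = 3). The window size is otherwise a free choice; results at the
  default are the package's contract.
- Mirror (reflect-without-repeat) padding at borders, matching scipy's
  `mode="mirror"`; the σ_r → ∞ limit of the conventional filter then
  equals `scipy.ndimage.gaussian_filter` exactly.
- `ε = 1/255` guards the division at (near-)zero pixels — one 8-bit
  quantization step. On images bounded away from zero the guard is
  inactive and the normalized filter is exactly scale-equivariant
  (multiplying the input by s > 0 multiplies the output by s).
- All computation in float64 on [0, 1] intensities; the implementation
  loops over window offsets with vectorized per-pixel arithmetic and is
  verified against an exhaustive per-pixel double loop to 1e-12.

The iterative scheme re-applies the *same-mode* single pass to its own
output with unchanged parameters. Iteration helps when one pass
under-smooths (small σ_r) and over-smooths otherwise; on the packaged
phantom the five-iteration benefit shows at σ_r ≲ 0.3 for the normalized
filter. Five iterations is the default used by the evaluation protocol.

## Quality metrics

The published formulas behind this measure suite are not recoverable in
algebraic form from the available source, so the package documents and
locks the following standard forms:

- `NMSE = Σ((I₀−Ī₀) − (I−Ī))² / Σ(I₀−Ī₀)²` (means removed, so constant
  offsets are free);
- α = mean-removed normalized cross-correlation of intensities;
- β = the same correlation computed on 4-neighbor Laplacians
  `c = 4I(x,y) − (up+down+left+right)`, evaluated on interior pixels so
  every stencil uses real neighbors;
- local contrast = mean |c| over a chosen point set (the absolute value
  keeps the measure discriminative in homogeneous noise, where signed
  Laplacians average toward zero);
- Pratt's FOM = `(1/max(I_A, I_I)) Σ_i 1/(1 + γ·d(i)²)` over reference
  pixels, nearest distances computed exactly with a KD-tree, γ = 0.05.

Degenerate inputs (constant reference, identically-zero Laplacian, empty
point sets) raise typed errors rather than returning NaN.

When FOM scores a snake result, the automatic boundary is taken as the
boundary pixels of the contour's *rasterized region mask* (members with a
4-neighbor outside), the same convention a hand-drawn reference mask uses.
Rasterizing the traced curve instead yields ~30% more pixels and the
`max(I_A, I_I)` normalization would penalize the mismatch in convention
rather than in geometry.

## B-spline GVF snake

The external force field diffuses the gradient of an edge map
`f = |∇(G_σ * I)|` (pre-smoothing σ = 1 px, map normalized to [0, 1]) by
gradient descent on the generalized GVF energy: with `g = exp(−|∇f|/k)`
and `h = 1 − g`,

```
u ← u + Δτ·[ g·∇²u − h·(u − f_x) ]     (likewise v with f_y)
```

from `(u, v) = (f_x, f_y)`. Explicit Euler with Δτ = 0.2 satisfies the
stability bound Δτ ≤ 1/4 for the 4-neighbor Laplacian with g ≤ 1; 80
iterations is the default diffusion budget. `k` gates smoothing by edge
strength: the default k = 0.5 (in units of the normalized edge magnitude)
smooths generously and suits clean or despeckled images; on raw speckled
images a smaller k keeps the field pinned to true edges.

The contour is a closed *cubic* B-spline over m cyclic control points
(default 48), uniform parameterization, evaluated through the standard
uniform cubic blending weights (verified against the Cox–de Boor
recursion, which the package also exposes). The spline's smoothness is the
only internal regularization — no tension/rigidity forces.

Evolution: sample the curve at `n_samples` (default 96) parameter-uniform
points, read the field there by bilinear interpolation (clamped at the
border), map sampled forces to control-point displacements through the
Moore–Penrose pseudo-inverse of the sampling matrix (computed once per
topology), and step by `step_size` (default 1.0). Stop when the largest
control-point displacement drops below `tol` (default 0.02 px) or after
`max_iters` (default 2000). A contour leaving the image frame raises an
error carrying the last valid contour. On a noise-free disk of radius 20
the snake initialized at radius 10 (concentric or offset by 5 px) recovers
the boundary to ~0.15 px mean radial error, FOM ≈ 0.998.

## Evaluation protocol and problem sizes

The σ_r sweep runs both filters at σ_d = 3, five iterations, σ_r from 0.1
to 1.0 in steps of 0.1, on the packaged 256×256 phantom over five seeds
(~2 minutes on one CPU). Curve-shape checks treat the unfiltered noisy
image's score as the σ_r → 0 anchor of each curve, since the filter tends
to the identity in that limit; "rise then fall" is then judged on the
anchored curve. The per-filter optimal point σ_r^T is the argmax of the
seed-averaged β curve.

The end-to-end segmentation comparison uses a 128×128 follicle phantom: a
disk of radius 20 at level 0.35 (residual internal echogenicity, as real
follicles are hypoechoic but not anechoic) on stroma at 0.75, speckled at
variance 0.075, segmented from a concentric radius-10 circle after
(i) no filtering, (ii) Gaussian smoothing (σ = 3, window 9),
(iii) conventional bilateral at σ_r = 0.3, (iv) normalized bilateral at
σ_r = 0.7 (each filter at its synthetic-image optimum, five iterations).

## Known limitations

- The packaged phantom is an emulation; absolute NMSE/α/β values on it
  differ from published values obtained on other phantoms. In particular,
  β after heavy smoothing collapses on this phantom (pointwise-Laplacian
  correlation is very sensitive to blur: Gaussian σ = 3 on the *clean*
  phantom already drops β to 0.10), so the conventional filter's β at
  σ_r = 0.7 is near zero here rather than moderate.
- On piecewise-constant phantoms the Gaussian baseline is artificially
  strong for *segmentation*: a blurred step edge keeps its gradient ridge
  at the edge position, so the GVF snake localizes it almost as well as a
  sharp edge. Despeckling clearly beats *no* filtering (unfiltered FOM
  ≈ 0.65 vs ≥ 0.90 filtered, and the normalized filter beats the
  conventional), but the expected advantage of edge-preserving filters
  over plain Gaussian smoothing does not materialize on this scene class —
  it depends on real-image properties (weak, textured boundaries, adjacent
  structures) that the multiplicative i.i.d. model does not produce.
- The snake requires a user-supplied circular initialization inside the
  target region; there is no automatic follicle detection.
- The reference O(N·w²) bilateral implementation favors exactness over
  speed; no grid/permutohedral acceleration is provided.
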