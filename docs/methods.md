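# Methods

## Model

The observation model is `f = Poisson(K u)`: a clean nonnegative image
`u` is convolved with a known point-spread function (the linear
operator `K`) and each pixel of the result parametrizes an independent
Poisson draw. The negative log-likelihood of this model, up to terms
constant in `u`, is the Kullback–Leibler-type fidelity
`Σ_i (Ku)_i − f_i log (Ku)_i`, with the conventions `0·log 0 = 0` and
`log` of a nonpositive argument treated as −∞ (the objective returns
+∞ there). The estimator is the MAP solution under a prior combining
second-order total generalized variation with a quadratic term:

```
min_{u,p}  β Σ[(Ku) − f log(Ku)] + (λ/2)‖u‖² + α₁‖∇u − p‖₁ + α₀‖ε(p)‖₁ + ι₊(u)
```

TGV² balances first- and second-order smoothness: the auxiliary field
`p` absorbs smooth gradients (so affine ramps cost nothing beyond the
variation of `p`), while jumps in `u` itself are charged like TV —
edges survive, staircasing does not. The quadratic `λ‖u‖²` term is a
mild ridge that suppresses isolated bright speckles Poisson noise can
otherwise leave behind.

## Discretization

Images are H×W arrays (row = vertical/y, column = horizontal/x).
`D1`/`D2` are forward differences along columns/rows; `∇u = (D1 u,
D2 u)`. Divergences are *defined* as exact negative adjoints of the
gradients rather than as independent stencils, so the discrete
integration-by-parts identities hold to round-off and the normal
equations solved below are the true optimality systems of the discrete
objective. Symmetric 2×2 tensor fields store three planes `(t11, t22,
t12)`; because `t12` represents two equal matrix entries, it is
counted twice in every inner product and in the pointwise Frobenius
magnitude `√(t11² + t22² + 2 t12²)`. This weighting propagates
consistently into the tensor shrinkage step and the `p` normal
equations (the `2 y₃` terms).

Boundary handling is a modeling choice the data cannot decide; the
default is periodic, which makes every linear system circulant and
hence FFT-diagonal (exact solves in O(N log N)). A symmetric (Neumann)
alternative is provided — forward differences vanishing at the far
edge, blur realized as symmetric-pad → correlate → exact fold-back
adjoint — with conjugate-gradient solves replacing the FFT fast path.

## The split Bregman iteration

Constraints `Ku = w`, `∇u − p = x`, `ε(p) = y`, `u = z` split the
objective. Penalties are written `ρ/2 ‖residual + b‖²` with the
Bregman/dual update `b += residual` — the scaled-ADMM pairing in which
the dual step is an ascent step. (The mirrored convention
`‖residual − b‖²` with `b −= residual` is equivalent; mixing the two,
i.e. `‖r − b‖²` with `b += r`, performs dual *descent* and diverges
geometrically — the heavily weighted `u`-solve then reproduces `b₁` as
its own residual, doubling it each sweep. This failure mode was
observed directly and pinned the convention.)

Per outer iteration, in order:

1. `w`: pointwise positive root of the KL prox quadratic,
   `w = ½(a + √(a² + 4βf/μ₁))`, `a = Ku + b₁ − β/μ₁`;
2. `x`: isotropic vector shrinkage of `∇u − p + b₂` at threshold `α₁/μ₂`;
3. `y`: weighted-Frobenius tensor shrinkage of `ε(p) + b₃` at `α₀/μ₃`;
4. `(u, p)`: one Gauss–Seidel pass — `u` from the normal equation with
   system `λI + βμ₁KᵀK + α₁μ₂ΣDⱼᵀDⱼ + μ₄I` (FFT-diagonal), then `p₁`
   and `p₂` from their coupled systems using the freshest iterates;
   `inner_iters` repeats the pass for a stricter saddle-point solve;
5. `z = max(u + b₄, 0)`: the nonnegativity projection (ordered after
   the `u`-solve so the formula is well defined);
6. dual updates `b += residual` for all four constraints.

Initialization is `u⁰ = f` (a zero start makes the relative-change
stopping rule undefined) and zeros elsewhere; the stopping test
`‖u^{k+1} − u^k‖/‖u^k‖ ≤ tol` is skipped for the first two sweeps. The
returned image is projected onto `u ≥ 0`.

### The hybrid penalty weighting

The `w/x/y/z` steps use the raw penalties `μ₁…μ₄`, while the `(u, p)`
normal equations carry the coupled weights `βμ₁, α₁μ₂, α₀μ₃, μ₄`. These
two weightings do not assemble into one common augmented Lagrangian,
so the iteration is not a textbook ADMM: each sub-step exactly
minimizes *its own* sub-problem (verified against dense and
brute-force oracles to 1e−8), but no single augmented objective is
monotone under every sub-step — measured violations are ≤ ~3×10⁻⁴
relative at the `(u, p)` steps for the μ-weighted objective (and
conversely at the `w/x` steps for the coupled-weighted one); the
corresponding acceptance check documents this honestly rather than
asserting a property the scheme does not have. The two self-consistent
repairs were implemented and measured: penalizing with μᵢ everywhere,
or with the coupled weights everywhere, both restore the textbook
descent property but degrade restoration quality dramatically under
the published parameter values (≈ 25 dB vs ≈ 33 dB PSNR on the
Gaussian fixture). The hybrid weighting is therefore retained as the
package's algorithm: it is the formulation the parameter values were
evidently tuned for, it converges in 30–70 sweeps on all fixtures, and
its fixed points restore markedly better.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| β | KL fidelity weight | 54 | scale-dependent (counts at peak 255) |
| λ | quadratic weight | 1e−3 | 0 gives the plain-TGV reduction |
| α₀ | second-order TGV weight | 16 | large values → TV-like staircasing |
| α₁ | first-order TGV weight | 9 | |
| μ₁…μ₄ | splitting penalties | 0.1, 0.6, 0.1, 0.02 | affect speed, not the model |
| tol | relative-change stop | 1e−3 | |
| max_iter | sweep cap | 300 | typical runs stop at 30–70 |
| bc | boundary condition | periodic | symmetric uses CG solves |

The defaults are the published Gaussian-blur setting (preset `test1`);
presets `test2`/`test3` carry β=75, λ=1e−5, α₀=17, α₁=13 for the box
and motion protocols. The bracket notation α=[16, 9] is read as
(α₀, α₁), matching the weight-vector ordering α = (α₀, …, α_{k−1}) of
the general TGV definition; both weights are exposed by name so either
reading can be forced. Intensities are kept on their native scale
(8-bit ↦ [0, 255]) because β, the KL term and PSNR's 255² constant are
all scale-dependent.

## Synthetic data

`make_phantom` produces three phantom families, each mixing the two
regimes that discriminate TGV² from TV: smooth affine ramps (where TV
staircases) and sharp jumps (where quadratic smoothing blurs).
`ramp-disks` keeps its left 40% purely affine — second differences
vanish there by construction — with hard-edged disks on the right;
`shapes` is piecewise constant; `piecewise-affine` joins two ramps
along a seeded oblique line. All phantoms sit on a floor of 15
intensity units (so Poisson means stay strictly positive and the KL
term finite) and are affinely mapped to span exactly [15, 255], making
the brightest pixel equal the Poisson `peak` so the degradation
operates at unit scale, as when drawing counts directly from blurred
8-bit intensities.

`degrade` blurs with the requested PSF (periodic convolution), scales
by `peak / max(u)` (unity for the standard phantoms), and draws every
pixel from a Poisson law with a seeded generator. The three PSF
recipes are a sampled, renormalized 5×5 Gaussian with σ=2; a uniform
5×5 box; and an anti-aliased line segment of length r at θ degrees
counter-clockwise (rasterized by linear distance-to-segment falloff —
the kernel is normalized, so only the (length, angle) semantics, not a
particular rasterizer's bit pattern, are promised).

What the phantoms do *not* emulate: natural-image texture, correlated
(read-out) noise, saturation, and spatially varying blur. Passing the
quality gates on phantoms therefore demonstrates correct model
behavior in the staircase/edge regimes, not photographic performance;
published figures on standard photographs additionally depend on the
specific noise realization and are not reproducible from a seed.

## Numerical choices

- Shrinkage at zero magnitude returns zero (guarded division).
- `relerr` uses the scale-free `‖u − û‖₂ / ‖u‖₂`; a literal
  squared-norm denominator variant exists behind a flag but is not
  scale-free and disagrees with the metric's name.
- SSIM defaults to the standard local form — 11×11 Gaussian window
  (σ=1.5), stabilizers C₁=(0.01·255)², C₂=(0.03·255)², mean over the
  border-cropped map — which matches scikit-image's Gaussian-weighted
  implementation to ~1e−7 (cross-checked in tests); a literal global
  single-window form is available as `mode="global"`.
- PSNR/SNR return +∞ for exact equality by documented contract.
- FFT solves are exact for the periodic systems (strictly positive
  denominators since λ + μ₄ > 0); CG solves iterate to relative
  residual 1e−10.
- All stochastic components (phantoms, Poisson draws, fixture suites)
  are driven by explicit seeds through `numpy` SeedSequences; the
  solver itself is deterministic and bit-reproducible.

## Problem sizes

Tests and the acceptance script run on 64×64 (occasionally 32×32 and
128×128) phantoms with 5 noise seeds per PSF family — sizes at which
the staircase/edge contrasts are already visible and a full
restoration takes a fraction of a second, so the whole suite completes
in well under a minute.

## Known limitations

- Periodic boundaries wrap blur across opposite edges; for scenes with
  strong edge-to-edge intensity mismatch use `bc="symmetric"` (slower,
  CG path) or pre-taper.
- No automatic parameter selection: β, α₀, α₁ must be chosen per
  noise level and blur; the presets are starting points.
- Grayscale 2-D only; no color, no volumes, no spatially varying PSF.
- The iteration's hybrid weighting (above) lacks a global convergence
  proof; convergence is verified empirically on the fixture suite.
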