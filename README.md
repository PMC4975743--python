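# tgvdeblur

Restoration of blurred, photon-limited (Poisson-noisy) grayscale
images — the degradation regime of astronomical, fluorescence-microscopy
and low-dose medical imaging, where the noise at each pixel is a Poisson
draw whose variance equals the local signal, so Gaussian least-squares
fidelity terms are the wrong likelihood.

## The model

Given an observation `f = Poisson(K u)`, where `K` convolves with a
known point-spread function, the restored image solves

```
min_{u, p}  β Σ_i [ (Ku)_i − f_i log (Ku)_i ]          Poisson (KL) fidelity
          + (λ/2) ‖u‖²                                  quadratic damping
          + α₁ ‖∇u − p‖₁ + α₀ ‖ε(p)‖₁                   second-order TGV
          + ι_{u ≥ 0}(u)                                nonnegative counts
```

The pair of L1 terms is second-order total generalized variation
(TGV²): the auxiliary vector field `p` lets the image gradient follow
smooth ramps without cost, so edges are preserved **without** the
"staircase" plateaus that plain total variation imprints on smooth
regions; `ε(p)` is the symmetrized Jacobian of `p`. The small `λ‖u‖²`
term damps the speckle outliers that TGV alone can leave on Poisson
data.

The minimization runs as a split Bregman (ADMM) iteration: auxiliary
variables `w = Ku`, `x = ∇u − p`, `y = ε(p)`, `z = u` split the
objective so that every block update is closed-form — a pointwise
quadratic root for the KL term, isotropic soft-thresholding for the two
L1 terms, a projection for nonnegativity, and FFT-diagonal linear
solves for `u` and `p` under periodic boundaries (conjugate gradients
under symmetric/Neumann boundaries).

## Worked example

```python
from tgvdeblur import (BlurOperator, DegradationSpec, SolverParams,
                       degrade, evaluate, gaussian_psf, make_phantom, restore)

clean = make_phantom(64, 64, "ramp-disks", seed=1)       # ramp + sharp disks
f = degrade(clean, DegradationSpec("gaussian:5,2", seed=2))   # blur + Poisson
K = BlurOperator(gaussian_psf(5, 2), f.shape)

result = restore(f, K, SolverParams())
print(evaluate(clean, result.u).as_table())
```

Running `python examples/restore_phantom.py` (this exact pipeline)
prints:

```
converged: True after 44 iterations (final relative change 9.77e-04)

degraded vs clean:          restored vs clean:
SNR (dB)   17.9604          SNR (dB)   27.6619
PSNR (dB)  22.8249          PSNR (dB)  32.5264
RelErr     0.1265           RelErr     0.0414
MSE        339.3023         MSE        36.3447
SSIM       0.4810           SSIM       0.9459
```

The restoration recovers ~9.7 dB of PSNR and lifts SSIM from 0.48 to
0.95: most of what the 5×5 Gaussian blur and the photon noise destroyed
is recovered, with the ramp left smooth and the disk edges sharp.
Other examples: `examples/psf_gallery.py` (the three PSF recipes),
`examples/staircase_tgv_vs_tv.py` (how a large α₀ collapses TGV² to
TV and re-introduces staircasing), `examples/cli_pipeline.py` (the
shell workflow).

## Command line

```
tgvdeblur simulate --outdir fixtures --seed 3 --sizes 64
tgvdeblur restore  --input degraded.tif --output restored.tif \
                   --psf gaussian:5,2 --preset test1 --reference clean.tif
tgvdeblur metrics  clean.tif restored.tif
```

`--psf` accepts `gaussian:SIZE,SIGMA`, `box:SIZE`, `motion:LENGTH,ANGLE`
or `file:PATH`; `--preset test1/test2/test3` loads the published
parameter sets (e.g. test1: β=54, λ=0.001, α₀=16, α₁=9); any flag or a
YAML `--config` overrides preset values. `restore` exits 0 on
convergence, 2 if the iteration cap was reached, 1 on invalid input.

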