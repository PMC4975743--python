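"""Restore a blurred, Poisson-noisy phantom and score the result.

Builds a 64x64 synthetic phantom (smooth ramp + sharp disks), degrades
it with a 5x5 Gaussian blur (sigma 2) followed by per-pixel Poisson
noise at peak 255, runs the split Bregman TGV^2+L2 restoration at the
published parameters, and prints quality metrics before and after.
Higher PSNR/SSIM and lower RelErr mean the restoration is closer to
the clean image.
"""

import numpy as np

from tgvdeblur import (
    BlurOperator,
    DegradationSpec,
    SolverParams,
    degrade,
    evaluate,
    gaussian_psf,
    make_phantom,
    restore,
)

clean = make_phantom(64, 64, "ramp-disks", seed=1)
f = degrade(clean, DegradationSpec("gaussian:5,2", peak=255, seed=2))
K = BlurOperator(gaussian_psf(5, 2), f.shape)

result = restore(f, K, SolverParams())  # defaults = Gaussian-blur preset
print(f"converged: {result.converged} after {result.iterations} iterations "
      f"(final relative change {result.history['rel_change'][-1]:.2e})")

print("\ndegraded vs clean:")
print(evaluate(clean, f).as_table())
print("\nrestored vs clean:")
print(evaluate(clean, result.u).as_table())
print("\nThe PSNR gain (dB) is the headline number: the restoration should "
      "recover most of what blur + photon noise destroyed.")
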