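"""The three point-spread functions used in the degradation protocols.

Prints each kernel with its basic invariants: nonnegative entries that
sum to one (so blurring conserves total photon count), an unambiguous
center, and the expected support shape (isotropic bell, flat box,
oriented line segment).
"""

import numpy as np

from tgvdeblur import box_psf, gaussian_psf, motion_psf

np.set_printoptions(precision=3, suppress=True)

for psf in (gaussian_psf(5, 2), box_psf(5), motion_psf(2, 45)):
    k = psf.kernel
    print(f"--- {psf.name} ({k.shape[0]}x{k.shape[1]}) ---")
    print(k)
    print(f"sum = {k.sum():.6f}, max at {np.unravel_index(k.argmax(), k.shape)}\n")

print("A kernel that sums to 1 maps a constant image to itself; the solver "
      "relies on this flux conservation for Poisson data.")
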