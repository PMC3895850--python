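"""From wrapped phase images to a per-pixel displacement field.

The phase stage smooths each wrapped phase image by certainty-weighted
normalized averaging (certainty = signal magnitude, Gaussian width 1 px),
subtracts the reference acquisition, unwraps the net phases with a
least-squares Poisson solver confined to the wall mask, and decodes 3-D
displacement by solving (2 pi k_e) D u = phi per pixel.
"""

import numpy as np

import densewall as dw

spec = dw.PhantomSpec(snr=20.0, seed=3)  # uniform 6% expansion
acq, truth, delin = dw.make_phantom(spec)

field = dw.process_acquisition(acq, delin.mask, sigma_px=1.0)

err = np.linalg.norm((field.u - truth.displacement)[delin.mask], axis=-1)
print(f"decoded displacement on {delin.mask.sum()} wall pixels")
print(f"RMS error vs ground truth: {np.sqrt(np.mean(err ** 2)):.4f} mm "
      f"(pixel size {spec.pixel_spacing} mm)")
print(f"max error: {err.max():.4f} mm")
# At SNR 20 the certainty-weighted smoothing keeps the RMS displacement
# error well below a tenth of a pixel, which is what makes sub-pixel wall
# tracking possible on a 2-3 mm thick wall.
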