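"""What the TVDM metric measures, on a tiny synthetic pair.

Builds a phantom, misaligns a copy, and prints the total variation of the
difference map for the aligned pair, the misaligned pair, and a pair that
differs only by a constant intensity offset.  The metric should be near
zero for the aligned and offset pairs (constant backgrounds vanish under
the gradient) and clearly larger for the misaligned pair.
"""

import numpy as np

from tvdmreg import Image2D, make_phantom, tvdm_cost

phantom = make_phantom(128, 128, seed=1)
offset = Image2D(phantom.pixels + 0.6)
misaligned = Image2D(np.roll(phantom.pixels, (3, 5), axis=(0, 1)))

print(f"aligned pair:          {tvdm_cost(phantom, phantom, 1.0):.6f}")
print(f"constant offset +0.6:  {tvdm_cost(phantom, offset, 1.0):.6f}")
print(f"shifted by (5, 3) px:  {tvdm_cost(phantom, misaligned, 1.0):.6f}")
print()
print("A constant intensity offset is invisible to the metric; a few-pixel")
print("misalignment multiplies it by orders of magnitude — that contrast is")
print("what the registration search descends.")
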