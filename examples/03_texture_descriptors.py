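"""Census-transform texture descriptors of a spectrogram image.

Shows the three code operators (census transform, CLBP, LTP) on a small
image and assembles the two spatial-pyramid histogram descriptors.
"""

import numpy as np

from spectrotex import (ccentrist_descriptor, census_transform, clbp_codes,
                        ltp_codes, pyramid_blocks, tcentrist_descriptor)

rng = np.random.default_rng(0)
img = rng.integers(0, 256, (128, 128)).astype(np.uint8)

ct = census_transform(img)
s, m, c = clbp_codes(img)          # riu2-mapped sign/magnitude + center bit
up, lo = ltp_codes(img, mu=5.0)    # ternary split into upper/lower codes
print(f"census codes: shape {ct.codes.shape}, alphabet {ct.n_codes}")
print(f"CLBP S/M alphabet {s.n_codes} (riu2), C alphabet {c.n_codes}")
print(f"LTP upper/lower alphabet {up.n_codes}")

layout = pyramid_blocks(128, 128)  # levels 0-2 -> 1 + 4 + 16 = 21 blocks
cc = ccentrist_descriptor(img, layout)
tc = tcentrist_descriptor(img, layout)
print(f"pyramid blocks: {layout.n_blocks}")
print(f"cCENTRIST length {len(cc)} = 21 blocks x 200 joint (S,M,C) bins")
print(f"tCENTRIST length {len(tc)} = 21 blocks x (256 upper + 256 lower)")
print("block histograms are L1-normalized:",
      np.allclose(cc.values.reshape(21, 200).sum(axis=1), 1.0))
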