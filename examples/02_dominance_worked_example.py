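"""Recompute a reported dominance effect from its printed components.

The strongest reported dominance effect (a coat-colour-gene SNP) has
dominance values d_11 = 0.629, d_12 = -1.280, d_22 = 1.920 with genotype
frequencies 0.445 / 0.421 / 0.134: both homozygotes positive, the
heterozygote negative (homozygous advantage, heterozygous disadvantage).
"""

import numpy as np

from epigwas import GenotypeFreqs1L, days_open_advantage, partition_single_locus

d = np.array([0.629, -1.280, 1.920])  # (d11, d12, d22), % DPR
f = GenotypeFreqs1L([0.445, 0.421, 0.134])

# any mean + additive component cancels in the dominance contrast
g = d + 55.0
part = partition_single_locus(g, f)
print("dominance values   :", part.d.round(3))
print("dominance effect   :", round(part.delta, 3))       # -2.555 (published)

# heterosis arithmetic: crossbred vs Holstein mean daughter pregnancy rate
adv = days_open_advantage(54.9703, 49.06)
print("days-open advantage:", round(adv, 1), "-> about", round(adv), "fewer days open")
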