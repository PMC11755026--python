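"""Gini inequality and Yitzhaki/Deaton relative deprivation.

Small worked examples first, then the identity that anchors the whole
module: the mean Deaton index of a population equals its Gini index.
"""

import numpy as np

from neighbordep import deaton, gini_exact, yitzhaki

incomes = [1, 2, 3]
print(f"incomes {incomes}: Gini = {gini_exact(incomes):.4f}")
print(f"poorest member: Yitzhaki = {yitzhaki(1, incomes):.3f} "
      f"(mean shortfall vs richer), Deaton = {deaton(1, incomes):.3f}")
print(f"richest member: Deaton = {deaton(3, incomes):.3f} (no one richer)")

# scale invariance: Deaton is a *relative* measure
print(f"after doubling all incomes: Deaton(poorest) = {deaton(2, [2, 4, 6]):.3f}")

# mean Deaton == Gini, the module's core identity
rng = np.random.default_rng(0)
y = rng.lognormal(12, 0.6, 500)
mean_d = np.mean([deaton(v, y) for v in y])
print(f"\nlog-normal sample (n=500): Gini = {gini_exact(y):.6f}, "
      f"mean Deaton = {mean_d:.6f}")
print(f"difference: {abs(mean_d - gini_exact(y)):.2e} (machine precision)")
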