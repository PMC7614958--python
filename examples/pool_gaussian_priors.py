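"""Pooling two overlapping Gaussian prior marginals.

Three submodels share quantities pairwise along a chain: p1 puts N(-2.5, 1)
on phi12, p3 puts N(2.5, 1) on phi23, and the middle submodel p2 puts a
correlated bivariate normal (rho = 0.8) on both.  The four chained pooling
operators combine these into one joint prior; the printed correlations show
which operators keep the middle submodel's dependence.
"""

import numpy as np

from chainmeld import (
    PhiLayout,
    gaussian_component,
    gaussian_pool_closed_form,
    pool_dictatorial_complete,
    pool_linear,
    pool_log,
)
from chainmeld.pooling import SubmodelPrior, grid_moments_2d

layout = PhiLayout(("phi12", "phi23"), (1, 1))
COV2 = np.array([[1.0, 0.8], [0.8, 1.0]])
p1 = gaussian_component(-2.5, 1.0, ("phi12",))
p2 = gaussian_component(np.zeros(2), COV2, ("phi12", "phi23"))
p3 = gaussian_component(2.5, 1.0, ("phi23",))

# logarithmic (product-of-experts) pooling: precisions add
poe = gaussian_pool_closed_form(
    [(np.array([-2.5]), np.eye(1), ("phi12",)),
     (np.zeros(2), COV2, ("phi12", "phi23")),
     (np.array([2.5]), np.eye(1), ("phi23",))],
    np.ones(3),
    layout,
)
corr_poe = poe.cov[0, 1] / np.sqrt(poe.cov[0, 0] * poe.cov[1, 1])
print(f"PoE pooling:        mean {poe.mean.round(3)}, correlation {corr_poe:.3f}")

# linear pooling: per-overlap mixtures, independent across overlaps
p2a = gaussian_component(0.0, 1.0, ("phi12",))
p2b = gaussian_component(0.0, 1.0, ("phi23",))
lin = pool_linear([(p1, p2a), (p2b, p3)], np.full((2, 2), 0.5), layout)
mom = grid_moments_2d(lin.log_density, [(-8, 8), (-8, 8)], 201)
print(f"linear pooling:     mean {mom['mean'].round(3)}, correlation {mom['corr']:.3f}")

# complete dictatorial pooling with the middle submodel authoritative
sps = [
    SubmodelPrior(1, p1, {"phi12": p1}),
    SubmodelPrior(2, p2, {"phi12": p2a, "phi23": p2b}),
    SubmodelPrior(3, p3, {"phi23": p3}),
]
dict_mid = pool_dictatorial_complete(sps, [2, 2], layout)
mom_d = grid_moments_2d(dict_mid.log_density, [(-8, 8), (-8, 8)], 201)
print(f"dictatorial (p2):   mean {mom_d['mean'].round(3)}, correlation {mom_d['corr']:.3f}")

print(
    "\nPoE blends all three marginals (correlation shrinks toward the middle\n"
    "prior's 0.8 as lambda_2 dominates); linear pooling always destroys the\n"
    "cross-overlap correlation; the dictatorial middle keeps p2 verbatim."
)
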