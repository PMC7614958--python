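"""Normal-approximation melding on the conjugate Gaussian chain.

Instead of recycling stage-one draws, the outer subposteriors and their
priors are summarised as Gaussians and folded into the middle submodel via
the precision-difference correction

    Sigma = (Sigma_nu^{-1} - Sigma_de^{-1})^{-1},
    mu    = Sigma (Sigma_nu^{-1} mu_nu - Sigma_de^{-1} mu_de).

On a chain whose subposteriors are exactly Gaussian the approximation is
exact, so the fitted moments should match the closed-form melded posterior.
"""

import numpy as np

from chainmeld.gaussian_meld import (
    GaussianSummary,
    approx_melded_log_density,
    fit_gaussian,
    gaussian_correction,
    stack_block_diag,
)
from chainmeld.samplers import MHConfig, adaptive_rwmh
from chainmeld.validation import GaussianChainDemo

demo = GaussianChainDemo()
rng = np.random.default_rng(0)

# summarise the side subposteriors from draws (as one would in practice)
draws1 = demo.exact_side_subposterior(1).sample(rng, 20_000)
draws3 = demo.exact_side_subposterior(3).sample(rng, 20_000)
nu = stack_block_diag(
    fit_gaussian(draws1[:, 0], "phi12"), fit_gaussian(draws3[:, 0], "phi23")
)
de = GaussianSummary(np.zeros(2), np.eye(2), "side priors")  # the N(0,1) priors
corr = gaussian_correction(nu, de)
print(f"correction mean {corr.mean.round(3)}, sd {np.sqrt(np.diag(corr.cov)).round(3)}")

ld = approx_melded_log_density(corr, demo.sub2)
samples, acc = adaptive_rwmh(
    lambda v: ld(v[:2], v[2:]), np.zeros(3), MHConfig(iterations=40_000, warmup=10_000), rng
)
exact = demo.exact_melded_posterior()
print("quantity   approx-meld mean   exact mean")
for col, (name, idx) in enumerate([("phi12", 0), ("phi23", 1), ("psi2", 3)]):
    print(f"{name:<9} {samples[:, col].mean():>15.3f} {exact.mean[idx]:>12.3f}")
print(
    "\nBecause the side subposteriors here are exactly Gaussian, the\n"
    "approximate melded posterior coincides with the exact one up to the\n"
    "Monte-Carlo error of the moment fits and the sampler."
)
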