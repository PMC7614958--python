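"""Exact validation of the stage-two sampler on a fully discrete chain.

With every variable in {0, 1, 2} the melded posterior (243 joint states)
can be enumerated, and the three Metropolis-within-Gibbs block kernels can
be written down as 27x27 matrices.  Detailed balance then holds exactly,
and long-run frequencies converge to the enumerated posterior.
"""

import numpy as np

from chainmeld.samplers import StageTwoConfig, run_stage_two
from chainmeld.validation import DiscreteChainDemo, UniformDiscreteKernel

demo = DiscreteChainDemo()
target = demo.melded_marginal_pmf()
flat = target.ravel()

for name, K in demo.block_kernels().items():
    flux = flat[:, None] * K
    print(f"{name}: max detailed-balance violation {np.abs(flux - flux.T).max():.2e}")

pool = demo.stage_one_pool(np.random.default_rng(0), 50_000, 50_000)
draws = run_stage_two(
    pool, demo.sub2, demo.pooled,
    StageTwoConfig(sweeps=100_000, chains=1, warmup_frac=0.05),
    psi2_init=np.zeros(1),
    psi2_kernel_factory=lambda: UniformDiscreteKernel(),
    rng=np.random.default_rng(1),
)
i = draws.stacked("phi12").astype(int).ravel()
j = draws.stacked("phi23").astype(int).ravel()
k = draws.stacked("psi2").astype(int).ravel()
emp = np.zeros((3, 3, 3))
np.add.at(emp, (i, j, k), 1.0)
emp /= emp.sum()
tv = 0.5 * np.abs(emp - target).sum()
print(f"total variation after {i.size} sweeps: {tv:.4f}")
print(
    "\nDetailed-balance violations at machine precision mean each block\n"
    "kernel is exactly reversible for the melded posterior; the total\n"
    "variation shrinks toward zero as sweeps and the stage-one pool grow."
)
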