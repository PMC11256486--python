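"""FDR-controlled power for the serum study design.

With effect size 0.68 (the log2 fold-change threshold), SD 0.4375 (the
median protein SD), pi0 = 0.66 and FDR 0.1, the average power of the
two-sided two-sample comparison is computed per sample size via the
noncentral-t fixed point, and the smallest n reaching 0.8 power is found.
"""

import numpy as np

from tmtserum import PowerSpec, estimate_pi0, fdr_power, min_n_for_power
from tmtserum.power import power_table

spec = PowerSpec(effect_size=0.68, sigma=0.4375, pi0=0.66, fdr=0.10, n=10)
print("n per group   alpha_c      power")
for n, p in power_table(spec, range(5, 16)):
    a = fdr_power(PowerSpec(effect_size=0.68, sigma=0.4375, pi0=0.66,
                            fdr=0.10, n=n)).alpha_c
    marker = "  <- smallest group of the cohort" if n == 10 else ""
    print(f"{n:>10d}   {a:.5f}   {p:.4f}{marker}")

print(f"\nsmallest n with power >= 0.8: {min_n_for_power(spec, 0.8)}")

# pi0 estimation demo: a p-value mixture with two thirds true nulls
rng = np.random.default_rng(0)
p = np.concatenate([rng.uniform(size=13200), rng.beta(0.1, 1.0, size=6800)])
print(f"pi0 estimated from a 66% null mixture of 20,000 p-values: "
      f"{estimate_pi0(p):.3f}")
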