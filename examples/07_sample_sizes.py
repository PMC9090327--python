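"""A-priori sample sizes for the follow-up experiments.

Binomial: detect 15% vs chance 12.5% (one-sided, alpha 0.00625, power
0.95). t-test: detect Cohen's d = 0.2 (one-sided, alpha 0.05, power 0.95,
two equal groups).
"""
from oneshotshapes.stats import binomial_sample_size, t_test_sample_size

b = binomial_sample_size(p0=0.125, p1=0.15, alpha=0.00625, power=0.95)
print(f"binomial trials needed (normal approximation): {b.n}")
print(f"  exact-binomial search alternative: {b.exact_n}")
t = t_test_sample_size(d=0.2, alpha=0.05, power=0.95)
print(f"t-test total sample size: {t.n} "
      f"({t.params['n_per_group']} per group)")
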