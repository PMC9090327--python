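"""Category membership: 8-way sorting with per-cell binomial tests.

Simulated observers sort variations into the eight categories; the
confusion matrix is tested cell-wise against chance (12.5%) with a
Bonferroni-adjusted one-sided binomial test.
"""
from oneshotshapes.pipeline import RunConfig, prepare_dataset, run_experiment

cfg = RunConfig(seed=1, n_drawers=8, n_variations=8, exp3_bins=20)
data = prepare_dataset(cfg)
out = run_experiment("exp3", cfg, data)
print(f"correct: {out['k']}/{out['n']} = {100 * out['proportion']:.1f}% "
      f"(chance 12.5%, p={out['overall_test'].p_value:.2e})")
cm = out["confusion"]
diag_sig = [int(cm.significant.loc[c, c]) for c in cm.counts.index]
print("diagonal cells above chance at alpha=0.00625:", sum(diag_sig), "of 8")
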