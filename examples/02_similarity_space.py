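"""Similarity space: normalize placements, rank drawers, pick a subset.

Raters place each variation on an axis; distances are rescaled per rater
to [0, 1] (0 = exemplar), averaged, and used to pick a stimulus subset
spanning the similarity range in 20 equal-width bins.
"""
from oneshotshapes.pipeline import RunConfig, prepare_dataset, run_experiment

cfg = RunConfig(seed=1, n_drawers=8, n_variations=8)
data = prepare_dataset(cfg)
out = run_experiment("exp2", cfg, data)
trend = out["order_trend"]
print(f"pooled order trend: slope={trend.slope:.4f} R^2={trend.r_squared:.4f} "
      f"F({trend.df[0]},{trend.df[1]})={trend.f_stat:.2f} p={trend.p_value:.2f}")
# a flat trend means a drawer's later drawings are no closer to the
# exemplar than earlier ones (no drift over the session)
subset = out["spanning_subset"][4]
svals = out["scores"].loc[subset, "s"].round(2).tolist()
print(f"category 4 spanning subset ({len(subset)} shapes), similarities:")
print(svals)
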