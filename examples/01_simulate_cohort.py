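"""Simulate a drawing cohort: 17 drawers x 12 variations x 8 exemplars.

Each exemplar is a main body with 0-5 attached parts; variations warp the
body and may shuffle, mirror, omit, add or substitute parts, with all
ground truth recorded.
"""
from oneshotshapes.synthetic import generate_cohort

cohort = generate_cohort(seed=1)
df = cohort.records_frame()
print(f"drawings: {len(df)}  (per exemplar: "
      f"{df.groupby('category').size().iloc[0]})")
print("part-order ground truth:",
      df["order_class"].value_counts().to_dict())
by_drawer = df.groupby("drawer")["deviation"].mean()
print("least creative drawer mean deviation:", round(by_drawer.min(), 3))
print("most creative drawer mean deviation: ", round(by_drawer.max(), 3))
# deviation is the ground-truth dissimilarity to the exemplar (0 = copy);
# drawers are constructed with increasing characteristic magnitudes
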