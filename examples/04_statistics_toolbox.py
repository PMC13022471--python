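"""The statistical primitives on their own: BH-FDR, the mixed three-way
ANOVA's error strata, and Duncan's multiple range test."""

import numpy as np
import pandas as pd

from coherostrat import duncan_mrt, fdr_bh, mixed_anova_totcoh

# Benjamini-Hochberg step-up over one family of raw p-values
mask, p_fdr = fdr_bh([0.001, 0.01, 0.02, 0.03, 0.5], q=0.05)
print(f"BH: reject {mask.sum()} of 5, adjusted threshold p_FDR = {p_fdr}")

# mixed ANOVA on a synthetic Total Coherence table: 87 subjects split
# 42/45, five ROIs, two bands -> Group x ROI tested on (4, 340) df
rng = np.random.default_rng(0)
rows = []
for i in range(87):
    for roi in ("Frontal", "Central", "Parietal", "Occipital", "Temporal"):
        for band in ("Alpha 2", "Beta 1"):
            rows.append({"subject": f"S{i}", "band": band, "scope": roi,
                         "value": rng.normal(0.3, 0.05), "n_pairs": 1})
tot = pd.DataFrame(rows)
groups = {f"S{i}": ("L-MEP" if i < 42 else "H-MEP") for i in range(87)}
res = mixed_anova_totcoh(tot, groups)
row = res.effect("Group x ROI")
print(f"Group x ROI: F({row['df_num']:.0f}, {row['df_den']:.0f}) = "
      f"{row['F']:.3f}, p = {row['p']:.3f}  [null data]")

# Duncan's multiple range test over five cell means
table = duncan_mrt([0.30, 0.31, 0.33, 0.42, 0.44], n_per_cell=20,
                   ms_error=0.004, df_error=40,
                   labels=["A", "B", "C", "D", "E"])
sig = table[table["significant"]]
print("Duncan-separated pairs:",
      ", ".join(f"{r.cell_a}-{r.cell_b}" for r in sig.itertuples()))
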