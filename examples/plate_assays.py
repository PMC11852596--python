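"""Plate-assay quantification: viability, melanin content, qPCR fold change.

All three are tiny closed-form calculations over plate readings; inputs
here are inline replicate tables.
"""

import pandas as pd

from colmorph import cell_survival, melanin_content, relative_expression
from colmorph.assay import mean_sem

# CCK-8 viability at 450 nm: sample, blank and untreated-control wells
viab = [cell_survival(od, od_blank=0.08, od_control=0.92)
        for od in (0.74, 0.71, 0.77)]
m, s = mean_sem(viab)
print(f"cell survival:   {m:.1f} +/- {s:.1f} %  (3 replicate wells)")

# melanin at 405 nm, percent of the control-group mean OD
mel = [melanin_content(od, control_ods=[0.51, 0.49, 0.50])
       for od in (0.33, 0.35, 0.31)]
m, s = mean_sem(mel)
print(f"melanin content: {m:.1f} +/- {s:.1f} %  (below 100% = less pigment)")

# TYR mRNA by 2^(-ddCt): target normalised to beta-actin, treated vs control
qpcr = pd.DataFrame({
    "condition": ["treated"] * 2 + ["control"] * 2,
    "gene": ["target", "reference"] * 2,
    "ct": [24.95, 18.60, 24.11, 18.60],
})
fold = relative_expression(qpcr)
print(f"TYR fold change: {fold:.3f}  (< 1 = down-regulated vs control)")
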