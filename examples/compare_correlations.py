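"""Fisher r-to-z comparison of a raw versus a log-transformed correlation.

The published phospho-TBK1 : phospho-RelA contrast: in each cell type the
correlation improves when phospho-RelA is natural-log transformed, and the
r-to-z test quantifies whether the improvement is significant.
"""

import pandas as pd

from pathscreen import table1_report

rows = pd.DataFrame(
    [
        {"cell_type": "CD4+ T", "r_raw": 0.72, "r_transformed": 0.83, "n": 115},
        {"cell_type": "CD8+ T", "r_raw": 0.72, "r_transformed": 0.84, "n": 99},
        {"cell_type": "B", "r_raw": 0.68, "r_transformed": 0.86, "n": 108},
        {"cell_type": "monocyte", "r_raw": 0.44, "r_transformed": 0.74, "n": 115},
    ]
)

table = table1_report(rows)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(
    "p_rtoz is the two-sided p for the hypothesis that the two correlations\n"
    "are equal: every cell type favours the exponential (ln-transformed)\n"
    "model, monocytes most decisively (p = 0.0003)."
)
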