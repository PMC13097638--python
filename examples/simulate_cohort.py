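"""Simulate the default event-level cohort and summarise it.

Four mononuclear cell types (n = 115/99/108/115), eleven STING-pathway
analytes, ~6246 flow-cytometry events per peak, with the four embedded
coupling motifs (linear, logarithmic, exponential, inverse power).
"""

import numpy as np

from pathscreen import default_config, generate_cohort, summarise_medians, zscore

events, truth = generate_cohort(default_config(seed=1))
medians = summarise_medians(events)

print("samples per cell type:", {ct: len(m) for ct, m in medians.items()})
print(
    "mean events per peak:",
    round(float(np.mean([len(e) for e in events.records["events"]])), 1),
)

b = medians["B"]
print("\nB-cell median fluorescence (first 3 samples):")
print(b[["pSTING", "BDNF", "pTBK1", "pRelA"]].head(3).round(1))

z = zscore(medians)
print("\nper-analyte Z-scored cell-type means (pooled scaling):")
for ct in medians:
    print(f"  {ct:9s} STING={z[ct]['STING'].mean():+.2f}  IRF3={z[ct]['IRF3'].mean():+.2f}")
print(
    "\nB cells sit far below the other cell types on STING and IRF3 —\n"
    "the simulated cohort reproduces that cell-type-specific configuration."
)
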