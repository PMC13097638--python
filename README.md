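# pathscreen

Screening and classification of linear and nonlinear bivariate
associations among signalling-pathway components measured by flow
cytometry.

## The problem

Intracellular signalling pathways — here the STING (stimulator of
interferon genes) pathway in human peripheral blood mononuclear cells —
can be mapped from clinical samples by correlating the per-sample
expression levels of pathway components across a patient cohort. A linear
correlation between an upstream and a downstream component suggests
*rheostatic* regulation: a graded change upstream produces a
proportional change downstream. But threshold-like ("on-off")
regulation produces *nonlinear* bivariate relationships —
logarithmic, exponential, or power — that an ordinary Pearson
correlation matrix understates or misses entirely.

`pathscreen` implements the screening strategy for such relationships:

1. **Summarise** flow-cytometry event clouds to per-sample median
   fluorescence intensities (MFI), one expression matrix per cell type.
2. **Compare cell types** by one-way ANOVA on per-analyte Z-scores
   (pooled across cell types), Bonferroni-corrected.
3. **Screen** every analyte pair with four transform-pair Pearson
   matrices — (x, y), (ln x, y), (x, ln y), (ln x, ln y) — shading
   strong (|r| ≥ 0.7) and weak (0.6 < |r| < 0.7) entries and flagging
   pairs whose transformed |r| beats the raw |r| at the strong threshold.
4. **Fit and classify** each pair by linearized least squares over the
   four model forms

   | form | model | linearizing coordinates | label |
   |---|---|---|---|
   | linear | y = ax + b | (x, y) | rheostat |
   | logarithmic | y = a·ln(x) + b | (ln x, y) | on-switch |
   | exponential | y = a·e^(bx) | (x, ln y) | on-switch |
   | power | y = a·x^b | (ln x, ln y) | on-switch (b > 0) / off-switch (b < 0) |

   taking the form with maximal linearized \|r\| (ties within 0.01 resolve
   to linear for parsimony).
5. **Test model-form improvement** with the Fisher r-to-z comparison of
   two correlations: z_i = atanh(r_i),
   z = (z₂ − z₁)/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.

Because no public cohort is deposited, the package ships a seeded
event-level simulator (`pathscreen.simulate`) that reproduces the study
design — 4 cell types with n = 115/99/108/115 samples, 11 analytes
(STING, pSTING, pTBK1, pRelA, IRF3, NLRP3, BDNF, pAkt, pULK1, Traf6,
MyD88), ~6246 log-normal events per peak — with the four coupling motifs
embedded as ground truth, plus an agonist-titration mode (6 donors × 6
dose levels: 0 and five 5-fold dilutions from 1 μM). Real data enters as
plain wide-format TSV expression tables.

## Worked example

Comparing the raw and ln-transformed correlation of two pathway
components across four cell types (`examples/compare_correlations.py`):

```python
import pandas as pd
from pathscreen import table1_report

rows = pd.DataFrame([
    {"cell_type": "CD4+ T",   "r_raw": 0.72, "r_transformed": 0.83, "n": 115},
    {"cell_type": "CD8+ T",   "r_raw": 0.72, "r_transformed": 0.84, "n": 99},
    {"cell_type": "B",        "r_raw": 0.68, "r_transformed": 0.86, "n": 108},
    {"cell_type": "monocyte", "r_raw": 0.44, "r_transformed": 0.74, "n": 115},
])
print(table1_report(rows).to_string(index=False))
```

prints

```
cell_type   n  r_raw     p_raw  r_transformed  p_transformed  z_stat    p_rtoz
   CD4+ T 115   0.72 1.217e-19           0.83      2.007e-30   2.099   0.03582
   CD8+ T  99   0.72 4.533e-17           0.84      1.678e-27   2.172   0.02984
        B 108   0.68 5.828e-16           0.86      9.579e-33   3.364 0.0007691
 monocyte 115   0.44 8.641e-07           0.74      3.461e-21   3.579 0.0003451
```

Each row: both correlations are individually significant (`p_raw`,
`p_transformed` are two-sided Pearson p-values), and `p_rtoz` tests
whether the ln-transformed correlation is *better* — it is, in every cell
type, which is the signature of an exponential rather than linear
coupling between the two components.

The other scripts in `examples/` each demonstrate one capability:
cohort simulation (`simulate_cohort.py`), the transform-pair screen
(`screen_correlations.py`), model-form classification
(`classify_pair.py`), the dose titration (`titration.py`) and the full
pipeline (`full_pipeline.py`).

A thin CLI wraps the same library functions:

```bash
pathscreen run --seed 1 --out results_dir        # full pipeline
pathscreen table1 triplets.tsv                   # r-to-z contrast table
pathscreen simulate --seed 1 --out sim_dir       # cohort simulation only
```

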