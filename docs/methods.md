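# Methods

## Model and procedure

The object of analysis is a cohort of per-sample, per-cell-type
expression levels of signalling-pathway components ("analytes"),
measured by flow cytometry as the median fluorescence intensity (MFI) of
a unimodal event peak. A bivariate relationship between analytes x and y
is modelled by one of four forms — linear y = ax + b, logarithmic
y = a·ln(x) + b, exponential y = a·e^(bx), power y = a·x^b — each of
which is linear in some combination of log-transformed coordinates.
All fitting is *linearized* ordinary least squares on those coordinates
(the computation a spreadsheet trendline performs), not iterative
nonlinear least squares: the reported r values are Pearson coefficients
on the linearizing coordinates, which is exactly what the screening
matrices measure, so the screen and the fits agree by construction.

Screening computes four Pearson matrices per cell type over the analyte
panel: raw (x, y), the two mixed matrices (ln x, y) and (x, ln y), and
the double-log (ln x, ln y). The mixed matrices are asymmetric —
r(ln x, y) ≠ r(x, ln y) in general — and are stored as full tables; they
are transposes of one another. Entries are classified strong
(|r| ≥ 0.7), weak (0.6 < |r| < 0.7) or unshaded; the boundary values
0.7 and 0.6 classify as strong and unshaded respectively (the weak band
is open). A pair becomes a *nonlinear candidate* when a
transformed-coordinate |r| exceeds the raw |r| and reaches the strong
threshold. The diagonal r(x, ln x) is reported per analyte as a
transform self-check and flagged when ≤ 0.9: over a typical MFI spread
this correlation is high, and a low value warns that the raw and
log-scale screens could diverge for reasons unrelated to any coupling.

Classification takes the admissible form with maximal linearized |r|.
Forms requiring positivity (logarithmic/power in x, exponential/power in
y) are skipped — recorded as inadmissible, not errored — when the data
contain nonpositive values. A nonlinear winner must beat the linear |r|
by more than a tie tolerance (default 0.01) to displace it; this
parsimony margin prevents overcalling nonlinearity from noise and is
configurable. The regulatory label is a fixed taxonomy, not an
inference: linear → rheostat; logarithmic and exponential → on-switch;
power → off-switch when b < 0, on-switch when b > 0. The label is
withheld when even the best |r| is below the strong threshold.

Model-form improvement is tested with the Fisher r-to-z comparison of
two correlations using the independent-samples formula
z = (atanh r₂ − atanh r₁)/√(1/(n₁−3) + 1/(n₂−3)). The two correlations
in this use share the same samples, so the independent formula is an
approximation; it is nevertheless the default because it reproduces the
published contrast table numerically, and every result records which
method produced it. A dependent-correlation alternative (Steiger's Z for
overlapping correlations, using the correlation between the two response
coordinates) is available behind a flag. Perfect correlations (|r| = 1,
infinite Fisher z) degenerate the contrast to p = 0 or 1 directly. No
multiplicity correction is applied to the contrast p-values. All tests
are two-sided.

Pearson significance uses t = r·√((n−2)/(1−r²)) on n−2 degrees of
freedom; |r| = 1 returns p = 0 exactly. Cell-type comparisons are plain
one-way ANOVAs (no Welch correction) per analyte and unordered cell-type
pair on Z-scores, Bonferroni-adjusted with family size m = 6 by default
(the six pairs among four cell types, a per-analyte family); m is
configurable — e.g. 66 to span a panel of eleven analytes — and is echoed
in every result row. Z-scores pool all samples of all cell types per
analyte (ddof = 1); pooling within a cell type would force every
cell-type mean to zero and defeat the comparison. Association analyses
always consume raw positive medians, never Z-scores, since ln of a
negative Z-score is undefined.

## Synthetic cohorts

The simulator emulates the study design: four mononuclear cell types
(CD4+ T, CD8+ T, B, monocytes) with sample counts 115/99/108/115, eleven
STING-pathway analytes, and a mean of 6246 events per peak. Each
(sample, analyte) has a latent median; uncoupled analytes draw it
log-normally around a per-(cell type, analyte) baseline location with a
between-sample log-SD (default 0.5, i.e. ~50% coefficient of variation —
a spread wide enough that the four model forms are mutually
distinguishable over the realised x-range). Couplings act on the latent
scale in declaration order (the coupling graph must be acyclic) with
Gaussian noise added on each form's linearizing coordinate — on y for
linear/logarithmic, on ln y for exponential/power — so the generator's
truth coincides exactly with the fitter's model and recovered
coefficients are directly comparable to the truth. Latents that come out
nonpositive (possible for linear/logarithmic couplings) are resampled up
to 100 times, then error. Event clouds are log-normal around the latent
median (median of a log-normal is e^μ, so the peak is centred on the
truth) with within-peak log-SD 0.25, matching unimodal, right-skewed,
limited-variance fluorescence peaks; event counts are Poisson. An
optional per-cell-type dropout list emulates pre-registered viability
exclusions.

The default couplings embed the four motifs: linear STING→BDNF and
STING→pAkt in T cells and monocytes, logarithmic pSTING→BDNF and
pSTING→pAkt in B cells, inverse-power pSTING→pTBK1 (b = −1.5) and
exponential pTBK1→pRelA (b = 0.004) in every cell type. Coefficient
values are the package's own choices (none are published), sized so each
form's linearized signal spans O(1) at baseline MFI scales of roughly
100–200 units. Baseline locations qualitatively echo the reported
cell-type differences (B cells low in STING and IRF3; antigen-presenting
cells lower in pRelA and IRF3 than T cells).

The titration mode emulates the in-vitro agonist experiment: 6 donors ×
6 dose levels (0 plus five 5-fold dilutions from 1 μM). Dose drives the
root analyte (pSTING) through a strictly increasing saturating response
base + gain·d/(d + EC50) with a log-normal donor effect; downstream
analytes follow couplings, by default logarithmic pSTING→pTBK1 and
exponential pTBK1→pRelA — the short-term stimulation behaviour, which
differs from the ex-vivo inverse-power pSTING:pTBK1 motif.

Default coupling noise is SD 0.05 on the linearized coordinate. For the
exponential and power forms this is a ~5% multiplicative error — small
relative to biological scatter, and the simulated linearized r values
(≈ 0.99) are correspondingly higher than clinically observed ones
(0.4–0.9). The generator therefore demonstrates *recoverability* of the
embedded structure by the pipeline, not the noise regime of patient
data; noise is per-coupling configurable for harder regimes. Other real
features not emulated: instrument compensation/spillover, gating
artefacts, doublets, batch effects, heavy-tailed event distributions,
and any dependence of missingness on signal.

## Calibration experiments

`pathscreen.validate` runs replicate-level studies through the full
chain (event simulation → medians → classification). With 200 replicates
per form at the cohort sample sizes and noise SD 0.05, the generating
form and switch label are recovered in ≥ 95% of replicates for every
form, and both coefficients land within 10% relative error in ≥ 95%.
The binding constraint is the power-law prefactor a = e^intercept: its
log-scale standard error (~0.046 at n = 108) puts a 10% (|Δln a| ≤
0.095) band at roughly ±2 SE, so its replicate success rate sits near
96%, the closest to the bound. The screening-power study measures how
often the (x, ln y) matrix entry beats the raw entry for an exponential
truth at the smallest cohort size (n = 99): effectively always, which is
why the screen's uniform improvement across cell types is expected
whenever the truth is exponential.

## Numerical choices and conventions

- Medians use the mean-of-central-pair convention for even counts; an
  empty event list yields a missing value with a logged warning.
- Correlations use pairwise-complete observations with the per-pair n
  recorded (cohort n varies by cell type; listwise deletion would drop
  samples asymmetrically); entries with n < 3 or zero variance in either
  coordinate are missing (the latter with a warning).
- ln is the natural log of raw positive medians only; a matrix
  containing nonpositive values is an error, never silently shifted.
- Pipeline TSVs write floats at repr precision and are parsed back with
  round-trip float parsing, so re-running downstream stages from emitted
  files reproduces every table byte-for-byte.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; equal config and seed give byte-identical
  serialized outputs.
- Problem sizes in the shipped studies: 200 replicates per form for
  recovery, 100 replicates for screening power, two-analyte cohorts at
  the relevant cell type's n with full 6246-event peaks — large enough
  that the rates are stable to ~1–2 percentage points across seeds.

## Known limitations

- The independent-samples r-to-z contrast understates the information in
  shared-sample comparisons; the Steiger variant is provided but is not
  the default (see above).
- Classification is a label over fitted forms, not causal inference: the
  analysis provides no directionality, and couplings' x→y orientation in
  the simulator is a generative convention.
- The transform screen covers only the four forms linearizable by ln;
  saturating (Michaelis–Menten-like) or non-monotone relationships fall
  outside it and would surface, at best, as their nearest linearizable
  approximation.
- The "single exception" behaviour of the x-vs-ln(x) self-check seen in
  patient data is data-dependent; the package reports the check but
  cannot reproduce the exception without that data.
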