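# radrecon

Quantitative reconstruction of absorbed ionizing-radiation dose (in Gy)
from blood gene-expression profiles.

After a large-scale radiological event, triage requires estimating the
dose each exposed person received. mRNA levels in blood cells measured
~24 h after exposure carry that information: a few dozen genes rise
monotonically (and concavely) with dose. `radrecon` implements a complete
training/testing pipeline that turns log2 expression matrices into
continuous dose estimates:

1. **Signature selection.** On a training dataset, keep genes whose
   Spearman correlation with dose is Bonferroni-significant (α = 0.05)
   *and* larger than that of every injected synthetic noise variable
   (normal and uniform pseudo-genes matched to the pooled mean/SD of the
   real data, ~3:1 noise-to-gene ratio). Because samples at different
   doses come from the same blood donors, each surviving gene must also
   keep a Bonferroni-significant dose slope in a linear mixed-effects
   model with a random per-donor intercept. Repeated k-means clustering
   (50 restarts; a gene's score is how often it lands in the cluster whose
   median profile correlates best with dose), dose-label permutation, and
   a planted-predictor scenario provide robustness, false-positive and
   sensitivity controls.
2. **Normalizer selection.** Baseline expression drifts 2–4 fold between
   independent studies. Normalizer genes are dose-inert genes whose
   signal tracks the signature group's median in unirradiated (0 Gy)
   controls across pooled training datasets (smallest sum of squared
   differences). The reconstructor signal is, per sample,
   `S = median(signature genes) − median(normalizer genes)` — exactly
   invariant to array-wide shifts.
3. **Standard curve and inversion.** On training data,
   `Dose = k0 + k1·S + k2·S⁴` (power structure chosen by AICc among
   {1}, {1,2}, {1,3}, {1,4}, {1,2,4}) is fitted by ordinary least squares
   and by Huber robust regression (c = 1.345). Test-set doses are read off
   the fitted curve and summarized per true dose with R² (against the 1:1
   line) and RMSE in Gy.

A synthetic-study generator (`radrecon.simulate`) reproduces the
statistical structure this analysis assumes — planted concave dose
responders, co-varying normalizer-eligible genes, donor baseline
intercepts, cross-study baseline shifts, a platform-shifted test set —
so that every stage is testable against known ground truth.

## Worked example

`examples/04_dose_reconstruction.py` simulates the default four-dataset
study (5,000 genes; training doses 0–8 and 0–4 Gy; test doses 0–4.4 and
0–6 Gy; five donors each) and runs the full analysis:

```
signature: 38 genes; normalizers: 38 genes
train Spearman(S, dose) = 0.976
selected powers (1, 3); ols k = [0.08, 1.09, 1.38], robust k = [0.08, 1.13, 1.36]

test1 (same platform): R2 = 0.871, RMSE = 0.61 Gy
 true_dose_gy  n  mean   sd
         0.00  5  0.05 0.10
         0.56  5  0.65 0.33
         2.20  5  2.59 1.09
         4.40  5  4.09 0.51

test2 (different platform): R2 = 0.626, RMSE = 1.36 Gy
 true_dose_gy  n  mean   sd
          0.0  5  0.03 0.09
          1.5  5  2.00 0.86
          3.0  5  4.63 1.35
          6.0  5  6.43 1.67
```

Reading this: 38 of the 40 planted dose-responsive genes were recovered
with no false positives; the normalized signal correlates 0.976 with dose
across the pooled training sets; reconstructed doses on the same-platform
test set track the truth (group means within ~0.4 Gy everywhere), while
the platform-shifted test set shows the expected larger errors. Other
examples cover simulation (`01`), signature selection (`02`), normalizer
selection and shift invariance (`03`), and the permutation / planted-
predictor controls (`05`).

A thin command line mirrors the library
(`radrecon simulate | preprocess | select-signature | select-normalizers |
fit | reconstruct | evaluate | run-all`, with global `--seed`, `--config`,
`--out-dir`, `--log-level`); matrices and metadata travel as plain TSV.

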