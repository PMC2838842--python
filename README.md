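# twocolor

Genewise ratio- and intensity-based linear models for dual-color
gene-expression microarray data.

## The problem

On a dual-color (two-channel) array, two RNA samples labeled Cy3 and Cy5
are co-hybridized, yielding two intensity measurements per probe per array.
The classical analysis works on within-array log-ratios — equivalently, a
genewise ANOVA with a per-gene *array effect* — which protects against
between-array technical variation at the cost of nearly half the degrees of
freedom.  On modern high-quality platforms the array effect is small, and
simply analyzing the single log2 channel intensities (dropping the array
effect) can give more reproducible gene rankings and smaller p-values,
especially in complex direct designs such as interwoven loops.

This package implements both analyses and the machinery to compare them.
Per probe, the log2 channel intensities *y* are modeled as

    ratio model:      y = mu + tau_i + eta_j + alpha_k + eps
    intensity model:  y = mu + tau_i + eta_j + eps

with treatment effect tau_i (the F-tested factor of interest), optional
unit effect eta_j (cell line / subject), per-gene array effect alpha_k, and
Gaussian noise eps ~ N(0, sigma^2).  The toolkit covers:

- **preprocessing** — wide-TSV and Feature-Extraction-style channel
  readers, pooled quantile normalization (rank-wise mean reference, average
  ties), and the mean-intensity filter A > 7;
- **model fitting** — vectorized genewise least squares with pivoted-QR
  aliasing reports, treatment F-tests, pairwise M-value contrasts, and
  per-probe BIC = −2·logL + (rank + 1)·ln n for model selection;
- **evaluation** — Spearman correlation of p-value lists, ranked-bin and
  top-k overlap curves, recall at the ratio model's p-value cutoff,
  in-silico ratio reconstruction from single channels, treatment vs array
  effect-size densities, M-value reproducibility, and complete-linkage
  channel clustering (1 − Pearson r distance, Newick output);
- **power** — non-central-t power of the paired (with array effect) vs
  two-sample (without) analysis for direct two-group designs:
  `ncp = delta·sqrt(n)/(sqrt(2)·sigma_e)` with df = n − 1 when pairing, vs
  `ncp = delta/(sqrt(sigma_a² + sigma_e²)·sqrt(2/n))` with df = 2n − 2
  without;
- **simulation** — dual-color datasets with known ground truth on
  two-group-paired, replicated-factorial (dye-swap duplicates) and
  interwoven-loop topologies, plus technical-replicate splitting rules.

## Worked example

Simulate a cohort-style interwoven loop (7 groups × 7 subjects, each
hybridized twice, large subject-level variance), split it into two
biologically identical halves, fit both models per half, and compare their
reproducibility:

```sh
twocolor simulate --seed 42 --n-probes 2000 --topology interwoven-loop \
    --n-groups 7 --n-units-per-group 7 --sigma-unit 1.0 --fraction-de 0.1 \
    --out demo
twocolor fit demo/expression.tsv demo/design.tsv --model both \
    --split once-per-subject --out-prefix demo/fits
twocolor reproducibility demo/fits_half1_intensity.tsv \
    demo/fits_half2_intensity.tsv --k-max 500 --bin-size 500 \
    --out-prefix demo/rep_int
twocolor reproducibility demo/fits_half1_ratio.tsv \
    demo/fits_half2_ratio.tsv --k-max 500 --bin-size 500 \
    --out-prefix demo/rep_ratio
twocolor compare-models demo/fits_half1_ratio.tsv demo/fits_half1_intensity.tsv
```

Output (abridged):

```
spearman_rho    0.8754          # intensity model, between halves
spearman_rho    0.3897          # ratio model, between halves
intensity_preferred_fraction    0.9980
ratio_preferred_fraction        0.0020
```

The intensity model's p-values correlate at rho = 0.88 between the two
technical-replicate halves while the ratio model's reach only 0.39, and at
k = 500 the intensity model reproduces 79% of the top-ranked genes against
47% for the ratio model (`demo/rep_*_topk_overlap.tsv`).  BIC prefers the
intensity model for 99.8% of probes: with one subject pair per array, the
array effect consumes most degrees of freedom while explaining little
variance.  The analytic power view of the same trade-off:

```sh
twocolor power --delta -0.35 --sigma-e 0.25 --sigma-a 0.125 --n-min 2 --n-max 20
power_with_at_n2        0.0921
power_without_at_n2     0.1199
crossings       [(6, 7)]
```

The two-sample analysis wins for few arrays (more df); pairing overtakes it
between 6 and 7 arrays once removing sigma_a outweighs the df loss.

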