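# Methods

## Model

Each probe on a dual-color array yields one intensity per dye channel; an
experiment with *n* arrays gives a 2*n*-vector *y* of log2 intensities per
probe.  Two nested fixed-effects ANOVA models are fit per probe:

- **ratio model**: `y = mu + tau_i + eta_j + alpha_k + eps` — the per-gene
  array effect `alpha_k` absorbs between-array shifts, making the analysis
  equivalent to one on within-array log-ratios (for a balanced paired
  design the treatment F-test equals the squared paired t-test on
  log-ratios; the suite asserts this identity);
- **intensity model**: the same without `alpha_k`, treating single
  channels as exchangeable observations.

`tau_i` is the treatment/group factor of interest, `eta_j` an optional
experimental-unit factor (cell line; omitted for the cohort design, where
the subject is the unit of biological noise, not a modeled factor).  Dye
effects are not modeled: generated designs are dye-balanced and quantile
normalization equalizes channel distributions.  No multiple-testing
correction is applied anywhere — downstream comparisons operate on ranks
and would be distorted by it.

### Fitting and inference

Fits use the Moore–Penrose pseudo-inverse, so rank-deficient designs
(treatment partially confounded with arrays, as in replicated factorials)
are handled without intervention: coefficients are the minimum-norm
solution, estimable contrasts are unique, and a pivoted-QR aliasing report
lists redundant columns.  Treatment and unit factors use reference-level
coding; the array factor uses full indicator coding, whose redundancy with
the intercept the pseudo-inverse resolves.  A contrast c is declared
estimable when `X⁺X c = c` to 1e-8.

The treatment F-test is the extra-sum-of-squares test against the same
model with treatment columns removed: `F = ((RSS_r − RSS_f)/q)/(RSS_f/df_f)`
with `q = df_r − df_f`.  Degenerate probes: an exact full fit with reduced
misfit reports p = 0 (flagged); a vector both models fit exactly reports
F = 0, p = 1; a saturated model (0 residual df) reports an undefined
p-value with a flag instead of raising.

BIC uses the Gaussian profile likelihood at the ML variance RSS/n, with
parameter count = column-space rank + 1 (residual variance); the lower BIC
wins and ties go to the intensity model.  Ranking ties on p-values are
broken lexicographically by probe id, a stable documented rule shared by
all overlap metrics.

### Array effect size

The per-probe "array effect size" reported for ratio-model fits is the
mean absolute *centered* array coefficient (deviation from the mean array
level).  Centering makes the summary invariant to the indicator coding's
redundancy and to the choice of reference array; raw minimum-norm
indicator coefficients would absorb a share of the baseline and are not
interpretable as effect sizes.

## Preprocessing

All 2n channels are pooled into a single quantile normalization: each
channel is mapped onto the rank-wise mean of the per-channel sorted values,
ties receiving the mean of the reference values at their tied ranks (so
dye-swapped duplicates normalize symmetrically); log2 is applied after.
Pooling all channels — rather than normalizing within arrays only — makes
channels exchangeable, which the intensity analysis requires.  Zero or
negative intensities are rejected rather than offset-corrected: no
background correction is performed, and a silent pseudocount would change
the intensity filter.  The A-filter keeps probes with mean log2 intensity
strictly above the threshold (default 7) across *all* channels, so
per-probe sample sizes stay equal; it is applied to the full normalized
dataset before any replicate split.

## Technical-replicate splitting

`by-replicate-set` assigns each array's two channels to the half named by
their replicate-set label.  `once-per-subject` handles designs where every
unit was hybridized exactly twice: co-hybridization links units into
cycles (arrays are edges, units vertices), and the split walks each cycle
assigning alternate arrays to alternate halves, so each unit lands once per
half and as many within-array pairs as possible stay intact (one torn
array per odd cycle).  This choice is deliberate: assigning e.g. each
unit's first channel to half 1 would fill a half with single-channel
arrays, saturating the with-array-effect model (0 residual df) and making
the comparison impossible.  It also reproduces the situation the loop
design creates in practice — the two halves pair the same samples
differently on arrays, which is precisely why ratio-based results
reproduce poorly when biological variance is large.  A seeded variant
randomizes the per-cycle parity for robustness studies.

## Power analysis

For a direct two-group design with n arrays, both analyses test the same
effect delta with a t statistic; power comes from the non-central
t-distribution with `power = P(|T'_{df,ncp}| > t_{df,1−alpha/2})`:

| analysis | df | noncentrality |
|---|---|---|
| paired (with array effect) | n − 1 | `delta·sqrt(n)/(sqrt(2)·sigma_e)` |
| two-sample (without) | 2n − 2 | `delta/(sqrt(sigma_a²+sigma_e²)·sqrt(2/n))` |

Array effects are treated as fixed, as the ratio model implies: pairing
cancels sigma_a exactly, while the intensity analysis absorbs it into the
per-channel noise under its own exchangeability assumption (the
Monte-Carlo checks simulate each analysis under the model it assumes).
alpha defaults to 0.05 two-sided; both are flags.  When estimated from
data, sigma_e² is the ratio-model residual variance (RSS/df) and sigma_a²
the excess of the intensity-model residual variance over it, floored at 0.
scipy's noncentral-t CDF returns NaN for large df × large ncp; the
Johnson–Kotz normal approximation is substituted there (the regime where
power is numerically 1).  Average power over a gene set keeps probes with
|delta| > 0.25 — a set that plausibly carries differential signal — and
averages per-probe power, i.e. the expected fraction declared significant.

## Simulator

`simulate_dataset` draws `y[g,c] = mu[g] + tau[g,group(c)] + b[g,unit(c)]
+ alpha[g,array(c)] + dye_shift + eps[g,c]`, all Gaussian.  Array effects
are per (probe, array) — spot-level, matching what the genewise ratio
model estimates — not array-wide shifts.  One root seed spawns
per-component substreams, so enlarging the probe count leaves existing
probes' values unchanged.  Defaults (log2 units): baseline N(10, 1), noise
sd 0.25 (typical residual scatter of modern oligo platforms), array-effect
sd 0.1 (small relative to noise, the regime of current commercial arrays),
subject sd 0 (set ~1.0 for cohort emulations), DE fraction 0.2 with
N(0, 0.5) per-group effects; dye effect 0 (balanced designs, a nonzero
option exists for misspecification studies).

Topologies: `two-group-paired` puts both groups on every array with a
dye swap halfway; `factorial-replicated` crosses units with treatments and
hybridizes every treatment pair in both dye orientations within each
replicate set (each sample measured once per dye — 8 arrays / 16 channels
per set for 4 treatments × 2 units), giving each half 11 intensity-model
and 6 ratio-model residual df; `interwoven-loop` chains samples around a
loop g → g+1 so every unit appears exactly twice, once per dye.

### Study conditions used by tests and the acceptance script

- *Cell-line-like*: factorial, 4 treatments × 2 units × 2 sets, 20,000
  probes, DE fraction 0.05 with effect sd 1.0, no subject variance.  The
  small fraction of strongly responding genes reflects a targeted
  perturbation experiment on a genome-wide array; with a top-1000 list
  this yields ~90%/~79% reproduced genes (intensity/ratio) and ~95% BIC
  preference for intensity — the regime of a high-quality replicated
  factorial.
- *Brain-like*: interwoven loop, 7 groups × 7 subjects, 20,000 probes,
  DE fraction 0.1 with effect sd 0.4, subject sd 1.0 (biological variance
  dominating the effects).  Here the ratio model's rankings collapse
  (different sample pairings between halves) while intensity rankings
  remain reproducible, and BIC prefers intensity essentially everywhere.
- *Benchmark*: two-group paired, 10 arrays, DE fraction 0.3, effect sd
  0.4.  Used for BIC at small sample size, in-silico ratio reconstruction,
  and the power trade-off (the average-power curves cross near total
  sample size 12).

What the generator does **not** emulate: intensity-dependent
(variance–mean) noise, heavy-tailed effects, spot-quality artifacts,
probe-level sequence effects, or correlated probes.  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
design-driven phenomena (df trade-off, pairing artifacts, BIC penalty
behavior), not quantitative agreement with any particular real dataset.

## Numerical choices

- RSS comparisons use an absolute floor of 1e-10 (relative to the reduced
  RSS) to classify exact fits.
- `rank` is `numpy.linalg.matrix_rank` with its default tolerance; the
  aliasing report uses pivoted QR with tolerance
  `max(|R_ii|)·max(shape)·eps`.
- Quantile normalization interpolates fractional (tied) ranks linearly on
  the reference distribution.
- Clustering distance is `1 − Pearson r` between channel vectors
  (scale-free, standard for expression QC; Euclidean available); linkage
  is scipy complete linkage, whose deterministic ordering is the tie rule.
  Constant channels are rejected by name.
- KDE bandwidth for effect-size densities is Silverman's rule, overridable.
- Dataset TSVs are written with `%.17g` and read with round-trip float
  parsing, so write/read cycles are bit-exact.

## Known limitations

- Fixed-effects only: no mixed-model (random array) variant and no
  empirical-Bayes variance moderation, so per-probe variance estimates are
  noisy at few df.
- Power analysis covers two-group comparisons (single-df contrasts) only.
- The once-per-subject split assumes each unit appears exactly twice;
  higher replication levels are out of scope.
- Individual array coefficients are not estimable in general; only
  centered summaries are reported.
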