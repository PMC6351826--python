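# Methods

## Scientific setting

During OSKM reprogramming of human dermal fibroblasts, DNA-methylation age
predictors ("epigenetic clocks") report a steep, roughly linear fall in
predicted age during the partially reprogrammed phase, stabilizing near
zero around day 20 of a 49-day course, while fibroblast-identity gene
expression declines with different, stepwise kinetics. `rejuvotrack`
implements the three quantitative pieces of that analysis — clock
prediction, broken-stick time-course modelling, and longitudinal clustering
of marker expression — plus generators that plant known structure so every
estimator can be validated by recovery.

## Clock engine

A clock is a linear predictor `score = intercept + Σ wᵢ βᵢ` over CpG beta
values in [0, 1], read from a plain-text file:

```
#name=...          #intercept=...        #transform=identity|log-linear
#adult_age=...     (required for log-linear)
cg00000001,0.42    ... one probe,weight record per line
```

For log-linear clocks the score lives on the transformed-age scale
`f(age) = log(age+1) − log(adult_age+1)` (age ≤ adult_age), else
`(age − adult_age)/(adult_age+1)`; predicted age is `f⁻¹(score)`. The
transform is continuous, strictly increasing, zero at `adult_age`
(default 20 years, per-clock configurable) and defined for age > −1; its
inverse is defined on all reals, so any score maps to a finite age.

Numerical and policy choices:

* **Missing probes** default to a hard error: silent imputation distorts
  predicted age. `impute_half` substitutes β = 0.5; `impute_reference`
  substitutes user-supplied per-probe means. The per-sample count of
  imputed probes is reported in every output row. A sample with *no*
  called clock probe is always an error.
* **Beta validation**: values outside [0, 1] by more than 1e−6 are rejected
  (they are almost certainly logit-scale M-values); values within the
  tolerance are clipped.
* Single age-tracking CpGs are followed as raw per-day beta mean ± SD
  (`extract_cpg_trajectory`), not as one-probe clocks, because the
  interesting quantity there is the methylation trajectory itself, not a
  calibrated age.
* Published coefficient sets are **not** bundled (provenance/licensing);
  the package ships a 50-probe toy clock generator for tests and demos.

## Broken-stick model

The per-sample ages are aggregated by day (mean, SD with ddof = 1, n), and
the model

`y(t) = a + b₁·min(t − t₀, τ − t₀) + b₂·max(t − τ, 0)`

is fitted on **replicate-level** points (not per-day means) inside a window
(default days 3–49: the earliest days precede the onset of decline). For
each candidate τ the model is linear and solved by least squares; τ is
chosen by exhaustive search to minimize RSS, with ties broken toward the
smallest candidate (relative RSS tolerance 1e−10). Candidates default to
the observed days strictly inside the window plus midpoints of adjacent
days, keeping only candidates with at least two distinct observed days on
each side; continuity at τ is enforced by the parameterization, and a
discontinuous variant is out of scope.

Inference on `b₁` (SE, two-sided t-test, df = n − 3, via OLS) **conditions
on the estimated τ**, the standard practice for broken-stick fits; reports
label the p-value accordingly. Fitting replicate-level points unweighted is
a deliberate choice: with ~9 distinct days, per-day means would leave few
residual degrees of freedom and mis-state the slope SE. The fitted model's
RSS can never exceed that of the best single straight line, since a line is
the boundary case of the family (equal slopes); the suite asserts this
non-strictly against a directly fitted simple regression.

`simulate_fit_recovery` closes the loop: it simulates replicate-level
courses from a piecewise-linear truth with i.i.d. Gaussian age noise and
refits each one. Zero noise must reproduce the truth exactly; at the
default study conditions the slope estimate is unbiased to within
Monte-Carlo error and the modal breakpoint lands on the true day.

## Expression normalization and clustering

Per panel gene: replicates are averaged per day on the linear scale,
log2-transformed, and affinely rescaled so the first day maps to 0 and the
last to 1 (ascending panels) or 1 → 0 (descending). The affine rescale in
log space absorbs any per-gene constant reference or multiplicative scale,
which is why no explicit reference sample is needed; endpoint anchoring is
exact by construction, and intermediate days may legitimately fall outside
[0, 1] for non-monotone genes. A gene with equal first- and last-day log2
expression makes the rescale undefined and raises a named error. Missing
days are not supported (the source arrays are complete grids).

Clustering is longitudinal k-means: plain Euclidean distance between the
per-gene day vectors on the shared grid (no time warping — all genes share
one grid), `n_restarts` initializations per candidate k, best by
within-cluster sum of squares, and k selected by the Calinski–Harabasz
criterion over k = 1–6 by default. CH is undefined at k = 1, which is
recorded as NaN and selectable only when it is the sole candidate; at
k = n_genes the criterion degenerates (within-cluster variance 0) and is
recorded as +inf, so candidate ranges should stay below the gene count.
Genes are processed in probe-ID-sorted order with labels canonicalized by
first appearance, making results independent of input row order and fully
determined by the seed. Bundled panels carry the published cluster labels
as *hints* for comparison only — two fibroblast genes (HSP47, CD34) were
published without a label and are clustered anyway but flagged in the
selection report.

## Synthetic generators

`synth_beta_course` inverts the clock: from a mid-range base profile
(β = 0.5 everywhere) each sample's betas are shifted along the clock weight
vector by `(s − score₀)·w/‖w‖²` to hit the forward-transformed target age
exactly, and methylation-level noise is added **orthogonally to w**, so
beta noise and age noise are independently controllable — naive i.i.d. beta
noise would confound the two. Values are clipped to [0, 1]; clipping events
are counted, and more than 1% of entries clipped aborts generation (the
trajectory is unreachable for that clock). With zero noise and zero
clipping, prediction reproduces the targets to 1e−6 years.

Default scenario (the study conditions every recovery test uses): day grid
{0, 3, 7, 11, 15, 20, 28, 35, 42, 49}; decline −3.8 years/day from day 3 to
a breakpoint at day 20; plateau 0 years afterwards (start age 64.6 years
makes the trajectory exactly continuous); 3 replicates per day; age noise
SD 2 years; beta noise SD 0.01. Replicate counts and error magnitudes of
real time courses are not published for this design, so n = 3 and SD 2 yr
are labelled assumptions, chosen to resemble the SD error bars of typical
array replicates, and kept configurable. Noisy target ages are floored at
0 years before inversion: the log-linear transform is undefined at or below
−1 year, and a fully reprogrammed epigenome does not meaningfully predict
negative ages; the floor only affects plateau-phase noise realizations.
The default toy clock (50 probes, weights ~ N(0, 0.5), intercept set so the
base profile predicts 65 years) uses a fixed weight draw for which the
default trajectory is reachable without any clipping.

`synth_expression_course` plants per-gene log2 trajectories
`baseline_g + amplitude·(template + ε)`, ε ~ N(0, noise_sd), exponentiated
to the linear scale. The baseline (per-gene, N(8, 1) log2 units) and shared
amplitude (4 log2 units ≈ 16-fold dynamic range) are absorbed by the
pipeline's normalization, so recovered trajectories match the templates up
to noise. Shipped templates: two ascending pluripotency-like shapes (early
activation stabilizing by ~day 20, 11 genes; late activation stabilizing by
~day 28, 8 genes) and three descending fibroblast-like shapes (slow
decline, plateau-then-decline, immediate decline; 4/8/7 genes). Default
noise SD 0.05 arbitrary units keeps template separation well above noise,
the regime the clustering stage is designed for.

What the generators deliberately do **not** emulate: array probe-level
technical artifacts, batch effects, normalization residuals (BMIQ/noob is
out of scope — betas are taken as given), cell-subpopulation mixtures, and
probe-annotation drift. Passing recovery tests therefore demonstrates
estimator correctness under the stated noise model, not robustness to raw
array pathology.

## Pipeline

A YAML config names the inputs (clock files, beta matrix, expression
matrix, sample sheet, panels) and parameters (fit window, breakpoint grid,
k range, restarts, seed, output directory). Every output carries the seed
and a SHA-256 hash of the resolved config (output path excluded), and
reruns are byte-identical. Clocks that fail probe coverage are logged and
skipped; a run fails only when no clock succeeds. Problem sizes throughout
(200-course recovery simulations, 50-seed cluster-count sweeps, 50-probe
toy clocks) are desk-scale by design — each full suite completes in
seconds.

## Known limitations

* One breakpoint only; no ≥3-segment models, and no bootstrap confidence
  interval for τ (future work).
* The breakpoint search is grid-based; a continuous-τ optimum between grid
  candidates is not pursued, which matches the day-resolution reporting of
  reprogramming time courses.
* Inference on the pre-break slope ignores breakpoint-estimation
  uncertainty (it conditions on τ̂).
* Clock training (elastic-net fitting), IDAT parsing, array normalization
  and public-repository retrieval are out of scope.
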