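# Methods

`cismaxt` screens for cis-regulatory relationships between gene expression,
common genetic variants (SNP dosages) and DNA methylation (CpG sites)
measured on the same samples. It is built for the hard regime these studies
live in — a handful of samples (tens), thousands of probes, and windows of
dozens to hundreds of correlated predictors per probe — where per-feature
univariate testing wastes power and multivariable least squares is
ill-posed.

## Model

For one expression probe with centered outcome $y \in \mathbb{R}^n$ and the
standardized cis-window design $X \in \mathbb{R}^{n \times p}$ (SNP columns,
CpG columns, or both concatenated for the *global* model), the package
minimizes

$$
\frac{1}{2n}\lVert y - \beta_0 - X\beta \rVert_2^2
+ \lambda\Big( f \lVert \beta \rVert_1 + \tfrac{1-f}{2}\lVert \beta \rVert_2^2 \Big),
$$

with $f = 1$ the LASSO and $f \in (0,1)$ the elastic net. The solver is
scikit-learn's cyclical coordinate descent (`enet_path`), run along a
geometric penalty path from $\lambda_{\max} = \max_j |x_j^\top y| / (nf)$
(the smallest penalty whose solution is all-zero, from the KKT conditions at
$\beta = 0$) down to $\lambda_{\max} \cdot r_{\min}$.

**Mixing convention.** $f$ is the *L1 fraction*: $f = 1$ is the LASSO and
$f \to 0$ approaches ridge. Some of the literature parameterizes the same
family by the ridge fraction $\alpha = 1 - f$ (so that $\alpha = 1$ is
ridge); the estimator exposes `ridge_fraction_` next to
`chosen_l1_fraction_` so results can be read in either convention without
ambiguity.

**Penalty selection.** $\lambda$ — and for the elastic net the pair
$(f, \lambda)$ jointly over a grid of L1 fractions (default 0.01…0.99 by
0.01) — is chosen to minimize the pooled $k$-fold cross-validated squared
prediction error ($k = 5$ by default; with $n = 27$ the folds have sizes
6, 6, 5, 5, 5). Folds are contiguous blocks of a seeded shuffle, fixed per
design, and reused across the whole path, the whole mixing grid and every
permutation replicate of a probe, so that CV noise never differs between
arms that are meant to be comparable. Ties in CV error (within $10^{-12}$)
resolve to the largest $\lambda$, then the largest $f$: the sparsest of the
equally good models. The minimum-CV-error rule is used rather than the
one-standard-error rule; the screen's null calibration comes from
permutation, not from the conservativeness of the selection rule.

**Goodness of fit.** Each fitted model is scored against the intercept-only
null by the Gaussian deviance with the ML variance profiled out per model:

$$
D = 2\,[\ell(\text{full}) - \ell(\text{null})] = n \ln \frac{RSS_0}{RSS_1}.
$$

$D \ge 0$ always, because $\beta = 0$ is feasible for the penalized
problem, so the training RSS of a penalized fit never exceeds $RSS_0$.
Degenerate guards: empty design or constant $y$ give $D = 0$; $RSS_1$ is
floored at $10^{-12} RSS_0$ so interpolating fits stay finite.

## Significance: step-down permutation maxT

Penalized estimates are biased and carry no usable standard errors, so
per-model significance and family-wise error control are obtained in one
permutation pass. Sample labels of the expression vectors are permuted $B$
times (default 100) and *every* fit — CV penalty selection included — is
redone per replicate. With observed deviances ordered
$|D_{(1)}| \ge \dots \ge |D_{(m)}|$ and $D_{(i),b}$ the permuted statistic
of ordered hypothesis $i$ in replicate $b$:

$$
U_{(m),b} = |D_{(m),b}|, \qquad U_{(i),b} = \max(U_{(i+1),b}, |D_{(i),b}|),
$$
$$
p_{(i)} = \#\{b : U_{(i),b} \ge |D_{(i)}|\} / B, \qquad
\tilde p_{(i)} = \max(\tilde p_{(i-1)}, p_{(i)}).
$$

The final monotonicity pass is standard in the Westfall–Young step-down
procedure and guarantees that adjusted p-values are non-decreasing in rank
and that each probe's adjusted p dominates its own marginal permutation
p-value. Ties in $|D|$ order by ascending probe id (stable). Probes with no
cis candidates are kept as hypotheses with $D = 0$, so the tested family is
always the full probe universe.

One shared reordering per replicate is applied to all probes (the default):
this preserves the dependence structure between genes under the null, which
is what lets the procedure adapt to inter-gene correlation. A per-probe
independent mode (`shared_permutations=False`) exists for comparison.

At $B = 100$ the smallest nonzero adjusted p is 0.01 and an estimate of
exactly 0 is possible; outputs render 0 as `<0.01` (`<1/B`) to make the
resolution explicit. No pseudo-count smoothing is applied. The default
significance rule is strict: $\tilde p < 0.1$.

**Exchangeability by construction.** `run_model` first reorders every layer
into sorted-sample-id order and derives folds and the permutation plan from
that canonical order. Relabeling the input samples identically in all
layers therefore changes nothing — every deviance and adjusted p-value is
invariant — and any execution order of the replicates yields identical
results given the plan.

## Preprocessing

* **M-values:** CpG beta-values are modelled on the
  $M = \log_2(\beta/(1-\beta))$ scale, which is closer to homoscedastic.
  Betas are clipped to $[10^{-6}, 1-10^{-6}]$ first (count logged); values
  outside $[0,1]$ are errors.
* **Standardization:** predictor columns are centered and scaled by the
  population SD (divide by $n$), matching the $1/n$ objective
  normalization. Constant columns are dropped (logged). Coefficients are
  reported on the standardized scale.
* **Perfect-LD filter:** SNP pairs with $r^2 = 1$ (within $10^{-12}$;
  includes $r = -1$ allele-coding mirrors) are collapsed to the
  first-occurring feature in genomic order. Detection runs in
  $O(\text{features} \times \text{samples})$ by grouping sign-canonical
  z-score keys and verifying candidates by direct correlation; constant
  rows, whose correlation is undefined, are retained. The filter exists
  because exact duplicates make the design rank-deficient without adding
  information; *near*-perfect LD is deliberately left in — handling
  correlated predictors is the method's job, and pre-filtering them risks
  discarding the functional variant.
* **Missing values** are a hard error everywhere; imputation belongs
  upstream.

## Cis windows

The window of a probe annotated on $[s, e)$ is
$[\max(0, s - w), e + w)$ on the same chromosome, $w$ = 1 Mb by default,
symmetric and strand-agnostic (anchored on the annotated interval, not a
midpoint). Point features belong if their start lies inside; interval
features by any-overlap. Coordinates are BED convention (0-based,
half-open) throughout.

## Synthetic data

The generator exists to calibrate and stress the screen, not to imitate a
population:

* **Null expression:** i.i.d. $\mathcal{N}(\mu = 8.4, \sigma^2 = 0.4)$,
  $n = 27$ samples by default — log-scale microarray-like intensities,
  independent of every predictor, so any discovery on such data is a false
  positive by construction.
* **Genotypes:** Hardy–Weinberg dosages with per-SNP MAF uniform on
  $(0.05, 0.5]$, organized in LD blocks (default size 5): each block copies
  a founder genotype with per-sample redraw probability 0.1, giving high
  within-block correlation. Block size 1 gives independent SNPs; redraw
  probability 0 gives perfect LD (exercising the LD filter).
* **Methylation:** latent Gaussian M-values with exchangeable correlation
  (default 0.5) within islands of 5 CpGs, pushed through the logistic
  inverse of the M-transform, so the transform recovers the latent scale
  exactly.
* **Signals:** selected probes get
  $\mu + \sum \beta_k \cdot \text{standardized(feature}_k) +
  \mathcal{N}(0, \text{noise\_sd}^2)$; a standardized $\beta = 2$ with
  noise SD 0.3 explains $4/4.09 \approx 98\%$ of that probe's variance.
* Probes are spaced 2.2 Mb apart (22 pseudo-chromosomes), so ±1 Mb windows
  never share features; layer seeds are spawned disjointly from the master
  seed, so e.g. changing genotype knobs never perturbs the expression draws.

What this does *not* emulate: realistic allele-frequency spectra,
recombination-map LD decay, cell-type composition, batch structure, probe
cross-hybridization, or trans effects. Passing the calibration suite on
these data shows the procedure controls its error rate and recovers strong
planted cis signals under multicollinear $p \gg n$ designs; it does not
certify behavior under real-data artifacts that the generator omits.

## Numerical choices and problem sizes

* Penalty path: 20 log-spaced values, $r_{\min} = 0.01$. At $n = 27$ and
  $k = 5$ the CV error curve's fold-to-fold noise dwarfs the difference
  between adjacent path points at ~27% spacing, so a denser grid buys
  nothing statistically; both knobs are exposed.
* Coordinate descent: fold fits run at tolerance $10^{-3}$ (they only feed
  penalty *selection*); the refit at the chosen penalty runs at $10^{-7}$.
  The small-$\lambda$ end of a path need not fully converge when
  $n \ll p$; residual duality gaps there do not move the CV minimum.
* Per-probe engines precompute the standardized design and per-fold Gram
  matrices once and reuse them across all $B + 1$ fits of that probe.
* The calibration suite runs scaled-down study shapes chosen as the
  package's own reference conditions: one 200-probe and one 50-probe null
  screen ($B = 100$), 20 null datasets of 50 probes for the family-wise
  error estimate, and 20 seeds × 10 probes for power/recovery;
  `scripts/acceptance.py` uses 10 null datasets for its error-rate
  estimate.

## Known limitations

* $B = 100$ gives coarse p-value resolution (increments of 0.01); raising
  `n_permutations` is the only remedy and costs linearly.
* A single-run null screen has, by exchangeability, probability
  $\approx 10/(B+1)$ of at least one discovery at threshold 0.1 — that is
  the error rate working as designed, not a defect; calibration claims rest
  on the repeated-dataset estimate.
* The deviance compares *training* fits; it is a goodness-of-fit screen
  statistic, not an out-of-sample estimate of effect size, and selected
  coefficients are shrunken (biased) by construction.
* The elastic-net joint grid search is exhaustive over (grid × path ×
  folds); with the full 99-point mixing grid it is roughly 20× the LASSO
  cost per probe. Coarser grids are the practical default at permutation
  scale.
* Probes and features are matched by id between matrix and annotation
  files; the package does no liftover or annotation retrieval.
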