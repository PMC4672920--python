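# cismaxt

Cis-window penalized regression across omics layers, with significance and
family-wise error control from a single permutation pass.

## What problem this solves

Studies that profile the same tumor or tissue samples on several platforms —
SNP arrays, CpG methylation arrays, expression arrays — want to know which
genes' expression levels are driven by nearby genetic variants and/or
methylation. The regime is hostile: tens of samples against thousands of
probes, dozens-to-hundreds of candidate features per gene, and strong
correlation among those features (LD blocks, CpG islands). Univariate
per-feature testing ignores the joint structure; ordinary multivariable
regression is ill-posed at `n << p`; and penalized fits, which handle both,
produce biased coefficients with no usable standard errors — so there is no
analytic p-value to rank or threshold them with.

`cismaxt` implements the standard answer to all three at once. For every
expression probe it builds the set of SNPs and CpGs within ±1 Mb of the
gene, fits a penalized multivariable model of expression on those features —
LASSO or elastic net, with the penalty chosen by k-fold cross-validation —
in three flavors (SNP-only, CpG-only, and the *global* model concatenating
both layers), and scores each fit by its Gaussian deviance against the
intercept-only null,

    D = 2[loglik(full) − loglik(null)] = n · ln(RSS₀ / RSS₁).

Significance comes from the step-down **maxT** permutation procedure of
Westfall & Young: sample labels of the expression vectors are permuted B
times (shared across probes, preserving inter-gene dependence), every fit —
including its CV penalty selection — is redone, and adjusted p-values are
computed from the successive maxima of the permuted deviances. One
permutation pass yields both the p-values and the family-wise error
correction. Audience: statistical geneticists and bioinformaticians running
eQTL/methQTL-style integration screens, and anyone needing a permutation-
calibrated significance layer on top of penalized per-gene models.

See `docs/methods.md` for the model, the algorithm and every numerical
choice.

## Worked example

Simulate a 27-sample dataset of 8 probes with 30-SNP cis windows, plant a
strong effect of one SNP on one probe (standardized β = 2, noise SD 0.3 ⇒
~98% of that probe's variance), and screen with LASSO at B = 100:

```python
import cismaxt as cm

spec = cm.SimSpec(
    m_probes=8, n_samples=27, snps_per_window=30, seed=11, noise_sd=0.3,
    effects=(("probe00000", "snp00000_0004", 2.0),),
)
data = cm.simulate_with_signal(spec)

screen = cm.MaxTScreen(n_permutations=100, k_folds=5, seed=11,
                       model="snp", method="lasso")
screen.fit(data.expression, snps=data.snps)
print(screen.results_[["probe_id", "deviance", "p_adj", "rank",
                       "significant", "n_snps_selected"]].head(4))
```

Output (the `selected_feature_ids` column is elided here):

```
  probe_id   deviance  p_adj  rank  significant  n_snps_selected
probe00000 129.516196   0.00     1         True                7
probe00006  15.328937   0.54     2        False                9
probe00007   9.792410   0.65     3        False                4
probe00001   6.703620   0.69     4        False                2
```

The planted probe dominates: its deviance (129.5) towers over the null
probes (≤ 15), and none of the 100 permuted successive maxima reach it, so
its adjusted p-value is 0 — reported as `<0.01` in the results TSV, since
B = 100 cannot resolve below 1/B. Every other probe is correctly
non-significant at the 0.1 threshold. Among the 7 features selected for
probe00000 are block-mates of the causal SNP: its LD block is simulated at
r ≈ 0.9, and the LASSO picks representatives from correlated groups — the
elastic net (`method="enet"`) tends to bring in whole groups instead.

The same screen is available from the shell:

```bash
cismaxt simulate --m-probes 8 --seed 11 --out-dir sim/
cismaxt run --expr sim/expression.tsv --expr-bed sim/expression.bed \
            --snp sim/snp.tsv --snp-bed sim/snp.bed \
            --model snp --method lasso --permutations 100 --out-dir out/
cismaxt summarize --results out/results.tsv --results out2/results.tsv \
                  --out overlap.tsv
```

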